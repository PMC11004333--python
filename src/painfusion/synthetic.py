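"""Synthetic session generator emulating a thermode heat-pain protocol.

Produces paired facial-video / single-lead-ECG sessions with the structural
properties the assessment framework assumes: 448x448 frame sequences at a
fixed frame rate, ECG sampled at a fixed rate with known R-peak ground truth,
five balanced pain classes (NP, P1..P4) per subject, and label-dependent
effects — a facial "expression" deformation that grows with pain level and
ramps up toward the session's end, and a heart-rate offset proportional to
the pain level.  Faces are purely geometric surrogates (ellipse head, brow
and mouth strokes); only the statistical structure matters for testing, not
photo-realism.

Everything is deterministic given (seed, subject, label, repetition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

__all__ = [
    "LABELS",
    "ProtocolSpec",
    "EffectConfig",
    "SyntheticECG",
    "SyntheticSession",
    "SessionRecord",
    "synth_ecg",
    "synth_session",
    "synth_dataset",
    "build_session",
    "write_session",
]

LABELS: tuple[str, ...] = ("NP", "P1", "P2", "P3", "P4")
_LEVEL = {lab: i for i, lab in enumerate(LABELS)}


@dataclass(frozen=True)
class ProtocolSpec:
    """Counts and sampling constants of the acquisition protocol."""

    n_subjects: int = 87
    reps_per_level: int = 20
    n_pain_levels: int = 4
    n_baseline: int = 20
    window_s: float = 5.5
    fps: float = 25.0
    fs: float = 512.0
    seed: int = 0

    @property
    def sessions_per_subject(self) -> int:
        return self.n_baseline + self.n_pain_levels * self.reps_per_level

    @property
    def total_sessions(self) -> int:
        return self.n_subjects * self.sessions_per_subject

    @property
    def n_frames(self) -> int:
        return int(round(self.window_s * self.fps))

    @property
    def n_ecg_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def labels(self) -> tuple[str, ...]:
        return LABELS[: 1 + self.n_pain_levels]


@dataclass(frozen=True)
class EffectConfig:
    """Label-dependent effect sizes injected into the synthetic sessions.

    ``bpm_per_level`` adds that many BPM per pain level to the subject's
    baseline heart rate; ``deform_px_per_level`` scales the facial-stroke
    displacement (pixels per level at 448x448).  Defaults are conventions
    chosen so the classes are separable but overlap across subjects.
    """

    bpm_per_level: float = 3.0
    deform_px_per_level: float = 3.0
    ecg_noise_sd: float = 0.05
    frame_noise_sd: float = 4.0
    baseline_bpm_mean: float = 72.0
    baseline_bpm_sd: float = 7.0


@dataclass
class SyntheticECG:
    samples: np.ndarray          # amplitude, arbitrary units
    fs: float                    # Hz
    r_peaks_truth: np.ndarray    # 0-based sample indices, strictly increasing
    hr_truth: np.ndarray         # BPM per whole second


@dataclass
class SyntheticSession:
    frames: np.ndarray           # (f, 448, 448, 3) uint8
    ecg: SyntheticECG
    label: str
    subject_id: str


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def _qrs_wavelet(fs: float) -> np.ndarray:
    """A narrow biphasic spike resembling a QRS complex (~100 ms support)."""
    half = int(round(0.05 * fs))
    t = np.arange(-half, half + 1) / fs
    sigma = 0.012
    return (1.0 - (t / sigma) ** 2) * np.exp(-0.5 * (t / sigma) ** 2)


def _t_wave(fs: float) -> np.ndarray:
    half = int(round(0.10 * fs))
    t = np.arange(-half, half + 1) / fs
    return 0.2 * np.exp(-0.5 * (t / 0.05) ** 2)


def synth_ecg(bpm_profile, fs: float, duration: float, noise_sd: float = 0.0,
              seed: int = 0) -> SyntheticECG:
    """Generate an ECG-like trace with known R-peak positions.

    ``bpm_profile`` gives the instantaneous heart rate for each whole second
    (a scalar is broadcast).  Consecutive R peaks are spaced
    ``round(60 * fs / bpm)`` samples apart, using the rate of the second the
    current peak falls in.  The trace is a QRS wavelet train plus T waves,
    a slow baseline wander, and white noise of standard deviation
    ``noise_sd`` (in units of the R amplitude, which is 1).
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    n_seconds = int(np.floor(duration))
    profile = np.broadcast_to(np.asarray(bpm_profile, dtype=float),
                              (max(n_seconds, 1),)).copy()
    if np.any(profile < 30) or np.any(profile > 220):
        raise ValueError("BPM values must lie in [30, 220]")

    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    peaks = []
    idx = int(round(0.05 * fs))  # first beat shortly after record start
    while idx < n:
        peaks.append(idx)
        sec = min(int(idx // fs), len(profile) - 1)
        idx += int(round(60.0 * fs / profile[sec]))
    peaks = np.asarray(peaks, dtype=int)

    samples = np.zeros(n)
    qrs = _qrs_wavelet(fs)
    twave = _t_wave(fs)
    t_offset = int(round(0.30 * fs))
    for p in peaks:
        _add_centered(samples, qrs, p)
        _add_centered(samples, twave, p + t_offset)
    # slow baseline wander
    tt = np.arange(n) / fs
    samples += 0.1 * np.sin(2 * np.pi * 0.33 * tt + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, n)

    return SyntheticECG(samples=samples, fs=float(fs), r_peaks_truth=peaks,
                        hr_truth=profile[:n_seconds])


def _add_centered(signal: np.ndarray, wave: np.ndarray, center: int) -> None:
    half = len(wave) // 2
    lo, hi = center - half, center - half + len(wave)
    s_lo, s_hi = max(lo, 0), min(hi, len(signal))
    if s_lo >= s_hi:
        return
    signal[s_lo:s_hi] += wave[s_lo - lo: s_hi - lo]


# ---------------------------------------------------------------------------
# Face surrogate drawing
# ---------------------------------------------------------------------------

def _draw_face(size: int, deform: float, geom: dict) -> np.ndarray:
    """Draw a geometric face surrogate; ``deform`` displaces brows and mouth."""
    img = Image.new("RGB", (size, size), (32, 32, 40))
    d = ImageDraw.Draw(img)
    cx, cy = geom["cx"], geom["cy"]
    rx, ry = geom["rx"], geom["ry"]
    d.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=(208, 172, 140))
    # eyes
    ex, ey, er = 0.42 * rx, 0.25 * ry, max(int(0.09 * rx), 2)
    for sx in (-1, 1):
        x, y = cx + sx * ex, cy - ey
        d.ellipse([x - er, y - er, x + er, y + er], fill=(40, 32, 28))
    # brows: inner ends pulled down/ together with pain
    by = cy - 0.45 * ry
    for sx in (-1, 1):
        x0, x1 = cx + sx * 0.20 * rx, cx + sx * 0.62 * rx
        d.line([x0, by + deform, x1, by - 0.3 * deform],
               fill=(60, 40, 30), width=max(int(0.05 * rx), 2))
    # mouth: a line that opens (drops) with pain
    my = cy + 0.48 * ry
    d.line([cx - 0.35 * rx, my, cx, my + deform, cx + 0.35 * rx, my],
           fill=(120, 40, 40), width=max(int(0.05 * rx), 2))
    # nasolabial strokes deepen with pain
    if deform > 0:
        for sx in (-1, 1):
            d.line([cx + sx * 0.18 * rx, cy + 0.12 * ry,
                    cx + sx * (0.30 * rx + 0.5 * deform), my - 0.10 * ry],
                   fill=(150, 110, 90), width=2)
    return np.asarray(img, dtype=np.uint8)


def synth_session(subject_id, label: str, spec: ProtocolSpec, seed: int = 0,
                  effects: EffectConfig | None = None,
                  rep: int = 0, frame_size: int = 448) -> SyntheticSession:
    """Build one labelled session (frames + ECG) for one subject.

    Deterministic under identical (subject_id, label, seed, rep).  The mean
    of ``ecg.hr_truth`` equals the subject baseline plus
    ``level * effects.bpm_per_level``.
    """
    if label not in LABELS:
        raise ValueError(f"invalid label {label!r}; expected one of {LABELS}")
    effects = effects or EffectConfig()
    level = _LEVEL[label]
    subj_idx = _subject_index(subject_id)

    subj_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), subj_idx]))
    baseline = float(np.clip(
        subj_rng.normal(effects.baseline_bpm_mean, effects.baseline_bpm_sd),
        45.0, 160.0))
    geom_scale = subj_rng.uniform(0.85, 1.0)

    sess_seq = np.random.SeedSequence([int(seed), subj_idx, level, int(rep)])
    sess_rng = np.random.default_rng(sess_seq)
    ecg_seed = int(sess_rng.integers(0, 2**31 - 1))

    n_seconds = int(np.floor(spec.window_s))
    bpm = np.full(max(n_seconds, 1), baseline + level * effects.bpm_per_level)
    ecg = synth_ecg(bpm, spec.fs, spec.window_s,
                    noise_sd=effects.ecg_noise_sd, seed=ecg_seed)

    f = spec.n_frames
    half = frame_size // 2
    geom = {
        "cx": half + sess_rng.integers(-8, 9),
        "cy": half + sess_rng.integers(-8, 9),
        "rx": int(0.62 * half * geom_scale),
        "ry": int(0.82 * half * geom_scale),
    }
    amp = level * effects.deform_px_per_level * frame_size / 448.0
    frames = np.empty((f, frame_size, frame_size, 3), dtype=np.uint8)
    for k in range(f):
        ramp = 0.3 + 0.7 * (k / (f - 1) if f > 1 else 1.0)
        frame = _draw_face(frame_size, amp * ramp, geom).astype(np.float64)
        if effects.frame_noise_sd > 0:
            frame += sess_rng.normal(0.0, effects.frame_noise_sd, frame.shape)
        frames[k] = np.clip(frame, 0, 255).astype(np.uint8)
    return SyntheticSession(frames=frames, ecg=ecg, label=label,
                            subject_id=str(subject_id))


def _subject_index(subject_id) -> int:
    s = str(subject_id)
    digits = "".join(ch for ch in s if ch.isdigit())
    if digits:
        return int(digits) % (2**31 - 1)
    return sum(ord(c) for c in s) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Dataset-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionRecord:
    """Lazy handle for one session of the protocol manifest."""

    subject_id: str
    session_index: int
    label: str
    rep: int
    seed: int


def synth_dataset(spec: ProtocolSpec, effects: EffectConfig | None = None,
                  out_dir: str | Path | None = None,
                  ) -> tuple[pd.DataFrame, list[SessionRecord]]:
    """Lay out the full balanced protocol as a manifest of session records.

    Per subject: ``n_baseline`` NP sessions and ``reps_per_level`` sessions
    at each pain level, in a randomized per-subject order.  Sessions are
    represented lazily (build with :func:`build_session`); if ``out_dir`` is
    given every session is materialized to disk (PNG frames + ECG CSV) and
    the manifest gains path columns.
    """
    effects = effects or EffectConfig()
    records: list[SessionRecord] = []
    rows = []
    for s in range(spec.n_subjects):
        subject_id = f"S{s + 1:03d}"
        labels = ["NP"] * spec.n_baseline
        for lv in range(1, spec.n_pain_levels + 1):
            labels += [LABELS[lv]] * spec.reps_per_level
        order_rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), _subject_index(subject_id), 777]))
        order_rng.shuffle(labels)
        rep_counter: dict[str, int] = {}
        for sess_idx, lab in enumerate(labels):
            rep = rep_counter.get(lab, 0)
            rep_counter[lab] = rep + 1
            rec = SessionRecord(subject_id=subject_id, session_index=sess_idx,
                                label=lab, rep=rep, seed=spec.seed)
            records.append(rec)
            rows.append({"subject": subject_id, "session": sess_idx,
                         "label": lab, "video_dir": "", "ecg_path": ""})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(records):
            session = build_session(rec, spec, effects)
            vdir, epath = write_session(session, out_dir, rec)
            manifest.loc[i, "video_dir"] = str(vdir)
            manifest.loc[i, "ecg_path"] = str(epath)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, records


def build_session(record: SessionRecord, spec: ProtocolSpec,
                  effects: EffectConfig | None = None,
                  frame_size: int = 448) -> SyntheticSession:
    return synth_session(record.subject_id, record.label, spec,
                         seed=record.seed, effects=effects, rep=record.rep,
                         frame_size=frame_size)


def write_session(session: SyntheticSession, out_dir: Path,
                  record: SessionRecord) -> tuple[Path, Path]:
    """Write frames as zero-padded PNGs and ECG as two-column CSV."""
    vdir = Path(out_dir) / session.subject_id / f"sess{record.session_index:04d}"
    vdir.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(session.frames):
        Image.fromarray(frame).save(vdir / f"frame{k:05d}.png")
    epath = vdir / "ecg.csv"
    pd.DataFrame({
        "sample_index": np.arange(len(session.ecg.samples)),
        "amplitude": session.ecg.samples,
    }).to_csv(epath, index=False)
    return vdir, epath
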