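"""Face cropping and tile decomposition of video frames.

The face region is cropped (highest-confidence detector box, expanded to a
square) and resized to 448x448 with **no alignment** — head movement is a
behavioural pain cue and de-rotating the face would erase it.  Each crop is
then decomposed into four disjoint 224x224 quadrant tiles plus a bicubic
224x224 resize of the whole crop, giving five images per frame.

The face detector is a pluggable interface (boxes + confidences); a
passthrough detector that returns the whole frame serves pre-cropped or
synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from PIL import Image

from .resample import bicubic_resize

__all__ = [
    "FaceCrop",
    "TileSet",
    "FaceDetector",
    "PassthroughDetector",
    "NoFaceError",
    "detect_and_crop",
    "make_tileset",
    "crop_session",
    "load_frame_dir",
]

CROP_SIZE = 448
TILE_SIZE = 224


class NoFaceError(RuntimeError):
    def __init__(self, frame_index: int):
        super().__init__(f"no face detected in frame {frame_index}")
        self.frame_index = frame_index


@dataclass
class FaceCrop:
    image: np.ndarray            # (448, 448, 3)
    source_frame_index: int = 0

    def __post_init__(self):
        if self.image.shape[:2] != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"face crop must be {CROP_SIZE}x{CROP_SIZE}")


@dataclass
class TileSet:
    """Resized full crop + 4 quadrants (TL, TR, BL, BR), each 224x224x3."""

    full: np.ndarray
    tiles: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

    @property
    def images(self) -> list[np.ndarray]:
        return [self.full, *self.tiles]


class FaceDetector(Protocol):
    def detect(self, frame: np.ndarray) -> list[tuple[tuple[int, int, int, int], float]]:
        """Return [(box=(x0, y0, x1, y1), confidence), ...]; may be empty."""


class PassthroughDetector:
    """Reports the whole frame as a single full-confidence face box."""

    def detect(self, frame: np.ndarray):
        h, w = frame.shape[:2]
        return [((0, 0, w, h), 1.0)]


def detect_and_crop(frame: np.ndarray, detector: FaceDetector,
                    frame_index: int = 0) -> FaceCrop:
    """Crop the highest-confidence face box, square-expanded, to 448x448.

    No rotation or landmark alignment is applied: the output orientation
    always equals the input orientation.
    """
    boxes = detector.detect(frame)
    if not boxes:
        raise NoFaceError(frame_index)
    (x0, y0, x1, y1), _ = max(boxes, key=lambda b: b[1])
    h, w = frame.shape[:2]
    side = min(max(x1 - x0, y1 - y0), h, w)
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    sx0 = int(round(cx - side / 2.0))
    sy0 = int(round(cy - side / 2.0))
    sx0 = int(np.clip(sx0, 0, max(w - side, 0)))
    sy0 = int(np.clip(sy0, 0, max(h - side, 0)))
    square = frame[sy0: sy0 + side, sx0: sx0 + side]
    if square.shape[:2] != (CROP_SIZE, CROP_SIZE):
        square = bicubic_resize(square.astype(np.float64), CROP_SIZE, CROP_SIZE)
        square = np.clip(square, 0, 255)
    return FaceCrop(image=np.ascontiguousarray(square.astype(frame.dtype)
                                               if frame.dtype == np.uint8
                                               else square),
                    source_frame_index=frame_index)


def make_tileset(crop: FaceCrop) -> TileSet:
    """Decompose a 448x448 crop into 4 quadrants and a resized full image.

    Quadrant order is TL, TR, BL, BR with half-open pixel ranges, so the four
    tiles reassemble the crop exactly.
    """
    img = crop.image
    if img.shape[:2] != (CROP_SIZE, CROP_SIZE):
        raise ValueError(f"expected a {CROP_SIZE}x{CROP_SIZE} crop")
    t = TILE_SIZE
    tiles = (img[:t, :t], img[:t, t:], img[t:, :t], img[t:, t:])
    full = bicubic_resize(img.astype(np.float64), t, t)
    if img.dtype == np.uint8:
        full = np.clip(full, 0, 255)
    return TileSet(full=full, tiles=tiles)


def crop_session(frames: Sequence[np.ndarray], detector: FaceDetector,
                 ) -> list[FaceCrop]:
    """Crop every frame, reusing the last successful box on a miss.

    The session fails only if no frame yields a detection.
    """
    crops: list[FaceCrop] = []
    last_good: FaceCrop | None = None
    pending = 0
    for k, frame in enumerate(frames):
        try:
            crop = detect_and_crop(frame, detector, frame_index=k)
        except NoFaceError:
            if last_good is None:
                pending += 1
                continue
            crop = FaceCrop(image=last_good.image, source_frame_index=k)
        crops.append(crop)
        if pending:  # backfill leading misses with the first success
            crops = [FaceCrop(image=crop.image, source_frame_index=j)
                     for j in range(pending)] + crops
            pending = 0
        last_good = crop
    if not crops:
        raise NoFaceError(0)
    return crops


def load_frame_dir(path: str | Path) -> list[np.ndarray]:
    """Load a session directory of PNG frames in filename order."""
    files = sorted(Path(path).glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG frames under {path}")
    return [np.asarray(Image.open(f).convert("RGB")) for f in files]
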