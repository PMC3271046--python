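"""Synthetic endoscopy-like frames and scripted videos with ground truth.

The generator emulates what the detectors key on, not anatomy: a bright,
vignetted airway-wall texture with rich mid/high-frequency content (band-pass
filtered noise standing in for mucosal texture) surrounding one or more
near-black lumen disks, plus Gaussian-blurred counterparts standing in for
motion/defocus "non-informative" frames.  Everything is deterministic under
(seed, script), so fixtures regenerate bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .frame_io import (
    AnnotationEntry,
    AnnotationSet,
    ArrayVideoSource,
    Frame,
    VideoSource,
)

__all__ = [
    "GenerationError",
    "SceneSegment",
    "SceneScript",
    "SEGMENT_KINDS",
    "make_informative_frame",
    "make_noninformative_frame",
    "make_video",
    "SyntheticVideo",
]

SEGMENT_KINDS = ("sharp_single_lumen", "sharp_bifurcation", "blurred", "lesion_tagged")


class GenerationError(RuntimeError):
    """Raised when a requested frame geometry cannot be placed."""


@dataclass(frozen=True)
class SceneSegment:
    duration_frames: int
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_frames < 1:
            raise ValueError("segment duration must be at least 1 frame")
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")


@dataclass(frozen=True)
class SceneScript:
    """Ordered scene segments plus fps and the seed fixing all randomness."""

    segments: tuple[SceneSegment, ...]
    fps: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("script needs at least one segment")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def frame_count(self) -> int:
        return sum(s.duration_frames for s in self.segments)


def _place_lumina(
    rng: np.random.Generator, size: int, n_lumina: int
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping lumen disks; (row, col, radius)."""
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_lumina):
        ok = False
        for _attempt in range(200):
            r = rng.uniform(0.10, 0.14) * size
            margin = r + 2
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            # centres far enough apart that edges stay >= 1 radius clear
            if all(
                np.hypot(cy - py, cx - px) >= r + pr + max(r, pr)
                for py, px, pr in placed
            ):
                placed.append((cy, cx, r))
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place {n_lumina} lumina in a {size}x{size} frame"
            )
    return placed


def make_informative_frame(
    seed: int, size: int = 256, n_lumina: int = 1
) -> tuple[Frame, list[tuple[float, float, float]]]:
    """Generate a sharp endoscopy-like frame with ``n_lumina`` dark lumina.

    Returns the frame and the lumen geometry as ground truth, a list of
    (row, col, radius) disks.  The wall is bright band-limited noise with a
    radial vignette; lumen interiors have luminance <= 20 and radius
    >= 0.1 * size, pairwise separated by at least one disk radius.
    """
    if size < 64:
        raise ValueError("size must be at least 64")
    if n_lumina not in (1, 2, 3):
        raise ValueError("n_lumina must be 1, 2 or 3")
    rng = np.random.default_rng(seed)

    noise = rng.standard_normal((size, size))
    # band-pass: difference of Gaussians keeps mid/high-frequency texture
    band = ndimage.gaussian_filter(noise, 0.6) - ndimage.gaussian_filter(noise, 4.0)
    band /= band.std()
    wall = 175.0 + 28.0 * band

    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r_norm = np.hypot(yy - cy, xx - cx) / (size / 2.0)
    vignette = 1.0 - 0.22 * np.clip(r_norm, 0.0, np.sqrt(2.0)) ** 2
    img = wall * vignette

    lumina = _place_lumina(rng, size, n_lumina)
    for ly, lx, lr in lumina:
        mask = np.hypot(yy - ly, xx - lx) <= lr
        img[mask] = rng.uniform(0.0, 15.0, size=int(mask.sum()))

    return Frame(np.clip(img, 0.0, 255.0)), lumina


def make_noninformative_frame(base: Frame, sigma: float) -> Frame:
    """Gaussian-blur a frame into a non-informative counterpart.

    Reflected boundary handling; ``sigma`` of at least 2 (gross blur well
    beyond focus jitter, matching out-of-focus or motion-smeared views).
    """
    if sigma < 2:
        raise ValueError("sigma must be at least 2")
    blurred = ndimage.gaussian_filter(base.pixels, sigma, mode="reflect")
    return Frame(np.clip(blurred, 0.0, 255.0))


@dataclass
class FrameTruth:
    informative: bool
    branching: bool
    lesion: bool = False


class SyntheticVideo(VideoSource):
    """Lazily rendered scripted video; frame ``i`` is generated on access."""

    def __init__(self, script: SceneScript, size: int = 256):
        self.script = script
        self.size = size
        self.fps = script.fps
        self.frame_count = script.frame_count
        self._plan: list[tuple[str, int, float]] = []  # (kind, frame_seed, sigma)
        self.truth: list[FrameTruth] = []
        rng = np.random.default_rng(script.seed)
        annotations: list[AnnotationEntry] = []
        offset = 0
        for seg in script.segments:
            seg_seeds = rng.integers(0, 2**31 - 1, size=seg.duration_frames)
            sigma = float(seg.params.get("sigma", rng.uniform(6.0, 12.0)))
            for j in range(seg.duration_frames):
                self._plan.append((seg.kind, int(seg_seeds[j]), sigma))
                self.truth.append(
                    FrameTruth(
                        informative=seg.kind != "blurred",
                        branching=seg.kind == "sharp_bifurcation",
                        lesion=seg.kind == "lesion_tagged",
                    )
                )
            if seg.kind == "lesion_tagged":
                centre = offset + seg.duration_frames // 2
                annotations.append(
                    AnnotationEntry(centre, "lesion", seg.params.get("label", "lesion"))
                )
            offset += seg.duration_frames
        self.annotations = AnnotationSet(entries=annotations, fps=script.fps)

    def get_frame(self, index: int) -> Frame:
        kind, fseed, sigma = self._plan[index]
        if kind == "sharp_bifurcation":
            frame, _ = make_informative_frame(fseed, self.size, n_lumina=2)
        else:
            frame, _ = make_informative_frame(fseed, self.size, n_lumina=1)
        if kind == "blurred":
            frame = make_noninformative_frame(frame, sigma)
        return frame

    def materialize(self) -> ArrayVideoSource:
        return ArrayVideoSource(list(self), fps=self.fps)


def make_video(script: SceneScript, size: int = 256) -> tuple[SyntheticVideo, list[FrameTruth], AnnotationSet]:
    """Render a scripted video with per-frame ground truth.

    Blurred segments are marked non-informative, bifurcation segments
    branching, and each lesion_tagged segment carries one lesion annotation
    at its central frame.
    """
    video = SyntheticVideo(script, size=size)
    return video, video.truth, video.annotations
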