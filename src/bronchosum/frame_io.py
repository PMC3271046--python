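"""Frame, video and annotation I/O.

Frames are 2-D luminance matrices on the 0-255 scale; videos are random-access
frame sources (image-sequence directories, container files via imageio, or
in-memory arrays); annotations and edit decision lists round-trip through JSON.
All frame indices are 0-based and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Frame",
    "VideoSource",
    "ArrayVideoSource",
    "ImageSequenceSource",
    "AnnotationSet",
    "AnnotationEntry",
    "TAG_CLASSES",
    "to_luminance",
    "read_video",
    "write_image_sequence",
    "load_annotations",
    "save_annotations",
]

#: Valid annotation tag classes: manually introduced treatment markers,
#: physician annotations, and (automatically detected) lesion tags.
TAG_CLASSES = ("marker", "annotation", "lesion")

# ITU-R BT.601 luma weights.
_BT601 = np.array([0.299, 0.587, 0.114])

DEFAULT_FPS = 25.0  # PAL-region clinical recording default


@dataclass(frozen=True)
class Frame:
    """A single video frame as a 2-D luminance matrix (0-255 scale)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"Frame pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"Frame must be at least 8x8, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("Frame values must lie within [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def to_luminance(rgb_frame: np.ndarray) -> Frame:
    """Convert a 3-channel RGB image (0-255) to a luminance :class:`Frame`.

    Uses ITU-R BT.601 luma weights (0.299 R + 0.587 G + 0.114 B); hue and
    saturation are discarded, only luminance is retained.
    """
    rgb = np.asarray(rgb_frame, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(
            f"Expected an HxWx3 RGB array, got shape {np.shape(rgb_frame)}"
        )
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB values must lie within [0, 255]")
    luma = rgb @ _BT601
    return Frame(np.clip(luma, 0.0, 255.0))


class VideoSource:
    """Random-access sequence of constant-size frames with a frame rate."""

    frame_count: int
    fps: float

    def get_frame(self, index: int) -> Frame:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def duration_seconds(self) -> float:
        return self.frame_count / self.fps

    def __len__(self) -> int:
        return self.frame_count

    def __getitem__(self, index: int) -> Frame:
        if index < 0:
            index += self.frame_count
        if not 0 <= index < self.frame_count:
            raise IndexError(f"frame index {index} out of range")
        return self.get_frame(index)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.frame_count):
            yield self.get_frame(i)


class ArrayVideoSource(VideoSource):
    """In-memory video backed by a list of equally sized frames."""

    def __init__(self, frames: Sequence[Frame], fps: float = DEFAULT_FPS):
        if len(frames) < 1:
            raise ValueError("a video needs at least one frame")
        if fps <= 0:
            raise ValueError("fps must be positive")
        shape = frames[0].pixels.shape
        for i, f in enumerate(frames):
            if f.pixels.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {f.pixels.shape}, expected {shape}"
                )
        self._frames = list(frames)
        self.frame_count = len(frames)
        self.fps = float(fps)

    def get_frame(self, index: int) -> Frame:
        return self._frames[index]


class ImageSequenceSource(VideoSource):
    """Video backed by a directory of numbered PNG/JPEG frames."""

    def __init__(self, paths: Sequence[Path], fps: float = DEFAULT_FPS):
        import imageio.v3 as iio

        if not paths:
            raise IOError("image sequence is empty")
        if fps <= 0:
            raise ValueError("fps must be positive")
        self._paths = list(paths)
        self._iio = iio
        self.frame_count = len(paths)
        self.fps = float(fps)
        first = self._load(0)
        self._shape = first.pixels.shape
        # Eagerly validate dimensional consistency so errors name the frame.
        for i in range(1, self.frame_count):
            shape = self._probe_shape(i)
            if shape != self._shape:
                raise IOError(
                    f"frame {i} ({self._paths[i].name}) has size {shape}, "
                    f"expected {self._shape}"
                )

    def _probe_shape(self, index: int) -> tuple[int, int]:
        return self._load(index).pixels.shape

    def _load(self, index: int) -> Frame:
        img = np.asarray(self._iio.imread(self._paths[index]))
        if img.ndim == 3:
            if img.shape[2] == 4:  # drop alpha
                img = img[:, :, :3]
            return to_luminance(img)
        return Frame(img)

    def get_frame(self, index: int) -> Frame:
        return self._load(index)


class _ContainerSource(VideoSource):
    """Video container file decoded through imageio (when a backend exists)."""

    def __init__(self, path: Path, fps: float | None = None):
        import imageio.v3 as iio

        try:
            frames = iio.imread(path, index=None)
            meta = iio.immeta(path)
        except Exception as exc:  # no plugin / corrupt file
            raise IOError(f"cannot decode video container {path}: {exc}") from exc
        frames = np.asarray(frames)
        if frames.ndim == 3 and frames.shape[-1] in (3, 4):
            frames = frames[None]  # single RGB frame
        if frames.shape[0] < 1:
            raise IOError(f"no decodable frames in {path}")
        if fps is None:
            fps = float(meta.get("fps", DEFAULT_FPS))
        converted = []
        for img in frames:
            if img.ndim == 3:
                converted.append(to_luminance(img[:, :, :3]))
            else:
                converted.append(Frame(img))
        self._inner = ArrayVideoSource(converted, fps=fps)
        self.frame_count = self._inner.frame_count
        self.fps = self._inner.fps

    def get_frame(self, index: int) -> Frame:
        return self._inner.get_frame(index)


_FRAME_FILE_RE = re.compile(r".*\.(png|jpg|jpeg)$", re.IGNORECASE)


def read_video(path: str | Path, fps: float | None = None) -> VideoSource:
    """Open a video from an image-sequence directory or a container file.

    For image sequences, frames are the directory's PNG/JPEG files in
    lexicographic order and ``fps`` defaults to 25 when not given; for
    container files the frame rate comes from the container metadata.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video source does not exist: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if _FRAME_FILE_RE.match(p.name))
        if not files:
            raise IOError(f"no image frames found in directory {path}")
        return ImageSequenceSource(files, fps=fps if fps is not None else DEFAULT_FPS)
    return _ContainerSource(path, fps=fps)


def write_image_sequence(frames: Sequence[Frame], out_dir: str | Path) -> list[Path]:
    """Write frames as ``frame_%06d.png`` greyscale files under ``out_dir``."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:06d}.png"
        iio.imwrite(p, np.clip(np.round(frame.pixels), 0, 255).astype(np.uint8))
        paths.append(p)
    return paths


@dataclass(frozen=True)
class AnnotationEntry:
    frame_index: int
    tag_class: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.tag_class not in TAG_CLASSES:
            raise ValueError(
                f"unknown tag_class {self.tag_class!r}; expected one of {TAG_CLASSES}"
            )
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")


@dataclass
class AnnotationSet:
    """Frame-indexed markers, physician annotations and lesion tags."""

    entries: list[AnnotationEntry] = field(default_factory=list)
    fps: float = DEFAULT_FPS

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, frame_count: int) -> None:
        for i, e in enumerate(self.entries):
            if e.frame_index >= frame_count:
                raise ValueError(
                    f"annotation entry {i}: frame {e.frame_index} is out of "
                    f"range for a {frame_count}-frame video"
                )


def load_annotations(path: str | Path) -> AnnotationSet:
    """Load an annotation JSON file.

    Schema: ``{"fps": float, "entries": [{"frame": int, "class": str,
    "label": str}]}`` with ``class`` in {marker, annotation, lesion}.
    """
    with open(path) as fh:
        doc = json.load(fh)
    entries = []
    for i, raw in enumerate(doc.get("entries", [])):
        try:
            entries.append(
                AnnotationEntry(
                    frame_index=int(raw["frame"]),
                    tag_class=str(raw["class"]),
                    label=str(raw.get("label", "")),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"annotation entry {i}: {exc}") from exc
    return AnnotationSet(entries=entries, fps=float(doc.get("fps", DEFAULT_FPS)))


def save_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    doc = {
        "fps": annotations.fps,
        "entries": [
            {"frame": e.frame_index, "class": e.tag_class, "label": e.label}
            for e in annotations.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
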