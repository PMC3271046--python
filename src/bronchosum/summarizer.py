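"""Summary assembly: per-frame labels -> prioritized shots -> budgeted EDL.

The summary keeps shots built from inclusion criteria (physician annotations,
treatment markers, lesion tags, airway-branching views, and representative
samples of the informative material in between) and drops frames tagged with
the exclusion criterion (non-informative).  The target length follows the
"about twelve times shorter" rule — one minute of source maps to five seconds
of summary — with a 30-second floor, capped at the source length.

Priority order is annotation > marker > lesion > branching > representative:
explicit physician input outranks automatic detections.  All selection is
deterministic, so identical inputs always yield identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .frame_io import AnnotationSet, Frame, VideoSource, write_image_sequence

__all__ = [
    "PRIORITY_ORDER",
    "FrameLabelTrack",
    "Shot",
    "SummaryConfig",
    "EditDecisionList",
    "compute_budget",
    "build_shots",
    "select_shots",
    "summarize",
    "render_summary",
    "save_edl",
    "load_edl",
]

logger = logging.getLogger(__name__)

#: Shot priority classes, highest first.
PRIORITY_ORDER = ("annotation", "marker", "lesion", "branching", "representative")
_TAGGED_CLASSES = ("annotation", "marker", "lesion", "branching")


@dataclass
class FrameLabelTrack:
    """Per-frame labels feeding the summarizer.

    Boolean arrays of equal length: the informative flag (exclusion
    criterion when False), the branching flag, and one array per tag class.
    """

    informative: np.ndarray
    branching: np.ndarray
    annotation: np.ndarray
    marker: np.ndarray
    lesion: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("informative", "branching", "annotation", "marker", "lesion"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be a 1-D boolean array")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError(
                    f"label track length mismatch: {name} has {arr.size} "
                    f"entries, expected {n}"
                )
            arrays[name] = arr
        for name, arr in arrays.items():
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.informative.size

    @classmethod
    def empty(cls, n: int) -> "FrameLabelTrack":
        z = np.zeros(n, dtype=bool)
        return cls(np.ones(n, dtype=bool), z.copy(), z.copy(), z.copy(), z.copy())

    @classmethod
    def assemble(
        cls,
        informative: Sequence[bool],
        branching: Sequence[bool],
        annotations: AnnotationSet | None = None,
    ) -> "FrameLabelTrack":
        """Merge detector outputs and an annotation set into one track."""
        inf = np.asarray(informative, dtype=bool)
        n = inf.size
        track = cls(
            inf,
            np.asarray(branching, dtype=bool),
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=bool),
        )
        if annotations is not None:
            annotations.validate_against(n)
            for e in annotations.entries:
                getattr(track, e.tag_class)[e.frame_index] = True
        return track

    def class_mask(self, priority: str) -> np.ndarray:
        if priority == "branching":
            return self.branching
        return getattr(self, priority)


@dataclass(frozen=True)
class Shot:
    """Half-open frame interval [start, end) with a priority class."""

    start: int
    end: int
    priority: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid shot interval [{self.start}, {self.end})")
        if self.priority not in PRIORITY_ORDER:
            raise ValueError(f"unknown priority {self.priority!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SummaryConfig:
    """Summary length and shot-shaping parameters.

    ratio
        Source-to-summary duration divisor (default 12: one minute of source
        per five seconds of summary).
    min_summary_seconds
        Summary floor in seconds (default 30), capped at the source length.
    pad_frames
        Context padding added around tagged frames (default 12, about half a
        second at 25 fps); padding never resurrects non-informative frames.
    merge_gap_frames
        Adjacent same-priority runs separated by fewer than this many frames
        merge into one shot (default 12), provided the gap is informative.
    lesion_core_seconds
        Lesion shots longer than this are thinned to their central stretch
        before budgeting when the priority material exceeds the budget.
    """

    ratio: float = 12.0
    min_summary_seconds: float = 30.0
    pad_frames: int = 12
    merge_gap_frames: int = 12
    lesion_core_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.ratio <= 1:
            raise ValueError("ratio must exceed 1")
        if self.min_summary_seconds <= 0:
            raise ValueError("min_summary_seconds must be positive")
        if self.pad_frames < 0 or self.merge_gap_frames < 0:
            raise ValueError("pad_frames and merge_gap_frames must be >= 0")


@dataclass
class EditDecisionList:
    """Ordered, pairwise-disjoint shots plus source timing metadata."""

    shots: list[Shot]
    fps: float
    frame_count: int

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.frame_count < 0:
            raise ValueError("invalid EDL metadata")
        prev_end = 0
        for s in self.shots:
            if s.start < prev_end:
                raise ValueError("EDL shots must be sorted and disjoint")
            if s.end > self.frame_count:
                raise ValueError(
                    f"shot [{s.start}, {s.end}) exceeds frame_count {self.frame_count}"
                )
            prev_end = s.end

    @property
    def total_frames(self) -> int:
        return sum(len(s) for s in self.shots)

    @property
    def duration_seconds(self) -> float:
        return self.total_frames / self.fps

    def frame_indices(self) -> list[int]:
        out: list[int] = []
        for s in self.shots:
            out.extend(range(s.start, s.end))
        return out


def compute_budget(frame_count: int, fps: float, config: SummaryConfig) -> int:
    """Summary length budget in frames.

    ``round(max(frame_count / ratio, min(min_summary_seconds * fps,
    frame_count)))`` — the twelve-fold reduction with a 30-second floor that
    can never exceed the source length.
    """
    floor = min(config.min_summary_seconds * fps, frame_count)
    return int(round(max(frame_count / config.ratio, floor)))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def _pad_run(
    start: int, end: int, pad: int, informative: np.ndarray
) -> tuple[int, int]:
    """Extend a run by up to ``pad`` frames each side through informative
    frames only (padding never resurrects non-informative frames)."""
    n = informative.size
    left = start
    while left > 0 and start - left < pad and informative[left - 1]:
        left -= 1
    right = end
    while right < n and right - end < pad and informative[right]:
        right += 1
    return left, right


def build_shots(track: FrameLabelTrack, config: SummaryConfig) -> list[Shot]:
    """Turn the label track into disjoint prioritized shots.

    Non-informative frames are removed from candidacy.  For each tag class,
    maximal tagged runs are padded by ``pad_frames`` (through informative
    frames only) and runs separated by an informative gap shorter than
    ``merge_gap_frames`` are merged.  Each frame then takes its single
    highest-priority class (annotation > marker > lesion > branching), and
    the untagged informative stretches left over become representative
    segments.
    """
    n = len(track)
    inf = track.informative
    class_masks: dict[str, np.ndarray] = {}
    for cls in _TAGGED_CLASSES:
        base = track.class_mask(cls) & inf
        mask = np.zeros(n, dtype=bool)
        intervals = [
            _pad_run(s, e, config.pad_frames, inf) for s, e in _runs(base)
        ]
        for i, (s, e) in enumerate(intervals):
            mask[s:e] = True
            if i > 0:
                ps, pe = intervals[i - 1]
                gap = s - pe
                if 0 < gap < config.merge_gap_frames and inf[pe:s].all():
                    mask[pe:s] = True
        class_masks[cls] = mask

    assignment = np.full(n, -1, dtype=np.int8)
    for rank, cls in enumerate(_TAGGED_CLASSES):
        free = assignment < 0
        assignment[class_masks[cls] & free] = rank

    representative = inf & (assignment < 0)
    assignment[representative] = len(_TAGGED_CLASSES)

    shots: list[Shot] = []
    classes = _TAGGED_CLASSES + ("representative",)
    for rank, cls in enumerate(classes):
        for s, e in _runs(assignment == rank):
            shots.append(Shot(s, e, cls))
    shots.sort(key=lambda s: s.start)
    return shots


def _central_subinterval(shot: Shot, length: int) -> Shot:
    start = shot.start + (len(shot) - length) // 2
    return Shot(start, start + length, shot.priority)


def select_shots(
    shots: Sequence[Shot],
    budget: int,
    fps: float,
    config: SummaryConfig,
    frame_count: int | None = None,
) -> EditDecisionList:
    """Admit shots into the budget by priority and emit the EDL.

    Priority classes are admitted in order (annotation, marker, lesion,
    branching), shots within a class in temporal order; a shot that would
    overflow the budget is truncated symmetrically about its centre and
    admission stops.  Leftover budget is spread over the representative
    segments by deterministic centred subsampling, proportional to segment
    length with a one-frame minimum per segment while budget allows.
    """
    shots = sorted(shots, key=lambda s: s.start)
    if frame_count is None:
        frame_count = max((s.end for s in shots), default=0)
    prev = 0
    for s in shots:
        if s.start < prev:
            raise ValueError("input shots must be disjoint")
        prev = s.end

    rank = {cls: i for i, cls in enumerate(PRIORITY_ORDER)}
    priority_shots = [s for s in shots if s.priority != "representative"]
    rep_segments = [s for s in shots if s.priority == "representative"]

    # Lesion thinning: when the priority material alone exceeds the budget,
    # long lesion shots are reduced to their central core before admission.
    if sum(len(s) for s in priority_shots) > budget:
        core = max(1, int(round(config.lesion_core_seconds * fps)))
        priority_shots = [
            _central_subinterval(s, core)
            if s.priority == "lesion" and len(s) > core
            else s
            for s in priority_shots
        ]

    priority_shots.sort(key=lambda s: (rank[s.priority], s.start))
    selected: list[Shot] = []
    remaining = budget
    for s in priority_shots:
        if remaining <= 0:
            break
        if len(s) <= remaining:
            selected.append(s)
            remaining -= len(s)
        else:
            selected.append(_central_subinterval(s, remaining))
            remaining = 0

    if remaining > 0 and rep_segments:
        total = sum(len(s) for s in rep_segments)
        if total <= remaining:
            selected.extend(rep_segments)
            remaining -= total
        else:
            quota = remaining
            allocs: list[int] = []
            for s in rep_segments:
                share = (quota * len(s)) // total
                a = min(len(s), max(1, share), remaining)
                allocs.append(a)
                remaining -= a
            for i, s in enumerate(rep_segments):  # top up to fill the budget
                if remaining <= 0:
                    break
                extra = min(len(s) - allocs[i], remaining)
                allocs[i] += extra
                remaining -= extra
            selected.extend(
                _central_subinterval(s, a)
                for s, a in zip(rep_segments, allocs)
                if a > 0
            )

    selected.sort(key=lambda s: s.start)
    return EditDecisionList(shots=selected, fps=fps, frame_count=frame_count)


def summarize(
    video: VideoSource,
    annotations: AnnotationSet | None,
    dct_model,
    branch_params,
    config: SummaryConfig | None = None,
    keep_noninformative: bool = False,
) -> EditDecisionList:
    """Full pipeline: classify, detect branching, build and budget shots.

    Non-informative frames are excluded from candidacy and never reach the
    branch detector (blur destroys the dark-region geometry); set
    ``keep_noninformative`` to bypass the exclusion criterion.
    """
    from .branch_detector import is_branching, segment_dark_regions
    from .dct_detector import INFORMATIVE, classify_frame, dct_nonzero_fraction

    config = config or SummaryConfig()
    n = video.frame_count
    informative = np.zeros(n, dtype=bool)
    branching = np.zeros(n, dtype=bool)
    for i in range(n):
        frame = video.get_frame(i)
        frac = dct_nonzero_fraction(frame, dct_model)
        informative[i] = classify_frame(frac, dct_model) == INFORMATIVE
        if informative[i]:
            branching[i] = is_branching(segment_dark_regions(frame, branch_params))
    logger.info(
        "classified %d frames: %d informative, %d branching",
        n, int(informative.sum()), int(branching.sum()),
    )
    if not informative.any() and not keep_noninformative:
        logger.warning("no informative frames found; summary will be empty")
    if keep_noninformative:
        informative[:] = True

    track = FrameLabelTrack.assemble(informative, branching, annotations)
    shots = build_shots(track, config)
    budget = compute_budget(n, video.fps, config)
    edl = select_shots(shots, budget, video.fps, config, frame_count=n)
    logger.info(
        "budget %d frames; selected %d shots totalling %d frames",
        budget, len(edl.shots), edl.total_frames,
    )
    return edl


def render_summary(
    video: VideoSource, edl: EditDecisionList, out_path: str | Path
) -> list[Path]:
    """Write the EDL's frames, in order, as a PNG image sequence."""
    indices = edl.frame_indices()
    if not indices:
        logger.warning("EDL is empty; writing no frames to %s", out_path)
        Path(out_path).mkdir(parents=True, exist_ok=True)
        return []
    frames = (video.get_frame(i) for i in indices)
    return write_image_sequence(list(frames), out_path)


def save_edl(edl: EditDecisionList, path: str | Path) -> None:
    """Persist an EDL as JSON, or CSV when the path ends in .csv."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        import pandas as pd

        pd.DataFrame(
            [{"start": s.start, "end": s.end, "priority": s.priority}
             for s in edl.shots]
        ).to_csv(path, index=False)
        return
    doc = {
        "fps": edl.fps,
        "frame_count": edl.frame_count,
        "shots": [
            {"start": s.start, "end": s.end, "priority": s.priority}
            for s in edl.shots
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_edl(path: str | Path) -> EditDecisionList:
    with open(path) as fh:
        doc = json.load(fh)
    shots = [
        Shot(int(s["start"]), int(s["end"]), str(s["priority"]))
        for s in doc["shots"]
    ]
    return EditDecisionList(
        shots=shots, fps=float(doc["fps"]), frame_count=int(doc["frame_count"])
    )
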