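"""Raw gaze samples -> AOI-coded scanpaths.

The pipeline is: sample-level confidence filtering, dispersion-threshold
fixation detection (IDT), duration filtering, and assignment of fixation
centroids to named areas of interest (AOIs).  Defaults follow common practice
for ~120 Hz screen-based eye tracking: dispersion threshold 50 px, minimum
fixation duration 100 ms, fixations longer than 1500 ms discarded, samples
with tracker confidence below 0.9 dropped.

Coordinates are screen pixels with the origin at the top-left corner, x
growing rightward and y downward.  AOI rectangles are half-open,
[x0, x1) x [y0, y1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GazeRecording",
    "Fixation",
    "AOIRegion",
    "AOILayout",
    "Scanpath",
    "TrialUnusableError",
    "filter_samples",
    "detect_fixations",
    "map_to_scanpath",
    "preprocess_recording",
    "two_halves_layout",
]


class TrialUnusableError(ValueError):
    """Raised when filtering leaves no usable samples in a trial."""


@dataclass(frozen=True)
class GazeRecording:
    """Time-stamped gaze samples for one trial.

    ``t`` is in seconds and strictly increasing; ``x``/``y`` are pixels;
    ``confidence`` is the tracker's per-sample quality in [0, 1].
    """

    participant_id: str
    trial_id: str
    condition: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "confidence"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if not (self.x.size == self.y.size == self.confidence.size == n):
            raise ValueError("sample arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if n and (self.confidence.min() < 0 or self.confidence.max() > 1):
            raise ValueError("confidence must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class Fixation:
    """One detected fixation: onset [s], duration [ms], centroid [px]."""

    onset: float
    duration: float
    centroid_x: float
    centroid_y: float


@dataclass(frozen=True)
class AOIRegion:
    symbol: int
    name: str
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1
    priority: int

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return (x0 <= x < x1) and (y0 <= y < y1)


@dataclass(frozen=True)
class AOILayout:
    """Ordered collection of AOI rectangles with precedence.

    When a point lies in several regions the one with the highest priority
    wins; this makes small target boxes nested inside screen halves
    unambiguous.  Symbols and priorities must be unique.
    """

    regions: tuple[AOIRegion, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if not self.regions:
            raise ValueError("layout must contain at least one region")
        symbols = [r.symbol for r in self.regions]
        priorities = [r.priority for r in self.regions]
        if len(set(symbols)) != len(symbols):
            raise ValueError("region symbols must be unique")
        if len(set(priorities)) != len(priorities):
            raise ValueError("region priorities must be unique")
        for r in self.regions:
            x0, y0, x1, y1 = r.rect
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"malformed rectangle for region {r.name!r}")

    @property
    def alphabet_size(self) -> int:
        return max(r.symbol for r in self.regions) + 1

    def assign(self, x: float, y: float) -> int | None:
        """Symbol of the highest-priority region containing (x, y), else None."""
        best: AOIRegion | None = None
        for r in self.regions:
            if r.contains(x, y) and (best is None or r.priority > best.priority):
                best = r
        return None if best is None else best.symbol


def two_halves_layout(
    screen_w: float,
    screen_h: float,
    target_left: tuple[float, float, float, float] | None = None,
    target_right: tuple[float, float, float, float] | None = None,
    frame: float = 50.0,
) -> AOILayout:
    """Four-AOI layout for side-by-side image-comparison stimuli.

    Left and right screen halves (symbols 0, 1) plus optional target boxes in
    each image (symbols 2, 3), each grown by ``frame`` pixels on every side.
    Target boxes outrank the halves they sit in.
    """
    regions = [
        AOIRegion(0, "left_half", (0.0, 0.0, screen_w / 2.0, screen_h), priority=0),
        AOIRegion(1, "right_half", (screen_w / 2.0, 0.0, screen_w, screen_h), priority=1),
    ]
    for sym, name, rect in ((2, "target_left", target_left), (3, "target_right", target_right)):
        if rect is not None:
            x0, y0, x1, y1 = rect
            regions.append(
                AOIRegion(sym, name, (x0 - frame, y0 - frame, x1 + frame, y1 + frame), priority=sym)
            )
    return AOILayout(regions=tuple(regions))


@dataclass(frozen=True)
class Scanpath:
    """Ordered AOI symbol sequence for one trial.

    Symbols are integer codes in ``[0, alphabet_size)``; the sequence is the
    realization (x_1, ..., x_N) of the discrete fixation process.
    """

    symbols: np.ndarray
    alphabet_size: int
    participant_id: str = ""
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "symbols", np.asarray(self.symbols, dtype=np.int64)
        )
        if self.symbols.ndim != 1 or self.symbols.size < 1:
            raise ValueError("scanpath must be a non-empty 1-D symbol sequence")
        if self.symbols.min() < 0 or self.symbols.max() >= self.alphabet_size:
            raise ValueError("symbols must lie in [0, alphabet_size)")

    def __len__(self) -> int:
        return int(self.symbols.size)


# ---------------------------------------------------------------------------
# operations


def filter_samples(rec: GazeRecording, min_confidence: float = 0.9) -> GazeRecording:
    """Drop samples below the confidence threshold, preserving order."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    keep = rec.confidence >= min_confidence
    if not keep.any():
        raise TrialUnusableError(
            f"trial {rec.trial_id!r}: no samples with confidence >= {min_confidence}"
        )
    return replace(
        rec, t=rec.t[keep], x=rec.x[keep], y=rec.y[keep], confidence=rec.confidence[keep]
    )


def _dispersion(x: np.ndarray, y: np.ndarray, lo: int, hi: int) -> float:
    """Window dispersion = x-range + y-range over samples lo..hi inclusive."""
    xs = x[lo : hi + 1]
    ys = y[lo : hi + 1]
    return float((xs.max() - xs.min()) + (ys.max() - ys.min()))


def _idt_segment(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    max_dispersion: float,
    min_duration_s: float,
) -> list[Fixation]:
    fixations: list[Fixation] = []
    n = t.size
    i = 0
    while i < n:
        # smallest window starting at i spanning >= min_duration
        j = i
        while j < n and t[j] - t[i] < min_duration_s:
            j += 1
        if j >= n:
            break  # trailing window never reaches the duration threshold
        if _dispersion(x, y, i, j) <= max_dispersion:
            while j + 1 < n and _dispersion(x, y, i, j + 1) <= max_dispersion:
                j += 1
            fixations.append(
                Fixation(
                    onset=float(t[i]),
                    duration=float((t[j] - t[i]) * 1000.0),
                    centroid_x=float(x[i : j + 1].mean()),
                    centroid_y=float(y[i : j + 1].mean()),
                )
            )
            i = j + 1
        else:
            i += 1
    return fixations


def detect_fixations(
    rec: GazeRecording,
    max_dispersion: float = 50.0,
    min_duration: float = 100.0,
    max_duration: float = 1500.0,
    gap_factor: float = 2.0,
) -> list[Fixation]:
    """Dispersion-threshold (IDT) fixation detection.

    A window is grown from the current sample while its dispersion
    (x-range + y-range) stays within ``max_dispersion`` pixels; windows
    spanning at least ``min_duration`` ms are emitted as fixations at the
    window centroid.  Fixations longer than ``max_duration`` ms are removed
    afterwards (not split).  Recording gaps longer than ``gap_factor`` times
    the nominal sampling interval (e.g. created by confidence filtering)
    break windows.

    Durations are in milliseconds; timestamps in the recording are seconds.
    """
    if max_dispersion <= 0:
        raise ValueError("max_dispersion must be positive")
    if not 0 < min_duration < max_duration:
        raise ValueError("require 0 < min_duration < max_duration")
    if len(rec) < 2:
        return []

    dt = np.diff(rec.t)
    nominal = float(np.median(dt))
    breaks = np.nonzero(dt > gap_factor * nominal)[0]
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [len(rec)]))

    fixations: list[Fixation] = []
    for lo, hi in zip(starts, stops):
        if hi - lo < 2:
            continue
        fixations.extend(
            _idt_segment(
                rec.t[lo:hi], rec.x[lo:hi], rec.y[lo:hi], max_dispersion, min_duration / 1000.0
            )
        )
    return [f for f in fixations if f.duration <= max_duration]


def map_to_scanpath(
    fixations: Sequence[Fixation],
    layout: AOILayout,
    participant_id: str = "",
    trial_id: str = "",
    condition: str = "",
) -> Scanpath | None:
    """Assign each fixation centroid to an AOI symbol, keeping temporal order.

    Fixations outside every region are dropped.  Consecutive identical
    symbols are kept as separate time steps (each fixation is one step).
    Returns ``None`` when no fixation falls inside any region.
    """
    symbols = [
        s
        for f in fixations
        if (s := layout.assign(f.centroid_x, f.centroid_y)) is not None
    ]
    if not symbols:
        return None
    return Scanpath(
        symbols=np.asarray(symbols, dtype=np.int64),
        alphabet_size=layout.alphabet_size,
        participant_id=participant_id,
        trial_id=trial_id,
        condition=condition,
    )


def preprocess_recording(
    rec: GazeRecording,
    layout: AOILayout,
    min_confidence: float = 0.9,
    max_dispersion: float = 50.0,
    min_duration: float = 100.0,
    max_duration: float = 1500.0,
) -> tuple[list[Fixation], Scanpath | None]:
    """Full per-trial chain: confidence filter -> IDT -> AOI coding."""
    filtered = filter_samples(rec, min_confidence)
    fixations = detect_fixations(filtered, max_dispersion, min_duration, max_duration)
    scanpath = map_to_scanpath(
        fixations, layout, rec.participant_id, rec.trial_id, rec.condition
    )
    return fixations, scanpath
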