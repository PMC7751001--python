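"""Dimensionless morphometrics of a vertebral-canal cross-sectional-area profile.

The avian lumbosacral vertebral canal carries a series of dorsal transverse
recesses (the lumbosacral transverse canals, LSTCs) superimposed on a smooth
fusiform expansion that houses the glycogen body.  Given an ordered
anterior→posterior series of canal cross-sectional areas ``A_1..A_n`` this
module computes two scale-free statistics that separate the two features:

* **LSTC prominence** — the sample standard deviation of the ratios
  ``R_n = A_n / movmean3(A)_n``, where ``movmean3`` is the 3-point running
  mean with truncated 2-point windows at the ends.  On interior points
  ``R_n = 3 A_n / (A_{n-1} + A_n + A_{n+1})``; a profile without recesses has
  all ratios near 1 and prominence near 0.
* **expansion ratio** — the maximum of the same running mean divided by the
  mean of the first and last raw areas; the running mean suppresses the
  alternating recess signal, so this isolates the fusiform expansion.

The canonical protocol evaluates both statistics on an 11-section window
centred on the maximum-area section (5 canal/intercanal pairs around the
widest point of the lumbosacral region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, WindowOutOfRangeError

CANAL = "canal"
INTERCANAL = "intercanal"
_VALID_LABELS = frozenset({CANAL, INTERCANAL})

#: canonical number of sections in the published protocol
DEFAULT_WINDOW = 11


def _as_positive_array(areas, *, context: str = "") -> np.ndarray:
    arr = np.asarray(areas, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"area series must be one-dimensional{context}")
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
        raise InvalidInputError(f"all areas must be finite and strictly positive{context}")
    return arr


@dataclass(frozen=True, eq=False)
class AreaSeries:
    """Ordered cross-sectional areas (mm²) of one specimen's vertebral canal.

    Sections run anterior→posterior.  ``section_labels`` marks each plane as
    passing through a transverse-canal recess (``"canal"``) or through the
    bone between recesses (``"intercanal"``); labels are metadata only and do
    not enter the metric computations.  Real series may drop a section, so a
    non-alternating label sequence is a warning rather than an error.
    """

    specimen_id: str
    species_id: str
    areas: np.ndarray
    section_labels: tuple[str, ...] = ()
    source: str = "measured"  # measured | phantom | supplementary

    def __post_init__(self):
        arr = _as_positive_array(self.areas, context=f" (specimen {self.specimen_id!r})")
        object.__setattr__(self, "areas", arr)
        labels = tuple(self.section_labels)
        object.__setattr__(self, "section_labels", labels)
        if labels:
            if len(labels) != arr.size:
                raise InvalidInputError(
                    f"specimen {self.specimen_id!r}: {len(labels)} labels for {arr.size} areas"
                )
            bad = sorted(set(labels) - _VALID_LABELS)
            if bad:
                raise InvalidInputError(
                    f"specimen {self.specimen_id!r}: unknown section labels {bad}"
                )
            if any(a == b for a, b in zip(labels, labels[1:])):
                warnings.warn(
                    f"specimen {self.specimen_id!r}: section labels do not alternate "
                    "canal/intercanal (a section may have been dropped)",
                    stacklevel=3,
                )

    def __len__(self) -> int:
        return int(self.areas.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AreaSeries):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.species_id == other.species_id
            and self.source == other.source
            and self.section_labels == other.section_labels
            and np.array_equal(self.areas, other.areas)
        )


@dataclass(frozen=True, eq=False)
class MetricRecord:
    """Per-specimen morphometric statistics with their provenance.

    ``ratios`` holds the dimensionless ``R_n`` series when the record was
    computed from an :class:`AreaSeries`; cohort-simulated records draw the
    two statistics directly and carry ``ratios=None`` with ``n_sections=0``.
    """

    specimen_id: str
    species_id: str
    lstc_prominence: float
    expansion_ratio: float
    n_sections: int
    ratios: np.ndarray | None = None
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.lstc_prominence < 0:
            raise InvalidInputError("lstc_prominence must be non-negative")
        if self.expansion_ratio <= 0:
            raise InvalidInputError("expansion_ratio must be positive")
        if self.ratios is not None:
            object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetricRecord):
            return NotImplemented
        same_ratios = (
            self.ratios is None and other.ratios is None
        ) or (
            self.ratios is not None
            and other.ratios is not None
            and np.array_equal(self.ratios, other.ratios)
        )
        return (
            self.specimen_id == other.specimen_id
            and self.species_id == other.species_id
            and self.lstc_prominence == other.lstc_prominence
            and self.expansion_ratio == other.expansion_ratio
            and self.n_sections == other.n_sections
            and self.warnings == other.warnings
            and same_ratios
        )


def running_mean3(areas) -> np.ndarray:
    """3-point running mean with truncated windows at both ends.

    Interior element ``i`` is ``mean(A[i-1], A[i], A[i+1])``; the first and
    last elements use the 2-point means ``mean(A[0], A[1])`` and
    ``mean(A[-2], A[-1])`` because their windows fall outside the series.
    """
    arr = _as_positive_array(areas)
    if arr.size < 2:
        raise InvalidInputError("running mean needs at least 2 sections")
    sums = np.convolve(arr, np.ones(3), mode="same")
    counts = np.convolve(np.ones(arr.size), np.ones(3), mode="same")
    return sums / counts


def section_ratios(areas) -> np.ndarray:
    """Dimensionless per-section ratios ``R_n = A_n / movmean3(A)_n``.

    Equals ``3 A_n / (A_{n-1} + A_n + A_{n+1})`` on interior points; at the
    endpoints the truncated 2-point mean is used, so every section yields a
    ratio.  A constant series gives ratios exactly 1.
    """
    arr = _as_positive_array(areas)
    if arr.size < 3:
        raise InvalidInputError("section ratios need at least 3 sections")
    return arr / running_mean3(arr)


def lstc_prominence(areas) -> float:
    """Transverse-canal prominence: sample SD (n−1) of the section ratios.

    Scale-invariant; 0 exactly when all ratios are equal (e.g. any constant
    profile).  Larger values mean deeper recesses relative to the canal.
    """
    ratios = section_ratios(areas)
    return float(np.std(ratios, ddof=1))


def expansion_ratio(areas) -> float:
    """Canal expansion: max running-mean area over the mean of the end areas.

    The running mean removes the alternating recess signal, so this statistic
    measures the fusiform glycogen-body expansion independently of recess
    depth.  Equals 1 for a constant profile.
    """
    arr = _as_positive_array(areas)
    if arr.size < 3:
        raise InvalidInputError("expansion ratio needs at least 3 sections")
    return float(np.max(running_mean3(arr)) / ((arr[0] + arr[-1]) / 2.0))


def select_analysis_window(series: AreaSeries, window: int = DEFAULT_WINDOW) -> AreaSeries:
    """Extract the ``window`` consecutive sections centred on the maximum area.

    The published protocol uses 11 sections: the widest section near the
    middle of the lumbosacral region plus five sections each way.  Ties for
    the maximum are broken toward the profile midpoint, then anteriorly.

    Raises
    ------
    WindowOutOfRangeError
        If the maximum lies within ``window // 2`` sections of either end.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidInputError("window length must be odd and >= 3")
    n = len(series)
    if n < window:
        raise WindowOutOfRangeError(series.specimen_id, window - n)
    arr = series.areas
    maxima = np.flatnonzero(arr == arr.max())
    midpoint = (n - 1) / 2.0
    # nearest the midpoint; anterior (smaller index) wins remaining ties
    center = int(min(maxima, key=lambda i: (abs(i - midpoint), i)))
    half = window // 2
    lo, hi = center - half, center + half + 1
    if lo < 0 or hi > n:
        missing = max(-lo, hi - n)
        raise WindowOutOfRangeError(series.specimen_id, missing)
    return AreaSeries(
        specimen_id=series.specimen_id,
        species_id=series.species_id,
        areas=arr[lo:hi],
        section_labels=series.section_labels[lo:hi] if series.section_labels else (),
        source=series.source,
    )


def compute_metrics(series: AreaSeries, window: int = DEFAULT_WINDOW) -> MetricRecord:
    """Compute both statistics for one specimen.

    Profiles longer than ``window`` are first reduced to the maximum-centred
    window; shorter profiles (>= 3 sections) are accepted with a recorded
    ``short-series`` warning so partial specimens remain usable without
    silently altering the canonical protocol.
    """
    notes: list[str] = []
    if len(series) > window:
        series = select_analysis_window(series, window)
    elif len(series) < window:
        if len(series) < 3:
            raise InvalidInputError(
                f"specimen {series.specimen_id!r}: need at least 3 sections, got {len(series)}"
            )
        notes.append(f"short-series:{len(series)}<{window}")
    ratios = section_ratios(series.areas)
    return MetricRecord(
        specimen_id=series.specimen_id,
        species_id=series.species_id,
        lstc_prominence=float(np.std(ratios, ddof=1)),
        expansion_ratio=expansion_ratio(series.areas),
        n_sections=len(series),
        ratios=ratios,
        warnings=tuple(notes),
    )


def metrics_table(
    collection: list[AreaSeries],
    window: int = DEFAULT_WINDOW,
    *,
    skip_errors: bool = False,
) -> list[MetricRecord]:
    """Compute metrics for a collection, ordered by species then specimen.

    Fail-fast by default: the first failing series aborts with its id.  With
    ``skip_errors=True`` failing series are reported via a warning and
    dropped.
    """
    if not collection:
        raise InvalidInputError("metrics_table needs a non-empty collection")
    records: list[MetricRecord] = []
    for series in sorted(collection, key=lambda s: (s.species_id, s.specimen_id)):
        try:
            records.append(compute_metrics(series, window))
        except (InvalidInputError, WindowOutOfRangeError) as exc:
            if not skip_errors:
                raise
            warnings.warn(f"skipping specimen {series.specimen_id!r}: {exc}", stacklevel=2)
    return records
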