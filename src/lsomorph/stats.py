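"""Group-wise comparison of morphometric distributions.

Species-level analysis: multi-specimen species are collapsed to their mean
before any grouping or testing, so each species contributes one point, as a
comparative sample demands.  The central tool is the two-sample, two-sided
Kolmogorov–Smirnov test between species that do and do not practise a given
locomotor mode (perching, terrestrial, ...); the D statistic — the supremum
of the absolute difference of the two empirical CDFs — is the quantity of
interest, with the p-value reported for orientation only since species are
not phylogenetically independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError
from .metrics import MetricRecord
from .taxa import FLAG_COLUMNS, SpeciesRecord, flag_attr

METRIC_FIELDS = ("lstc_prominence", "expansion_ratio")

#: largest n1*n2 for which the exact (enumeration) p-value is used; mirrors
#: the convention of common statistical environments so deposited p-values
#: are comparable
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS statistic with sample sizes and p-value method."""

    d_statistic: float
    p_value: float
    n_group1: int
    n_group2: int
    method: str  # exact | asymptotic


@dataclass(frozen=True)
class GroupSummary:
    """Location/spread summary of one locomotor group (species-level)."""

    group_label: str
    n: int
    mean: float
    median: float
    sd: float
    degenerate: bool = False


def ks_statistic(x, y) -> float:
    """Supremum of |ECDF_x − ECDF_y| over the pooled sample points.

    Method-independent core of the KS test; well defined with ties.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def ks_two_sample(x, y) -> KSResult:
    """Two-sample, two-sided Kolmogorov–Smirnov test.

    The p-value is exact when ``n1*n2 <= 10000`` and the pooled sample has
    no ties; otherwise the asymptotic Kolmogorov distribution with effective
    size ``n1*n2/(n1+n2)`` is used (ties trigger the fallback with a
    warning).  D itself does not depend on the method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    d = ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties:
        warnings.warn(
            "ties present in the pooled sample; using the asymptotic p-value",
            stacklevel=2,
        )
    exact = (x.size * y.size <= EXACT_LIMIT) and not has_ties
    res = sps.ks_2samp(x, y, alternative="two-sided", method="exact" if exact else "asymp")
    assert np.isclose(res.statistic, d, atol=1e-12), "scipy D disagrees with ECDF sup"
    return KSResult(
        d_statistic=d,
        p_value=float(res.pvalue),
        n_group1=int(x.size),
        n_group2=int(y.size),
        method="exact" if exact else "asymptotic",
    )


def _species_level(metrics: list[MetricRecord]) -> pd.DataFrame:
    if not metrics:
        return pd.DataFrame(columns=["species_id", *METRIC_FIELDS])
    df = pd.DataFrame(
        {
            "species_id": [m.species_id for m in metrics],
            "lstc_prominence": [m.lstc_prominence for m in metrics],
            "expansion_ratio": [m.expansion_ratio for m in metrics],
        }
    )
    return df.groupby("species_id", as_index=False, sort=True).mean()


def _flag_lookup(species: list[SpeciesRecord], flag: str) -> dict[str, bool]:
    return {s.species_id: s.flag(flag) for s in species}


def _check_species_known(df: pd.DataFrame, lookup: dict[str, bool]) -> None:
    missing = sorted(set(df["species_id"]) - set(lookup))
    if missing:
        raise InvalidInputError(f"species missing from metadata table: {missing}")


def group_summary(
    metrics: list[MetricRecord],
    species: list[SpeciesRecord],
    field: str,
    flag: str,
) -> tuple[GroupSummary, GroupSummary]:
    """Species-level summaries for the flag-positive and flag-negative groups.

    Returns ``(positive, negative)``; a single-species group reports sd = 0
    and is marked degenerate.
    """
    if field not in METRIC_FIELDS:
        raise InvalidInputError(f"unknown metric field {field!r}; expected one of {METRIC_FIELDS}")
    lookup = _flag_lookup(species, flag)
    df = _species_level(metrics)
    _check_species_known(df, lookup)
    out = []
    for value in (True, False):
        vals = df.loc[[lookup[s] is value for s in df["species_id"]], field].to_numpy()
        if vals.size == 0:
            raise InvalidInputError(f"no species with {flag}={'yes' if value else 'no'}")
        degenerate = vals.size == 1
        out.append(
            GroupSummary(
                group_label=f"{flag}={'yes' if value else 'no'}",
                n=int(vals.size),
                mean=float(vals.mean()),
                median=float(np.median(vals)),
                sd=0.0 if degenerate else float(vals.std(ddof=1)),
                degenerate=degenerate,
            )
        )
    return out[0], out[1]


def ks_by_flag(
    metrics: list[MetricRecord],
    species: list[SpeciesRecord],
    field: str,
    flag: str,
) -> KSResult:
    """KS test of a metric between flag-positive and flag-negative species."""
    if field not in METRIC_FIELDS:
        raise InvalidInputError(f"unknown metric field {field!r}; expected one of {METRIC_FIELDS}")
    lookup = _flag_lookup(species, flag)
    df = _species_level(metrics)
    _check_species_known(df, lookup)
    pos = df.loc[[lookup[s] for s in df["species_id"]], field].to_numpy()
    neg = df.loc[[not lookup[s] for s in df["species_id"]], field].to_numpy()
    return ks_two_sample(pos, neg)


def morphospace_table(
    metrics: list[MetricRecord], species: list[SpeciesRecord]
) -> pd.DataFrame:
    """One row per species: both metrics plus every locomotor flag.

    Multi-specimen species are collapsed by the mean; rows are sorted by
    taxon name.  Duplicate rows in the species table are rejected.
    """
    ids = [s.species_id for s in species]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise InvalidInputError(f"duplicate species rows in metadata: {dupes}")
    df = _species_level(metrics)
    lookup = {s.species_id: s for s in species}
    _check_species_known(df, {k: True for k in lookup})
    for col in FLAG_COLUMNS:
        df[col] = [getattr(lookup[s], flag_attr(col)) for s in df["species_id"]]
    return df.sort_values("species_id", ignore_index=True)


def intraspecific_spread(
    metrics: list[MetricRecord],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Within-species dispersion versus between-species dispersion.

    Uses only species with >= 2 specimens (>= 2 such species required).
    Returns a per-species table of specimen counts, means and SDs of each
    metric, and the pooled within-species variance divided by the variance
    of the species means for each metric.  On data conforming to the
    comparative design this ratio is expected (not enforced) to be < 1.
    """
    df = pd.DataFrame(
        {
            "species_id": [m.species_id for m in metrics],
            "lstc_prominence": [m.lstc_prominence for m in metrics],
            "expansion_ratio": [m.expansion_ratio for m in metrics],
        }
    )
    counts = df.groupby("species_id")["lstc_prominence"].count()
    multi = counts[counts >= 2].index
    if len(multi) < 2:
        raise InvalidInputError(
            "intraspecific spread needs >= 2 species with >= 2 specimens each"
        )
    sub = df[df["species_id"].isin(multi)]
    table = sub.groupby("species_id").agg(
        n=("lstc_prominence", "count"),
        prominence_mean=("lstc_prominence", "mean"),
        prominence_sd=("lstc_prominence", lambda v: v.std(ddof=1)),
        expansion_mean=("expansion_ratio", "mean"),
        expansion_sd=("expansion_ratio", lambda v: v.std(ddof=1)),
    ).reset_index()
    ratios: dict[str, float] = {}
    for field in METRIC_FIELDS:
        grouped = sub.groupby("species_id")[field]
        # pooled within-species variance (df-weighted) over between-species variance
        nsz = grouped.count().to_numpy()
        wvar = grouped.var(ddof=1).to_numpy()
        within = float(np.sum((nsz - 1) * wvar) / np.sum(nsz - 1))
        between = float(grouped.mean().var(ddof=1))
        ratios[field] = within / between
    return table, ratios
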