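"""Readers and writers for the pipeline's tabular and tree formats.

Canonical formats: UTF-8 comma-separated CSV with a header row and "."
decimal; Newick for phylogenies.  Section indices are 0-based with the
anterior-most section first; species ids are binomials with an underscore
(``Apus_pacificus``) so they double as tree tip labels.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import pandas as pd

from .errors import ParseError
from .metrics import AreaSeries, MetricRecord
from .taxa import FLAG_COLUMNS, SpeciesRecord, flag_attr

AREA_COLUMNS = ("specimen_id", "species_id", "section_index", "section_label", "area_mm2")
SPECIES_COLUMNS = ("species_id", "order", "family", *FLAG_COLUMNS)


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _data_rows(index) -> list[int]:
    """1-based file row numbers (header is row 1)."""
    return [int(i) + 2 for i in index]


def read_area_table(path, *, source: str = "measured") -> list[AreaSeries]:
    """Load per-specimen area series from a long-format CSV.

    Expected columns: ``specimen_id, species_id, section_index,
    section_label, area_mm2``.  Sections are ordered by their 0-based index;
    all :class:`AreaSeries` invariants are validated on load.  Errors carry
    1-based file row numbers.
    """
    df = _read_csv(path, AREA_COLUMNS)
    idx = pd.to_numeric(df["section_index"], errors="coerce")
    bad = df.index[idx.isna() | (idx != idx.round())]
    if len(bad):
        raise ParseError(f"{path}: non-integer section_index", rows=_data_rows(bad))
    area = pd.to_numeric(df["area_mm2"], errors="coerce")
    bad = df.index[area.isna() | (area <= 0)]
    if len(bad):
        raise ParseError(f"{path}: non-numeric or non-positive area_mm2", rows=_data_rows(bad))
    df = df.assign(section_index=idx.astype(int), area_mm2=area.astype(float))
    dup = df.duplicated(subset=["specimen_id", "section_index"], keep=False)
    if dup.any():
        raise ParseError(
            f"{path}: duplicate (specimen_id, section_index) pairs",
            rows=_data_rows(df.index[dup]),
        )
    out: list[AreaSeries] = []
    for (specimen, species), grp in df.groupby(["specimen_id", "species_id"], sort=True):
        grp = grp.sort_values("section_index")
        out.append(
            AreaSeries(
                specimen_id=str(specimen),
                species_id=str(species),
                areas=grp["area_mm2"].to_numpy(),
                section_labels=tuple(grp["section_label"]),
                source=source,
            )
        )
    seen = [s.specimen_id for s in out]
    dupes = sorted({s for s in seen if seen.count(s) > 1})
    if dupes:
        raise ParseError(f"{path}: specimen(s) listed under multiple species: {dupes}")
    return out


def write_area_table(series: list[AreaSeries], path) -> None:
    rows = [
        {
            "specimen_id": s.specimen_id,
            "species_id": s.species_id,
            "section_index": i,
            "section_label": s.section_labels[i] if s.section_labels else "",
            "area_mm2": float(a),
        }
        for s in series
        for i, a in enumerate(s.areas)
    ]
    pd.DataFrame(rows, columns=list(AREA_COLUMNS)).to_csv(path, index=False)


_YESNO = {"yes": True, "no": False}


def read_species_table(path) -> list[SpeciesRecord]:
    """Load species metadata with yes/no locomotor flags.

    Expected columns: ``species_id, order, family, terrestrial, perching,
    fly, float, dive``; flag values must be exactly ``yes`` or ``no``.
    """
    df = _read_csv(path, SPECIES_COLUMNS)
    for col in FLAG_COLUMNS:
        vals = df[col].str.strip().str.lower()
        bad = df.index[~vals.isin(_YESNO)]
        if len(bad):
            raise ParseError(
                f"{path}: column {col!r} must be yes/no", rows=_data_rows(bad)
            )
        df[col] = vals.map(_YESNO)
    return [
        SpeciesRecord(
            species_id=str(r["species_id"]),
            order=str(r["order"]),
            family=str(r["family"]),
            **{flag_attr(c): bool(r[c]) for c in FLAG_COLUMNS},
        )
        for _, r in df.iterrows()
    ]


def write_species_table(species: list[SpeciesRecord], path) -> None:
    rows = [
        {
            "species_id": s.species_id,
            "order": s.order,
            "family": s.family,
            **{c: "yes" if getattr(s, flag_attr(c)) else "no" for c in FLAG_COLUMNS},
        }
        for s in species
    ]
    pd.DataFrame(rows, columns=list(SPECIES_COLUMNS)).to_csv(path, index=False)


def write_metrics_table(metrics: list[MetricRecord], path) -> None:
    rows = [
        {
            "specimen_id": m.specimen_id,
            "species_id": m.species_id,
            "lstc_prominence": m.lstc_prominence,
            "expansion_ratio": m.expansion_ratio,
            "n_sections": m.n_sections,
            "warnings": ";".join(m.warnings),
        }
        for m in metrics
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_tree(path) -> dendropy.Tree:
    """Load a Newick phylogeny whose tip labels are species ids."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ParseError(f"cannot parse Newick tree {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate tip labels {dupes}")
    return tree


def tip_order(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's ladderised leaf order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]


def plot_order(tree: dendropy.Tree, species_ids: list[str]) -> list[str]:
    """Species order for tree-aligned plots.

    Tree tips first (those present in the data), then any data species
    missing from the tree, reported via a warning and appended
    alphabetically.
    """
    tips = tip_order(tree)
    present = [t for t in tips if t in set(species_ids)]
    missing = sorted(set(species_ids) - set(tips))
    if missing:
        warnings.warn(f"species not in tree, appended to plot order: {missing}", stacklevel=2)
    return present + missing
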