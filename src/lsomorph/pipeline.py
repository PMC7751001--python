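"""End-to-end analysis: read tables, compute metrics, compare groups, report.

``run_full_pipeline`` produces, under the configured output directory:

* ``metrics.csv`` — per-specimen prominence and expansion ratio;
* ``group_summaries.csv`` — species-level mean/median/SD per flag group;
* ``ks_results.csv`` — two-sample KS D and p per (metric, flag);
* ``morphospace_<flag>.png``, ``ecdf_<flag>.png``, ``hist_<flag>.png`` —
  scatter of the two metrics, prominence ECDFs, prominence histograms,
  coloured by flag;
* ``tree_prominence.png`` — tip-aligned prominence bars when a phylogeny
  is supplied;
* ``run_manifest.json`` — config hash, seed and the list of outputs.

CSV outputs are byte-deterministic for identical inputs; figures are not
part of the determinism guarantee.  Any stage failure aborts with a
stage-tagged error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .errors import InvalidConfigError, StageError
from .metrics import DEFAULT_WINDOW, metrics_table
from .stats import METRIC_FIELDS, group_summary, ks_by_flag, morphospace_table

log = logging.getLogger("lsomorph")


@dataclass
class PipelineConfig:
    """Paths, protocol parameters and reporting options for one run."""

    area_table: str
    species_table: str
    tree: str | None = None
    window_length: int = DEFAULT_WINDOW
    closing_radius: int = 3
    ks_flags: tuple[str, ...] = ("perching", "terrestrial")
    out_dir: str = "lsomorph_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise InvalidConfigError("window_length must be odd and >= 3")
        self.ks_flags = tuple(self.ks_flags)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(data) - known)
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {unknown}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Outputs of one pipeline run, by artifact name."""

    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    ks_results: pd.DataFrame | None = None
    metrics: list = field(default_factory=list)


def _fig_morphospace(table: pd.DataFrame, flag: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for value, color in ((True, "tab:red"), (False, "tab:blue")):
        sub = table[table[flag] == value]
        ax.scatter(
            sub["lstc_prominence"], sub["expansion_ratio"],
            c=color, label=f"{flag}: {'yes' if value else 'no'}", alpha=0.8,
        )
    ax.set_xlabel("LSTC prominence")
    ax.set_ylabel("expansion ratio")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_ecdf(table: pd.DataFrame, flag: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for value, color in ((True, "tab:red"), (False, "tab:blue")):
        vals = np.sort(table.loc[table[flag] == value, "lstc_prominence"].to_numpy())
        if vals.size:
            ax.step(
                vals, np.arange(1, vals.size + 1) / vals.size, where="post",
                color=color, label=f"{flag}: {'yes' if value else 'no'}",
            )
    ax.set_xlabel("LSTC prominence")
    ax.set_ylabel("cumulative fraction of species")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_hist(table: pd.DataFrame, flag: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    bins = np.histogram_bin_edges(table["lstc_prominence"], bins=12)
    for value, color in ((True, "tab:red"), (False, "tab:blue")):
        ax.hist(
            table.loc[table[flag] == value, "lstc_prominence"], bins=bins,
            color=color, alpha=0.6, label=f"{flag}: {'yes' if value else 'no'}",
        )
    ax.set_xlabel("LSTC prominence")
    ax.set_ylabel("species count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_tree_bars(table: pd.DataFrame, order: list[str], path: Path) -> None:
    sub = table.set_index("species_id").loc[order]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(order))))
    ax.barh(np.arange(len(order)), sub["lstc_prominence"], color="tab:gray")
    ax.set_yticks(np.arange(len(order)), labels=order, fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("LSTC prominence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every analysis stage; see the module docstring for outputs."""
    logging.basicConfig(level=config.log_level.upper())
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    written: list[Path] = []

    def emit(name: str, filename: str):
        path = out_dir / filename
        written.append(path)
        bundle.files[name] = path
        return path

    stage = "read-inputs"
    try:
        series = lio.read_area_table(config.area_table)
        species = lio.read_species_table(config.species_table)
        tree = lio.read_tree(config.tree) if config.tree else None
        log.info("read %d area series, %d species", len(series), len(species))

        stage = "metrics"
        metrics = metrics_table(series, window=config.window_length)
        bundle.metrics = metrics
        lio.write_metrics_table(metrics, emit("metrics", "metrics.csv"))

        stage = "summaries"
        table = morphospace_table(metrics, species)
        rows = []
        for flag in config.ks_flags:
            for fld in METRIC_FIELDS:
                pos, neg = group_summary(metrics, species, fld, flag)
                for summ in (pos, neg):
                    rows.append({"metric": fld, "group": summ.group_label, "n": summ.n,
                                 "mean": summ.mean, "median": summ.median, "sd": summ.sd})
        pd.DataFrame(rows).to_csv(
            emit("group_summaries", "group_summaries.csv"), index=False, float_format="%.10g"
        )

        stage = "ks-tests"
        ks_rows = []
        for flag in config.ks_flags:
            for fld in METRIC_FIELDS:
                res = ks_by_flag(metrics, species, fld, flag)
                ks_rows.append({"metric": fld, "flag": flag, "d_statistic": res.d_statistic,
                                "p_value": res.p_value, "n_group1": res.n_group1,
                                "n_group2": res.n_group2, "method": res.method})
        ks_df = pd.DataFrame(ks_rows)
        bundle.ks_results = ks_df
        ks_df.to_csv(emit("ks_results", "ks_results.csv"), index=False, float_format="%.10g")

        stage = "figures"
        for flag in config.ks_flags:
            _fig_morphospace(table, flag, emit(f"morphospace_{flag}", f"morphospace_{flag}.png"))
            _fig_ecdf(table, flag, emit(f"ecdf_{flag}", f"ecdf_{flag}.png"))
            _fig_hist(table, flag, emit(f"hist_{flag}", f"hist_{flag}.png"))
        if tree is not None:
            order = lio.plot_order(tree, list(table["species_id"]))
            _fig_tree_bars(table, order, emit("tree_prominence", "tree_prominence.png"))

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_series": len(series),
            "n_species": len(species),
            "outputs": sorted(p.name for p in written),
        }
        with open(emit("manifest", "run_manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
    return bundle
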