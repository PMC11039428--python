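"""Orchestration: subset, aggregate, fit batteries, outlier sensitivity.

A run takes an effect-size table, a host tree and a symbiont tree, and
produces — for one of the analyses (host association, environment,
time, or the intracellular subset of environment) — the overall
intercept-only fit, one moderator fit per configured moderator, and
the whole battery repeated after one Cook's-distance outlier-removal
pass, serialised as JSON plus a human-readable Markdown table.

Phylogenetic structure: the configured tree (symbiont by default; host
as a one-flag swap) is pruned to the species present, stand-in tips
are relabelled from the substitution table, and each species tip is
expanded to one population tip per effect-size record so every record
maps to its own tip at effectively zero within-species distance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import phylo
from .effect_sizes import compute_effect_table
from .metamodel import FitError, MetaFit, fit_reml, make_spec
from .outliers import InfluenceReport, apply_outlier_rule

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "DEFAULT_MODERATORS",
    "subset_dataset",
    "aggregate_by_symbiont",
    "run_analysis",
    "write_report",
]

logger = logging.getLogger(__name__)

ANALYSES = ("host_association", "environment", "time", "environment_intracellular")

# moderator batteries per analysis: dependence-on-host is not examined for
# host association, generation time only for the environment analyses, and
# host life stage only for the time analysis
DEFAULT_MODERATORS: dict[str, list[str]] = {
    "host_association": [
        "host_kingdom", "association_type", "dependence_on_host",
        "symbiont_diversity", "host_reproduction", "symbiont_location",
        "genome_size_mb",
    ],
    "environment": [
        "host_kingdom", "association_type", "dependence_on_host",
        "symbiont_diversity", "host_reproduction", "symbiont_location",
        "genome_size_mb",
    ],
    "time": [
        "host_life_stage", "host_kingdom", "association_type",
        "dependence_on_host", "symbiont_diversity", "host_reproduction",
        "symbiont_location", "genome_size_mb",
    ],
    "environment_intracellular": [
        "host_kingdom", "generation_time_years", "genome_size_mb",
    ],
}
DEFAULT_MODERATORS["host_association"] = [
    m for m in DEFAULT_MODERATORS["host_association"] if m != "dependence_on_host"
]


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (YAML/JSON loadable)."""

    dataset: object                      # path to CSV or a DataFrame
    analysis: str = "environment"
    symbiont_tree: object | None = None  # path or dendropy.Tree
    host_tree: object | None = None
    random_effect_tree: str = "symbiont"  # or "host", or "none"
    substitutions: object | None = None  # path to 2-col CSV or dict
    moderators: list[str] | None = None  # None -> DEFAULT_MODERATORS[analysis]
    aggregation: str = "none"            # none | per_pairing | per_symbiont
    epsilon: float = 1e-6
    scale: float = 100.0
    variance_mode: str = "literal"
    aggregate_variance: str = "mean_over_n"  # or "mean"
    outlier_screen: bool = True
    refit_components: bool = True
    seed: int = 0
    output_dir: object | None = None

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(
                f"analysis must be one of {ANALYSES}, got {self.analysis!r}"
            )
        if self.random_effect_tree not in ("symbiont", "host", "none"):
            raise ValueError(
                f"random_effect_tree must be symbiont/host/none, "
                f"got {self.random_effect_tree!r}"
            )
        if self.aggregation not in ("none", "per_pairing", "per_symbiont"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def subset_dataset(records: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Records of one analysis; the intracellular variant additionally
    keeps only records whose symbiont resides inside host cells."""
    if "analysis" not in records.columns:
        raise ValueError("records lack an 'analysis' column")
    if analysis == "environment_intracellular":
        sub = records[
            (records["analysis"] == "environment")
            & (records.get("symbiont_location") == "intracellular")
        ]
    else:
        sub = records[records["analysis"] == analysis]
    if sub.empty:
        raise ValueError(f"no records for analysis {analysis!r}")
    return sub.copy()


def aggregate_by_symbiont(
    records: pd.DataFrame,
    mode: str,
    *,
    variance: str = "mean_over_n",
    strict_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse multiple effect sizes per symbiont (or per host-symbiont
    pairing) to their mean.

    y becomes the group mean; v becomes mean(v)/k by default (variance of
    a mean of independent effects) or plain mean(v) with
    ``variance="mean"``.  Columns in ``strict_cols`` (e.g. a continuous
    moderator) must be constant within each group — mixed values raise
    rather than being silently averaged.
    """
    if mode not in ("per_pairing", "per_symbiont"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    keys = ["symbiont_species"] if mode == "per_symbiont" else [
        "host_species", "symbiont_species",
    ]
    for k in keys:
        if k not in records.columns or records[k].isna().any():
            raise ValueError(f"missing species labels in column {k!r}")
    for col in strict_cols or []:
        if col not in records.columns:
            continue
        bad = records.groupby(keys)[col].nunique(dropna=False)
        bad = bad[bad > 1]
        if not bad.empty:
            raise ValueError(
                f"column {col!r} varies within aggregation groups "
                f"{list(bad.index)}; supply an explicit per-group value"
            )
    rows = []
    for _, grp in records.groupby(keys, sort=True):
        row = grp.iloc[0].copy()
        k = len(grp)
        row["y"] = grp["y"].mean()
        row["v"] = grp["v"].mean() / (k if variance == "mean_over_n" else 1)
        row["n_aggregated"] = k
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out


def _load_dataset(dataset) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        return dataset.copy()
    return pd.read_csv(dataset)


def _load_tree(tree):
    if tree is None:
        return None
    if isinstance(tree, dendropy.Tree):
        return tree
    return phylo.read_newick_file(tree)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _prepare_correlation(df: pd.DataFrame, config: AnalysisConfig):
    """Prune, substitute, population-expand and convert the configured tree."""
    if config.random_effect_tree == "none":
        return None, df
    species_col = (
        "symbiont_species" if config.random_effect_tree == "symbiont"
        else "host_species"
    )
    tree = _load_tree(
        config.symbiont_tree if config.random_effect_tree == "symbiont"
        else config.host_tree
    )
    if tree is None:
        raise ValueError(
            f"random_effect_tree={config.random_effect_tree!r} but no tree supplied"
        )
    subs = config.substitutions
    if subs is not None and not isinstance(subs, dict):
        subs = phylo.read_substitution_table(subs)
    if subs:
        tree = phylo.substitute_tips(tree, subs)
    species = df[species_col].astype(str)
    missing = sorted(set(species) - set(phylo.tip_labels(tree)))
    if missing:
        raise ValueError(
            f"species absent from the {config.random_effect_tree} tree "
            f"after substitution: {missing}"
        )
    tree = phylo.prune_to(tree, sorted(set(species)))
    df = df.copy()
    df["tip_label"] = [
        f"{sp}|{eid}" for sp, eid in zip(species, df["effect_id"].astype(str))
    ]
    multiplicity = df.groupby(species_col)["tip_label"].apply(list).to_dict()
    tree = phylo.expand_populations(tree, multiplicity, epsilon=config.epsilon)
    return phylo.bm_correlation(tree), df


@dataclass
class AnalysisReport:
    """Everything one run produced, with provenance for reproducibility."""

    analysis: str
    config: dict
    provenance: dict
    n_records: int
    n_retained: int
    overall: dict
    moderators: dict
    influence: dict | None

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "config": self.config,
            "provenance": self.provenance,
            "n_records": self.n_records,
            "n_retained": self.n_retained,
            "overall": self.overall,
            "moderators": self.moderators,
            "influence": self.influence,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [
            f"# Analysis: {self.analysis}",
            "",
            f"Records: {self.n_records} (retained after outlier rule: "
            f"{self.n_retained})",
            "",
            "| model | subset | n | estimate / QM | df | p |",
            "|---|---|---|---|---|---|",
        ]

        def fit_row(label, subset, d):
            if d is None:
                return f"| {label} | {subset} | — | — | — | — |"
            if "QM" in d:
                return (
                    f"| {label} | {subset} | {d['n']} | QM = {d['QM']:.3f} "
                    f"| {d['QM_df']} | {d['QM_p']:.3f} |"
                )
            c = d["coefficients"][0]
            return (
                f"| {label} | {subset} | {d['n']} | "
                f"{c['estimate']:.3f} (z = {c['z']:.3f}) | — | {c['p']:.3f} |"
            )

        lines.append(fit_row("overall", "all", self.overall.get("all")))
        lines.append(
            fit_row("overall", "outliers removed", self.overall.get("outliers_removed"))
        )
        for name, entry in self.moderators.items():
            if "skipped" in entry:
                lines.append(f"| {name} | — | — | skipped: {entry['skipped']} | — | — |")
                continue
            lines.append(fit_row(name, "all", entry.get("all")))
            lines.append(
                fit_row(name, "outliers removed", entry.get("outliers_removed"))
            )
        return "\n".join(lines) + "\n"


def _fit_to_dict(fit: MetaFit) -> dict:
    return fit.to_dict()


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run one analysis end to end.

    Computes effect sizes where raw summaries are given, subsets to the
    configured analysis, optionally aggregates, builds the phylogenetic
    correlation, fits the overall model and one model per moderator, and
    repeats every fit once with Cook's-distance-flagged records removed.
    """
    df = _load_dataset(config.dataset)
    needs_es = "y" not in df.columns or "v" not in df.columns
    if needs_es:
        df = compute_effect_table(
            df, scale=config.scale, variance_mode=config.variance_mode
        )
    df = subset_dataset(df, config.analysis)

    moderators = (
        config.moderators
        if config.moderators is not None
        else [
            m for m in DEFAULT_MODERATORS[config.analysis] if m in df.columns
        ]
    )
    if config.aggregation != "none":
        df = aggregate_by_symbiont(
            df,
            config.aggregation,
            variance=config.aggregate_variance,
            strict_cols=moderators,
        )

    # levels audit before fitting
    usable: list[str] = []
    skipped: dict[str, str] = {}
    for m in moderators:
        if m not in df.columns:
            skipped[m] = "column absent"
            continue
        col = df[m].dropna()
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() < 2:
                skipped[m] = "constant covariate"
                continue
        elif col.nunique() < 2:
            skipped[m] = f"single observed level ({sorted(col.unique())})"
            continue
        usable.append(m)
        logger.info("moderator %s levels: %s", m, sorted(col.astype(str).unique())[:10])
    for m, why in skipped.items():
        logger.warning("skipping moderator %s: %s", m, why)

    corr, df = _prepare_correlation(df, config)

    def battery(data: pd.DataFrame) -> tuple[dict, dict, object]:
        spec = make_spec(data, corr=corr if corr is not None else None)
        overall = fit_reml(spec)
        per_mod = {}
        for m in usable:
            try:
                mspec = make_spec(data, moderator=m, corr=corr)
                per_mod[m] = fit_reml(mspec)
            except FitError as err:
                per_mod[m] = err
        return {"overall": overall, "moderators": per_mod}, spec, overall

    full_fits, spec, overall_fit = battery(df)

    influence: InfluenceReport | None = None
    retained = df
    if config.outlier_screen:
        influence = apply_outlier_rule(
            spec, overall_fit, refit_components=config.refit_components
        )
        if influence.flagged:
            retained = df[~df["effect_id"].astype(str).isin(
                [str(f) for f in influence.flagged]
            )]
    reduced_fits = (
        battery(retained)[0] if config.outlier_screen and influence.flagged
        else full_fits
    )

    def pack(fits: dict) -> tuple[dict, dict]:
        ov = _fit_to_dict(fits["overall"])
        mods = {}
        for m, f in fits["moderators"].items():
            mods[m] = {"error": str(f)} if isinstance(f, Exception) else _fit_to_dict(f)
        return ov, mods

    ov_all, mods_all = pack(full_fits)
    ov_red, mods_red = pack(reduced_fits)
    mod_report = {}
    for m in usable:
        mod_report[m] = {"all": mods_all.get(m), "outliers_removed": mods_red.get(m)}
    for m, why in skipped.items():
        mod_report[m] = {"skipped": why}

    provenance = {"seed": config.seed}
    for key in ("dataset", "symbiont_tree", "host_tree"):
        val = getattr(config, key)
        if isinstance(val, (str, Path)) and Path(val).exists():
            provenance[f"{key}_sha256"] = _sha256(val)
    config_dict = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in vars(config).items()
        if isinstance(v, (str, int, float, bool, list, type(None)))
    }

    return AnalysisReport(
        analysis=config.analysis,
        config=config_dict,
        provenance=provenance,
        n_records=len(df),
        n_retained=len(retained),
        overall={"all": ov_all, "outliers_removed": ov_red},
        moderators=mod_report,
        influence=influence.to_dict() if influence is not None else None,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.md").write_text(report.to_markdown())
    if report.influence is not None:
        rows = [
            {"effect_id": k, "cooks_d": v,
             "flagged": k in set(report.influence["flagged"])}
            for k, v in report.influence["cooks_d"].items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "influence.csv", index=False)
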