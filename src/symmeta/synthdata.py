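"""Synthetic trees and effect-size tables with known generating truth.

The generator emulates the statistical structure the meta-analytic
model assumes: a true overall (transformed) effect, optional moderator
effects, study-level and record-level normal deviations, a
phylogenetically correlated deviation drawn from a Brownian-motion
correlation matrix of a simulated pure-birth tree, and known
heteroscedastic sampling noise.  It also back-transforms each record
into raw two-group summaries (means, SDs, n) whose percent change and
delta-method variance reproduce the record's (y, v) after the
cube-root transform, so the effect-size stage can be exercised
end-to-end.  Everything is deterministic per seed through a single
:class:`numpy.random.Generator` stream.

Default design sizes and variances are set to the scale of a typical
multi-study symbiont-fitness corpus: ~50 studies contributing one to a
few effect sizes each (~120 records), ~40 symbiont taxa, variance
components of order one on the cube-root-percent scale, and sampling
variances a fraction of the total heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .phylo import bm_correlation, read_newick

__all__ = ["SimulationTruth", "simulate_tree", "simulate_dataset"]


@dataclass
class SimulationTruth:
    """Generating parameters for a synthetic effect-size corpus.

    ``moderator_effects`` maps a categorical column name to
    ``{level: effect}`` (the transformed-scale shift added for that
    level; include every level, reference at 0.0).
    ``continuous_effects`` maps a numeric column name to its slope on a
    standard-normal covariate.  ``v_range`` bounds the uniform draw of
    the known sampling variances on the transformed scale.
    """

    beta0: float = 0.0
    sigma2_study: float = 1.0
    sigma2_within: float = 0.5
    sigma2_phylo: float = 1.0
    v_range: tuple[float, float] = (0.2, 1.0)
    n_studies: int = 50
    effects_per_study: float = 2.4  # mean of 1 + Poisson(mean - 1)
    n_tips: int = 40
    moderator_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    continuous_effects: dict[str, float] = field(default_factory=dict)
    analysis: str = "environment"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_study", "sigma2_within", "sigma2_phylo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.v_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid v_range {self.v_range}")
        if self.effects_per_study < 1:
            raise ValueError("effects_per_study must be >= 1")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["v_range"] = list(self.v_range)
        return d


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_tree(n_tips: int, seed=0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times, rescaled to
    unit root-to-tip depth (ultrametric).  Deterministic per seed."""
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    rng = _rng(seed)
    # root splits at time 0 into lineages 0 and 1; grow until n_tips
    parents: dict[int, tuple[int, int]] = {}  # node -> (child_a, child_b)
    birth_time = {0: 0.0, 1: 0.0}
    next_id = 2
    active = [0, 1]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active[k]
        a, b = next_id, next_id + 1
        next_id += 2
        parents[node] = (a, b)
        birth_time[a] = birth_time[b] = t
        active[k] = a
        active.append(b)
    t_end = t + rng.exponential(1.0 / len(active))

    labels = {node: f"t{i + 1}" for i, node in enumerate(sorted(active))}
    scale = t_end if t_end > 0 else 1.0

    def emit(node: int, stop_time: float) -> str:
        if node in parents:
            a, b = parents[node]
            split = birth_time[a]
            length = (split - birth_time[node]) / scale
            return f"({emit(a, t_end)},{emit(b, t_end)}):{length:.12f}"
        length = (stop_time - birth_time[node]) / scale
        return f"{labels[node]}:{length:.12f}"

    newick = f"({emit(0, t_end)},{emit(1, t_end)});"
    return read_newick(newick)


def _back_transform(y: float, v: float, n_rep: int = 10):
    """Two-group summaries whose percent change / delta variance reproduce
    (y, v) after cube-rooting; None if infeasible (|pc| >= 100 upward)."""
    pc = y**3
    var = v**3
    control_mean = 100.0
    alt_mean = control_mean * (1.0 - pc / 100.0)
    if alt_mean <= 0 or var <= 0:
        return None
    r = alt_mean / control_mean
    # split the relative variance evenly between the two groups
    rel = var / (2.0 * 100.0**2 * r**2)
    se_c = control_mean * np.sqrt(rel)
    se_a = alt_mean * np.sqrt(rel)
    return {
        "control_mean": control_mean,
        "control_disp": se_c * np.sqrt(n_rep),
        "control_n": n_rep,
        "alt_mean": alt_mean,
        "alt_disp": se_a * np.sqrt(n_rep),
        "alt_n": n_rep,
        "disp_kind": "sd",
    }


def simulate_dataset(
    truth: SimulationTruth,
    tree: dendropy.Tree | None = None,
    rng=None,
) -> tuple[pd.DataFrame, dendropy.Tree, dict]:
    """Draw a synthetic effect-size table from the generating model.

    Returns ``(table, tree, truth_echo)``.  The table carries the
    transformed effects (y, v), the untransformed percent change and
    variance, raw two-group summaries where the back-transformation is
    feasible (``raw_feasible`` flags the rest), moderator columns, and
    the tip mapping.  The truth echo records the generating parameters
    and the realised design sizes.
    """
    rng = _rng(truth.seed if rng is None else rng)
    if tree is None:
        tree = simulate_tree(truth.n_tips, rng)
    corr = bm_correlation(tree)
    tips = corr.labels

    counts = 1 + rng.poisson(max(truth.effects_per_study - 1.0, 0.0), truth.n_studies)
    n_records = int(counts.sum())
    study_ids = np.repeat([f"S{j + 1}" for j in range(truth.n_studies)], counts)

    tip_idx = rng.integers(len(tips), size=n_records)
    u_study = rng.normal(0.0, np.sqrt(truth.sigma2_study), truth.n_studies)
    u_within = rng.normal(0.0, np.sqrt(truth.sigma2_within), n_records)
    L = np.linalg.cholesky(
        corr.matrix + 1e-10 * np.eye(len(tips))
    )
    u_phylo_tip = np.sqrt(truth.sigma2_phylo) * (L @ rng.standard_normal(len(tips)))
    v = rng.uniform(truth.v_range[0], truth.v_range[1], n_records)
    eps = rng.normal(0.0, np.sqrt(v))

    y = np.full(n_records, truth.beta0)
    y += np.repeat(u_study, counts)
    y += u_phylo_tip[tip_idx]
    y += u_within + eps

    df = pd.DataFrame(
        {
            "study_id": study_ids,
            "effect_id": [f"E{i + 1}" for i in range(n_records)],
            "host_species": np.repeat(
                [f"host_{j + 1}" for j in range(truth.n_studies)], counts
            ),
            "symbiont_species": [tips[i] for i in tip_idx],
            "analysis": truth.analysis,
            "tip_label": [tips[i] for i in tip_idx],
        }
    )

    for name, levels in truth.moderator_effects.items():
        labs = sorted(levels)
        assign = rng.integers(len(labs), size=n_records)
        df[name] = [labs[a] for a in assign]
        y += np.array([levels[labs[a]] for a in assign])
    for name, slope in truth.continuous_effects.items():
        x = rng.standard_normal(n_records)
        df[name] = x
        y += slope * x

    df["y"] = y
    df["v"] = v
    df["percent_change"] = y**3
    df["variance"] = v**3

    raw_cols = [
        "control_mean", "control_disp", "control_n",
        "alt_mean", "alt_disp", "alt_n", "disp_kind",
    ]
    feasible = []
    raws = {c: [] for c in raw_cols}
    for yi, vi in zip(y, v):
        raw = _back_transform(float(yi), float(vi))
        feasible.append(raw is not None)
        for c in raw_cols:
            raws[c].append(raw[c] if raw is not None else np.nan)
    for c in raw_cols:
        df[c] = raws[c]
    df["raw_feasible"] = feasible

    echo = {
        "truth": truth.as_dict(),
        "n_records": n_records,
        "n_studies": truth.n_studies,
        "n_tips": len(tips),
        "n_raw_feasible": int(np.sum(feasible)),
    }
    return df, tree, echo
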