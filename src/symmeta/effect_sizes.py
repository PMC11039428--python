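"""Percent-change effect sizes for two-group fitness contrasts.

Symbiont fitness is reported on wildly different scales across studies
(CFU, counts, density, colonized area, nodule number, ...).  A
scale-free effect size is the percent change between a control/reference
condition and an alternative condition,

    pc = 100 * (mean_control - mean_alternative) / mean_control,

positive when fitness is greater in the control condition.  Its sampling
variance follows from the first-order delta method for a ratio of two
independent means.  Because a handful of contrasts yield very large
percent changes, the final effect and its variance are cube-root
transformed with the sign preserved before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementSummary",
    "RawEffect",
    "TransformedEffect",
    "EffectSizeError",
    "percent_change",
    "delta_method_variance",
    "signed_cube_root",
    "transform_record",
    "compute_effect_table",
]


class EffectSizeError(ValueError):
    """Raised for degenerate two-group summaries (zero control mean, etc.)."""


@dataclass(frozen=True)
class MeasurementSummary:
    """Group-level summary of a fitness measurement.

    Parameters
    ----------
    mean
        Group mean on the study's own scale.
    dispersion
        Reported dispersion on the same scale (non-negative).
    n
        Number of replicates (>= 1).
    dispersion_kind
        ``"sd"`` if ``dispersion`` is a standard deviation (the default;
        SE = sd / sqrt(n)) or ``"se"`` if it is already a standard error.
    """

    mean: float
    dispersion: float
    n: int
    dispersion_kind: str = "sd"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise EffectSizeError(f"n must be >= 1, got {self.n}")
        if self.dispersion < 0:
            raise EffectSizeError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.dispersion_kind not in ("sd", "se"):
            raise EffectSizeError(
                f"dispersion_kind must be 'sd' or 'se', got {self.dispersion_kind!r}"
            )

    @property
    def standard_error(self) -> float:
        """Standard error of the mean implied by the reported dispersion."""
        if self.dispersion_kind == "se":
            return float(self.dispersion)
        if self.n == 1:
            raise EffectSizeError(
                "standard error undefined: n=1 with a standard deviation"
            )
        return float(self.dispersion) / np.sqrt(self.n)


@dataclass(frozen=True)
class RawEffect:
    """Percent-change effect size with its sampling variance (percent^2)."""

    percent_change: float
    variance: float


@dataclass(frozen=True)
class TransformedEffect:
    """Signed cube root of the percent change and cube root of its variance."""

    y: float
    v: float


def percent_change(
    control: MeasurementSummary,
    alternative: MeasurementSummary,
    *,
    scale: float = 100.0,
    label: str | None = None,
) -> float:
    """Percent change in fitness from the control to the alternative condition.

    Positive values mean fitness is greater in the control (in-symbiosis /
    ambient / younger-host) condition; negative values mean fitness is
    greater in the alternative condition.

    ``scale`` defaults to 100 (percent); pass 1.0 for a plain fraction in
    sensitivity checks.
    """
    where = f" (record {label})" if label else ""
    if control.mean == 0:
        raise EffectSizeError(f"control mean is zero{where}: percent change undefined")
    if control.mean < 0 or alternative.mean < 0:
        warnings.warn(
            f"negative fitness mean{where}: fitness measures are expected to be "
            "non-negative; record flagged",
            stacklevel=2,
        )
    return scale * (control.mean - alternative.mean) / control.mean


def delta_method_variance(
    control: MeasurementSummary,
    alternative: MeasurementSummary,
    *,
    scale: float = 100.0,
    label: str | None = None,
) -> float:
    """First-order delta-method sampling variance of the percent change.

    With the ratio r = mean_alt / mean_control and squared standard errors
    of the two group means,

        var = scale^2 * r^2 * (SE_c^2 / mean_c^2 + SE_a^2 / mean_a^2),

    the standard variance for a ratio-of-means effect size with
    independent groups.
    """
    where = f" (record {label})" if label else ""
    if control.mean == 0 or alternative.mean == 0:
        raise EffectSizeError(f"zero group mean{where}: ratio variance undefined")
    se_c = control.standard_error
    se_a = alternative.standard_error
    r = alternative.mean / control.mean
    return (
        scale**2
        * r**2
        * (se_c**2 / control.mean**2 + se_a**2 / alternative.mean**2)
    )


def signed_cube_root(x):
    """Sign-preserving cube root, sign(x)*|x|^(1/3); odd and strictly increasing."""
    return np.cbrt(x)


def transform_record(
    effect: RawEffect, *, variance_mode: str = "literal"
) -> TransformedEffect:
    """Cube-root transform an effect size and its variance.

    ``variance_mode="literal"`` (default) cube-roots the variance itself,
    i.e. v = variance^(1/3).  ``variance_mode="delta"`` instead propagates
    the variance of the cube-rooted effect by the delta method,
    v = variance / (9 * |pc|^(4/3)), guarded for pc -> 0; available for
    sensitivity analysis.
    """
    if effect.variance < 0:
        raise EffectSizeError(f"negative variance {effect.variance}")
    y = float(signed_cube_root(effect.percent_change))
    if variance_mode == "literal":
        v = float(np.cbrt(effect.variance))
    elif variance_mode == "delta":
        pc = abs(effect.percent_change)
        if pc < 1e-8:
            raise EffectSizeError(
                "delta-method transform undefined for percent change ~ 0"
            )
        v = float(effect.variance / (9.0 * pc ** (4.0 / 3.0)))
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    return TransformedEffect(y=y, v=v)


_REQUIRED_RAW = ["control_mean", "control_disp", "control_n", "alt_mean", "alt_disp", "alt_n"]


def compute_effect_table(
    df: pd.DataFrame,
    *,
    scale: float = 100.0,
    variance_mode: str = "literal",
) -> pd.DataFrame:
    """Augment an effect-size table with percent_change, variance, y and v.

    Rows carrying precomputed ``percent_change`` and ``variance`` are used
    as-is; all other rows must provide the raw two-group summary columns
    (control_mean, control_disp, control_n, alt_mean, alt_disp, alt_n and
    optionally disp_kind in {sd, se}, default sd).  Rows with a zero
    control mean are rejected with their ids listed.
    """
    out = df.copy()
    n = len(out)
    pc = np.full(n, np.nan)
    var = np.full(n, np.nan)

    has_pre = (
        "percent_change" in out.columns
        and "variance" in out.columns
    )
    pre_mask = (
        out["percent_change"].notna() & out["variance"].notna()
        if has_pre
        else pd.Series(False, index=out.index)
    )

    ids = (
        out["effect_id"].astype(str)
        if "effect_id" in out.columns
        else out.index.astype(str)
    )
    bad: list[str] = []
    for pos, (idx, row) in enumerate(out.iterrows()):
        if has_pre and pre_mask.loc[idx]:
            pc[pos] = row["percent_change"]
            var[pos] = row["variance"]
            continue
        missing = [c for c in _REQUIRED_RAW if c not in out.columns or pd.isna(row[c])]
        if missing:
            bad.append(f"{ids.loc[idx]} (missing {', '.join(missing)})")
            continue
        kind = str(row.get("disp_kind", "sd")) if "disp_kind" in out.columns else "sd"
        if kind not in ("sd", "se") or pd.isna(row.get("disp_kind", "sd")):
            kind = "sd"
        try:
            ctrl = MeasurementSummary(
                float(row["control_mean"]), float(row["control_disp"]),
                int(row["control_n"]), kind,
            )
            alt = MeasurementSummary(
                float(row["alt_mean"]), float(row["alt_disp"]),
                int(row["alt_n"]), kind,
            )
            pc[pos] = percent_change(ctrl, alt, scale=scale, label=str(ids.loc[idx]))
            var[pos] = delta_method_variance(
                ctrl, alt, scale=scale, label=str(ids.loc[idx])
            )
        except EffectSizeError as err:
            bad.append(f"{ids.loc[idx]} ({err})")
    if bad:
        raise EffectSizeError(
            "records could not be converted to effect sizes: " + "; ".join(bad)
        )

    out["percent_change"] = pc
    out["variance"] = var
    transformed = [
        transform_record(RawEffect(p, w), variance_mode=variance_mode)
        for p, w in zip(pc, var)
    ]
    out["y"] = [t.y for t in transformed]
    out["v"] = [t.v for t in transformed]
    return out
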