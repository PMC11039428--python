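"""Multilevel random-effects meta-analysis fitted by REML.

The model for a vector of transformed effect sizes y with known
heteroscedastic sampling variances v is

    y = X beta + u_study + u_phylo + u_within + e,

where e_i ~ N(0, v_i) is fixed, u_study gives records of one study a
shared deviation with variance sigma2_study, u_within is a record-level
deviation with variance sigma2_within, and u_phylo is multivariate
normal with covariance sigma2_phylo * R for a Brownian-motion tip
correlation matrix R lifted to records.  The marginal covariance is

    M = diag(v) + sigma2_study * S + sigma2_within * I + sigma2_phylo * Z R Z',

with S the same-study indicator.  Variance components are estimated by
restricted maximum likelihood (bound-constrained quasi-Newton with an
analytic gradient and multiple starts); fixed effects follow by GLS at
the optimum.  Moderators are tested with Wald z statistics per
coefficient and an omnibus chi-square QM statistic for the moderator
block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
from scipy import stats

__all__ = [
    "FitError",
    "VarianceComponents",
    "ModelSpec",
    "MetaFit",
    "WaldResult",
    "build_design",
    "make_spec",
    "marginal_covariance",
    "reml_loglik",
    "fit_reml",
    "wald_tests",
]

V_FLOOR = 1e-10


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components on the transformed-effect scale (all >= 0)."""

    study: float = 0.0
    within: float = 0.0
    phylo: float = 0.0

    def __post_init__(self) -> None:
        for name in ("study", "within", "phylo"):
            if getattr(self, name) < 0:
                raise FitError(f"sigma2_{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_study": self.study,
            "sigma2_within": self.within,
            "sigma2_phylo": self.phylo,
        }


@dataclass
class DesignInfo:
    X: np.ndarray
    column_names: list[str]
    moderator_block: list[int]
    kept: np.ndarray  # boolean mask over the input records
    n_dropped: int


def build_design(records: pd.DataFrame, moderator: str | None) -> DesignInfo:
    """Intercept (+ moderator) fixed-effect design matrix.

    A categorical moderator with k observed levels contributes k-1 dummy
    columns against the alphabetically first level, so the omnibus QM
    test has df = k-1; a numeric moderator contributes one centered
    column (df = 1).  Records with a missing moderator value are dropped
    (mask returned; count logged via a warning).
    """
    n = len(records)
    if moderator is None:
        return DesignInfo(np.ones((n, 1)), ["intercept"], [], np.ones(n, bool), 0)
    if moderator not in records.columns:
        raise FitError(f"moderator column {moderator!r} not in records")
    col = records[moderator]
    kept = col.notna().to_numpy()
    n_dropped = int((~kept).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} records with missing {moderator!r}", stacklevel=2
        )
    col = col[kept]
    if pd.api.types.is_numeric_dtype(col):
        x = col.to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(x)), x - x.mean()])
        return DesignInfo(X, ["intercept", moderator], [1], kept, n_dropped)
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise FitError(
            f"moderator {moderator!r} has a single observed level {levels}"
        )
    ref, others = levels[0], levels[1:]
    X = np.ones((len(col), 1 + len(others)))
    names = ["intercept"]
    vals = col.astype(str).to_numpy()
    for j, lev in enumerate(others, start=1):
        X[:, j] = (vals == lev).astype(float)
        names.append(f"{moderator}[{lev}]")
    return DesignInfo(X, names, list(range(1, 1 + len(others))), kept, n_dropped)


@dataclass
class ModelSpec:
    """Aligned response, known variances, design and random structures."""

    y: np.ndarray
    v: np.ndarray
    X: np.ndarray
    column_names: list[str]
    moderator_block: list[int] = field(default_factory=list)
    study: np.ndarray | None = None          # study id per record
    R: np.ndarray | None = None              # tip-by-tip correlation
    tip_index: np.ndarray | None = None      # record -> row of R
    record_ids: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if np.any(v < 0):
            raise FitError("negative sampling variances")
        if np.any(v < V_FLOOR):
            warnings.warn(
                f"{int((v < V_FLOOR).sum())} sampling variances below "
                f"{V_FLOOR:g} floored",
                stacklevel=2,
            )
            v = np.maximum(v, V_FLOOR)
        self.v = v
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if not (len(self.v) == n and self.X.shape[0] == n):
            raise FitError("y, v and X are not aligned")
        if self.study is not None:
            self.study = np.asarray(self.study)
            if len(self.study) != n:
                raise FitError("study vector not aligned")
        if (self.R is None) != (self.tip_index is None):
            raise FitError("R and tip_index must be supplied together")
        if self.R is not None:
            self.R = np.asarray(self.R, dtype=float)
            self.tip_index = np.asarray(self.tip_index, dtype=int)
            if len(self.tip_index) != n:
                raise FitError("tip_index not aligned")
            if not np.allclose(self.R, self.R.T, atol=1e-10):
                raise FitError("phylogenetic correlation matrix not symmetric")
            w = np.linalg.eigvalsh(self.R)
            if w.min() < -1e-8:
                raise FitError(
                    f"phylogenetic correlation matrix not PSD "
                    f"(min eigenvalue {w.min():.3e})"
                )
        if self.record_ids is None:
            self.record_ids = list(range(n))

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def active_components(self) -> list[str]:
        comps = []
        if self.study is not None:
            comps.append("study")
        comps.append("within")
        if self.R is not None:
            comps.append("phylo")
        return comps

    def r_expanded(self) -> np.ndarray | None:
        if self.R is None:
            return None
        return self.R[np.ix_(self.tip_index, self.tip_index)]

    def drop_record(self, pos: int) -> "ModelSpec":
        """Spec with record at position ``pos`` removed (design columns that
        become empty are dropped; the caller compares shared coefficients)."""
        keep = np.ones(self.n, bool)
        keep[pos] = False
        X = self.X[keep]
        nonzero = [j for j in range(X.shape[1]) if np.any(X[:, j] != 0)]
        block = [nonzero.index(j) for j in self.moderator_block if j in nonzero]
        return ModelSpec(
            y=self.y[keep],
            v=self.v[keep],
            X=X[:, nonzero],
            column_names=[self.column_names[j] for j in nonzero],
            moderator_block=block,
            study=None if self.study is None else self.study[keep],
            R=self.R,
            tip_index=None if self.tip_index is None else self.tip_index[keep],
            record_ids=[r for r, k in zip(self.record_ids, keep) if k],
        )


def make_spec(
    records: pd.DataFrame,
    *,
    moderator: str | None = None,
    corr=None,
    tip_col: str = "tip_label",
    study_col: str = "study_id",
    y_col: str = "y",
    v_col: str = "v",
    id_col: str = "effect_id",
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from an effect-size table.

    ``corr`` is a :class:`symmeta.phylo.CorrelationMatrix` (or ``None``
    for a non-phylogenetic model); every record's ``tip_col`` label must
    then be a tip of the matrix.
    """
    design = build_design(records, moderator)
    df = records.loc[design.kept]
    R = tip_index = None
    if corr is not None:
        if tip_col not in df.columns:
            raise FitError(f"records lack a {tip_col!r} column for tip mapping")
        pos = {lab: i for i, lab in enumerate(corr.labels)}
        missing = sorted(set(df[tip_col].astype(str)) - set(pos))
        if missing:
            raise FitError(f"records map to tips absent from the tree: {missing}")
        R = corr.matrix
        tip_index = df[tip_col].astype(str).map(pos).to_numpy()
    return ModelSpec(
        y=df[y_col].to_numpy(dtype=float),
        v=df[v_col].to_numpy(dtype=float),
        X=design.X,
        column_names=design.column_names,
        moderator_block=design.moderator_block,
        study=df[study_col].to_numpy() if study_col in df.columns else None,
        R=R,
        tip_index=tip_index,
        record_ids=(
            df[id_col].tolist() if id_col in df.columns else list(df.index)
        ),
    )


def _study_indicator(study: np.ndarray) -> np.ndarray:
    return (study[:, None] == study[None, :]).astype(float)


def marginal_covariance(vc: VarianceComponents, spec: ModelSpec) -> np.ndarray:
    """M = diag(v) + sigma2_study*S + sigma2_within*I + sigma2_phylo*R_records."""
    M = np.diag(spec.v) + vc.within * np.eye(spec.n)
    if spec.study is not None and vc.study != 0:
        M += vc.study * _study_indicator(spec.study)
    if spec.R is not None and vc.phylo != 0:
        M += vc.phylo * spec.r_expanded()
    return M


def _loglik_core(vc: VarianceComponents, spec: ModelSpec, want_grad: bool):
    n, p = spec.n, spec.p
    M = marginal_covariance(vc, spec)
    try:
        L = sla.cholesky(M, lower=True)
    except np.linalg.LinAlgError as err:
        raise FitError(f"marginal covariance not positive definite: {err}") from err
    logdet_M = 2.0 * np.log(np.diag(L)).sum()
    Minv_X = sla.cho_solve((L, True), spec.X)
    XtMinvX = spec.X.T @ Minv_X
    sign, logdet_XtMX = np.linalg.slogdet(XtMinvX)
    if sign <= 0:
        raise FitError("X' M^-1 X singular: rank-deficient design")
    XtMX_inv = np.linalg.inv(XtMinvX)
    Minv_y = sla.cho_solve((L, True), spec.y)
    beta = XtMX_inv @ (spec.X.T @ Minv_y)
    resid_term = Minv_y - Minv_X @ beta  # = P y
    quad = float(spec.y @ resid_term)
    ll = -0.5 * (logdet_M + logdet_XtMX + quad + (n - p) * np.log(2.0 * np.pi))
    if not want_grad:
        return ll, beta, XtMX_inv, None
    Minv = sla.cho_solve((L, True), np.eye(n))
    P = Minv - Minv_X @ XtMX_inv @ Minv_X.T
    r = resid_term
    grad = {}
    for comp in spec.active_components():
        if comp == "within":
            tr = float(np.trace(P))
            qf = float(r @ r)
        elif comp == "study":
            S = _study_indicator(spec.study)
            tr = float(np.sum(P * S))
            qf = float(r @ S @ r)
        else:  # phylo
            G = spec.r_expanded()
            tr = float(np.sum(P * G))
            qf = float(r @ G @ r)
        grad[comp] = -0.5 * (tr - qf)
    return ll, beta, XtMX_inv, grad


def reml_loglik(vc: VarianceComponents, spec: ModelSpec) -> float:
    """Restricted log-likelihood at the given variance components."""
    return _loglik_core(vc, spec, want_grad=False)[0]


def _vc_from_vector(theta: np.ndarray, comps: list[str]) -> VarianceComponents:
    d = dict(zip(comps, np.maximum(theta, 0.0)))
    return VarianceComponents(
        study=d.get("study", 0.0),
        within=d.get("within", 0.0),
        phylo=d.get("phylo", 0.0),
    )


@dataclass
class MetaFit:
    """REML fit: fixed effects, tests, variance components, diagnostics."""

    beta: np.ndarray
    cov_beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    vc: VarianceComponents
    reml_loglik: float
    converged: bool
    n: int
    n_fixed: int
    column_names: list[str]
    moderator_block: list[int]
    qm: float | None = None
    qm_df: int | None = None
    qm_p: float | None = None
    optimizer: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "coefficients": [
                {
                    "name": nm,
                    "estimate": float(b),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                }
                for nm, b, s, z, p in zip(
                    self.column_names, self.beta, self.se, self.z, self.p
                )
            ],
            "variance_components": self.vc.as_dict(),
            "reml_loglik": float(self.reml_loglik),
            "converged": bool(self.converged),
            "optimizer": self.optimizer,
        }
        if self.qm is not None:
            out["QM"] = float(self.qm)
            out["QM_df"] = int(self.qm_df)
            out["QM_p"] = float(self.qm_p)
        return out


def _starting_points(spec: ModelSpec, comps: list[str]) -> list[np.ndarray]:
    # method-of-moments total heterogeneity: residual variance of a WLS fit
    # minus the mean sampling variance, clipped away from zero
    w = 1.0 / spec.v
    XtWX = spec.X.T @ (spec.X * w[:, None])
    beta0 = np.linalg.solve(XtWX, spec.X.T @ (spec.y * w))
    resid = spec.y - spec.X @ beta0
    tot = max(float(np.var(resid, ddof=min(spec.p, len(resid) - 1))) - float(spec.v.mean()), 0.0)
    floor = max(1e-3 * float(np.var(spec.y)) if np.var(spec.y) > 0 else 1e-3, 1e-6)
    tot = max(tot, floor)
    k = len(comps)
    starts = [np.zeros(k)]
    mom = np.zeros(k)
    mom[comps.index("within")] = tot
    starts.append(mom)
    starts.append(np.full(k, tot / k))
    return starts


def fit_reml(
    spec: ModelSpec,
    *,
    tol: float = 1e-10,
    starts: list | None = None,
) -> MetaFit:
    """Maximise the restricted likelihood over the non-negative variance
    components and return fixed effects, Wald tests and diagnostics.

    Runs a bound-constrained quasi-Newton search (analytic gradient) from
    several starting points — zeros, a method-of-moments point, and an
    equal split — and keeps the best optimum.
    """
    if spec.n <= spec.p:
        raise FitError(f"need more records ({spec.n}) than fixed effects ({spec.p})")
    comps = spec.active_components()
    if starts is None:
        starts = _starting_points(spec, comps)

    def objective(theta: np.ndarray):
        vc = _vc_from_vector(theta, comps)
        ll, _, _, grad = _loglik_core(vc, spec, want_grad=True)
        return -ll, -np.array([grad[c] for c in comps])

    best = None
    attempts = []
    for x0 in starts:
        try:
            res = scipy.optimize.minimize(
                objective,
                np.asarray(x0, dtype=float),
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * len(comps),
                options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
            )
        except FitError as err:
            attempts.append({"start": list(map(float, x0)), "error": str(err)})
            continue
        attempts.append(
            {
                "start": list(map(float, x0)),
                "fun": float(res.fun),
                "success": bool(res.success),
                "nit": int(res.nit),
            }
        )
        if res.success and (best is None or res.fun < best.fun - 1e-12):
            best = res
    if best is None:
        candidates = [a for a in attempts if "fun" in a]
        if not candidates:
            raise FitError(f"REML optimisation failed at every start: {attempts}")
        raise FitError(
            "REML optimisation did not converge from any start; best attempt: "
            f"{min(candidates, key=lambda a: a['fun'])}"
        )
    vc = _vc_from_vector(best.x, comps)
    ll, beta, cov_beta, grad = _loglik_core(vc, spec, want_grad=True)
    grad_vec = np.array([grad[c] for c in comps])
    interior = best.x > 1e-12
    grad_ok = bool(np.all(np.abs(grad_vec[interior]) < 1e-4 * (1.0 + abs(ll))))
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fit = MetaFit(
        beta=beta,
        cov_beta=cov_beta,
        se=se,
        z=z,
        p=p,
        vc=vc,
        reml_loglik=ll,
        converged=bool(best.success) and grad_ok,
        n=spec.n,
        n_fixed=spec.p,
        column_names=list(spec.column_names),
        moderator_block=list(spec.moderator_block),
        optimizer={
            "attempts": attempts,
            "gradient": dict(zip(comps, map(float, grad_vec))),
            "active_bounds": [c for c, i in zip(comps, interior) if not i],
        },
    )
    if spec.moderator_block:
        w = wald_tests(fit, spec.moderator_block)
        fit.qm, fit.qm_df, fit.qm_p = w.qm, w.qm_df, w.qm_p
    return fit


@dataclass(frozen=True)
class WaldResult:
    z: np.ndarray
    p: np.ndarray
    qm: float
    qm_df: int
    qm_p: float


def wald_tests(fit: MetaFit, block: list[int]) -> WaldResult:
    """Per-coefficient Wald z tests plus the omnibus QM chi-square test
    that the block of moderator coefficients is jointly zero."""
    if not block:
        raise FitError("empty moderator block: QM undefined (use the intercept z)")
    b = fit.beta[block]
    V = fit.cov_beta[np.ix_(block, block)]
    qm = float(b @ np.linalg.solve(V, b))
    df = len(block)
    return WaldResult(
        z=fit.z,
        p=fit.p,
        qm=qm,
        qm_df=df,
        qm_p=float(stats.chi2.sf(qm, df)),
    )
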