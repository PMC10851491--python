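"""Conditional logistic regression with redlining interaction terms.

The conditional likelihood of a case-crossover stratum s with rows r,
linear predictors eta_r and a single case row c is

    l_s(beta) = eta_c - log sum_r exp(eta_r),

the softmax log-probability of the case day among its referents.  Any
stratum-constant term — the intercept and the redlined main effect —
cancels, so the models estimate only time-varying effects and their
interactions with the time-invariant redlined flag:

* PM2.5 model:  eta = b1 * PM/10 + ns(TMEAN, 4) + ns(VP, 4)
                      + b_int * redlined * PM/10
* heat model:   eta = b1 * extreme + ns(VP, 4) + b_int * redlined * extreme

where ns(x, 4) is a 4-column natural cubic spline (interior knots at the
pooled 25/50/75% quantiles, boundary knots at the range, linear beyond
the boundary).  The likelihood is maximised by Newton-Raphson with
step-halving on the analytic gradient and Hessian; the covariance is the
inverse observed information.  Results are reported as odds ratios with
Wald 95% intervals, PM2.5 per 10 ug/m3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile

#: exposures accepted by :class:`ModelSpec`
PM_EXPOSURES = ("pm25", "pm25_ma_2", "pm25_ma_3", "pm25_ma_4", "pm25_ma_5")
HEAT_EXPOSURES = ("any_heat", "wave_day_1", "wave_day_2", "wave_day_3",
                  "wave_day_4", "singleton")


class DegenerateCovariateError(ValueError):
    """Covariate has too few distinct values to place spline knots."""


# ---------------------------------------------------------------------------
# natural cubic spline basis


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic spline basis with fixed knots.

    Built from all knots xi_1 < ... < xi_K (boundary + interior) via the
    truncated-power representation with the natural (linear-tail)
    constraint folded in:

        d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)
        N_1(x) = x
        N_{k+1}(x) = d_k(x) - d_{K-1}(x),   k = 1..K-2

    giving K-1 columns: cubic between knots, C2 everywhere, and exactly
    linear outside the boundary knots.  With df=4 the interior knots sit
    at the 25/50/75% quantiles and K=5.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1

    @property
    def all_knots(self) -> np.ndarray:
        return np.r_[self.boundary_knots[0], self.interior_knots,
                     self.boundary_knots[1]]

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xi = self.all_knots
        K = xi.size

        def dk(k: int) -> np.ndarray:
            num = (np.clip(x - xi[k], 0, None) ** 3
                   - np.clip(x - xi[K - 1], 0, None) ** 3)
            return num / (xi[K - 1] - xi[k])

        d_last = dk(K - 2)
        cols = [x] + [dk(k) - d_last for k in range(K - 2)]
        return np.column_stack(cols)


def ns_basis(x, df: int = 4) -> tuple[np.ndarray, SplineBasis]:
    """Natural cubic spline design for covariate ``x`` with ``df`` columns.

    Interior knots at the quantiles i/df for i = 1..df-1 of ``x`` (the
    25/50/75% quantiles when df=4); boundary knots at the min and max.
    Returns ``(basis_matrix, basis)`` so the same knots can evaluate new
    points.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < df + 1:
        raise DegenerateCovariateError(
            f"need more than {df} distinct values to place {df - 1} interior knots"
        )
    probs = np.arange(1, df) / df
    interior = np.quantile(x, probs)
    lo, hi = float(x.min()), float(x.max())
    knots = np.unique(np.r_[lo, interior, hi])
    if knots.size < df + 1:
        raise DegenerateCovariateError(
            "quantile knots collide; covariate too discrete for a "
            f"df={df} natural spline"
        )
    basis = SplineBasis(
        interior_knots=tuple(float(k) for k in interior),
        boundary_knots=(lo, hi),
    )
    return basis.transform(x), basis


# ---------------------------------------------------------------------------
# conditional likelihood


def _stratum_layout(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets and sizes of contiguous stratum blocks."""
    change = np.r_[True, groups[1:] != groups[:-1]]
    starts = np.flatnonzero(change)
    counts = np.diff(np.r_[starts, groups.size])
    return starts, counts


def conditional_loglik(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Value, gradient and Hessian of the conditional log-likelihood.

    Rows must be sorted by stratum (``groups``) with exactly one case
    (``y`` true) per stratum.  Overflow is guarded by subtracting the
    within-stratum maximum of the linear predictor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    groups = np.asarray(groups)
    starts, counts = _stratum_layout(groups)
    cases_per = np.add.reduceat(y.astype(int), starts)
    if not np.all(cases_per == 1):
        raise ValueError("each stratum must contain exactly one case row")

    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    ez = np.exp(eta - np.repeat(m, counts))
    denom = np.add.reduceat(ez, starts)
    ll = float(eta[y].sum() - (np.log(denom) + m).sum())

    w = ez / np.repeat(denom, counts)  # within-stratum softmax weights
    grad = X[y].sum(axis=0) - X.T @ w
    WX = w[:, None] * X
    B = np.add.reduceat(WX, starts, axis=0)  # per-stratum weighted mean row
    hess = -(X.T @ WX - B.T @ B)
    return ll, grad, hess


@dataclass(frozen=True)
class ModelSpec:
    """One analysis cell: an exposure, its adjusters, and the interaction.

    ``exposure`` names either a PM2.5 column (lag 0 or a 2..5-day moving
    average, entered per ``scale`` = 10 ug/m3) or a binary heat exposure
    (any extreme day, a specific wave-day position, or a singleton
    extreme day).  PM2.5 models adjust for natural splines of TMEAN and
    VP; heat models for VP alone.  The interaction is redlined x exposure
    and is the estimand of interest; the redlined main effect is
    inestimable by design and deliberately absent.
    """

    exposure: str
    scale: float = 1.0
    adjust_tmean: bool = False
    spline_df: int = 4
    interaction: str = "redlined"

    @classmethod
    def pm25(cls, exposure: str = "pm25") -> "ModelSpec":
        if exposure not in PM_EXPOSURES:
            raise ValueError(f"unknown PM2.5 exposure {exposure!r}")
        return cls(exposure=exposure, scale=10.0, adjust_tmean=True)

    @classmethod
    def heat(cls, exposure: str = "any_heat") -> "ModelSpec":
        if exposure not in HEAT_EXPOSURES:
            raise ValueError(f"unknown heat exposure {exposure!r}")
        return cls(exposure=exposure, scale=1.0, adjust_tmean=False)


def _exposure_column(strata: pd.DataFrame, name: str) -> np.ndarray:
    if name == "any_heat":
        return strata["extreme"].to_numpy(dtype=float)
    if name.startswith("wave_day_"):
        j = int(name.rsplit("_", 1)[1])
        return (strata["wave_day"] == j).to_numpy(dtype=float)
    if name == "singleton":
        return strata["singleton"].to_numpy(dtype=float)
    return strata[name].to_numpy(dtype=float)


def build_design(
    strata: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], dict]:
    """Design matrix for one analysis over a long strata frame.

    Strata containing a missing value in any needed column are dropped
    whole (counted in the returned info dict).  Returns
    ``(X, y, groups, names, info)`` with rows sorted by stratum.
    """
    df = strata.sort_values(["record_id", "date"]).reset_index(drop=True)
    needed = ["tmean", "vp"] if spec.adjust_tmean else ["vp"]
    expo = _exposure_column(df, spec.exposure)
    bad = np.isnan(expo) | df[needed].isna().any(axis=1).to_numpy()
    drop_ids = set(df.loc[bad, "record_id"])
    if drop_ids:
        df = df[~df["record_id"].isin(drop_ids)].reset_index(drop=True)
        expo = _exposure_column(df, spec.exposure)

    x_exp = expo / spec.scale
    red = df[spec.interaction].to_numpy(dtype=float)
    cols = [x_exp]
    names = [spec.exposure]
    info: dict = {"n_strata_dropped_missing": len(drop_ids)}
    if spec.adjust_tmean:
        B, basis = ns_basis(df["tmean"].to_numpy(float), spec.spline_df)
        cols.extend(B.T)
        names.extend(f"ns_tmean_{i+1}" for i in range(B.shape[1]))
        info["tmean_basis"] = basis
    Bv, vbasis = ns_basis(df["vp"].to_numpy(float), spec.spline_df)
    cols.extend(Bv.T)
    names.extend(f"ns_vp_{i+1}" for i in range(Bv.shape[1]))
    info["vp_basis"] = vbasis
    cols.append(red * x_exp)
    names.append(f"{spec.interaction}_x_{spec.exposure}")

    X = np.column_stack(cols)
    y = df["is_case"].to_numpy(dtype=bool)
    groups = df["record_id"].to_numpy()
    info["n_strata"] = int(pd.unique(groups).size)
    return X, y, groups, names, info


@dataclass
class FitResult:
    """Maximum conditional likelihood fit of one analysis cell."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_strata: int
    names: list[str]
    spec: ModelSpec | None = None
    message: str = ""
    interaction_index: int = -1

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def odds_ratios(self) -> pd.DataFrame:
        """Per-term OR, Wald 95% CI and percent-excess-risk transform.

        Coefficients already sit on the reporting scale (PM2.5 per
        10 ug/m3), so OR = exp(beta).
        """
        se = self.se
        lo = np.exp(self.beta - Z_95 * se)
        hi = np.exp(self.beta + Z_95 * se)
        orr = np.exp(self.beta)
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.beta,
                "se": se,
                "or": orr,
                "ci_low": lo,
                "ci_high": hi,
                # direct (OR - 1) x 100 so degenerate fits surface as
                # extreme values rather than an exception
                "pct_excess": (orr - 1.0) * 100.0,
            }
        )

    @property
    def interaction(self) -> pd.Series:
        """The redlined-interaction row of :meth:`odds_ratios`."""
        return self.odds_ratios().iloc[self.interaction_index]


def fit_clogit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: Sequence[str] | None = None,
    max_iter: int = 60,
    ll_rtol: float = 1e-9,
    grad_tol: float = 1e-6,
) -> FitResult:
    """Newton-Raphson maximisation of the conditional likelihood.

    Step-halving keeps every iteration an ascent; convergence requires a
    relative log-likelihood change below ``ll_rtol`` and a gradient
    maximum below ``grad_tol``.  Separation (a diverging coefficient) or
    a singular information matrix yields ``converged=False`` with a
    diagnostic message rather than silent output.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    names = list(names) if names is not None else [f"b{i}" for i in range(p)]
    beta = np.zeros(p)
    ll, grad, hess = conditional_loglik(X, y, groups, beta)
    converged = False
    message = "max_iter reached"
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix (non-identifiable design)"
            break
        # step-halving: never accept a decrease
        t, ll_new = 1.0, -np.inf
        for _h in range(30):
            cand = beta + t * step
            ll_new, g_new, h_new = conditional_loglik(X, y, groups, cand)
            if ll_new >= ll:
                break
            t /= 2.0
        if ll_new < ll:
            message = "step-halving failed to ascend"
            break
        beta, grad, hess = cand, g_new, h_new
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        ll = ll_new
        if np.abs(beta).max() > 30:
            message = "separation suspected: coefficient diverging"
            break
        if rel < ll_rtol and np.abs(grad).max() < grad_tol:
            converged = True
            message = "converged"
            break
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
        message = "singular Hessian at optimum"
    if not converged:
        log.warning("conditional logit did not converge: %s", message)
    starts, _ = _stratum_layout(np.asarray(groups))
    return FitResult(
        beta=beta,
        covariance=cov,
        loglik=ll,
        converged=converged,
        n_strata=int(starts.size),
        names=names,
        message=message,
        interaction_index=p - 1,
    )


def fit_model(strata: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Build the design for ``spec`` and maximise the conditional likelihood."""
    X, y, groups, names, info = build_design(strata, spec)
    res = fit_clogit(X, y, groups, names)
    res.spec = spec
    res.n_strata = info["n_strata"]
    return res


def or_to_percent(or_value: float) -> float:
    """Odds ratio -> percent excess daily risk: (OR - 1) x 100."""
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    return (or_value - 1.0) * 100.0
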