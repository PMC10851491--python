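"""Spline basis, conditional likelihood, Newton fitter, OR reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from redlinex.model import (
    DegenerateCovariateError,
    ModelSpec,
    build_design,
    conditional_loglik,
    fit_clogit,
    fit_model,
    ns_basis,
    or_to_percent,
)


# ---------------------------------------------------------------------------
# natural cubic splines


def _ns_oracle_basis(x, interior, boundary):
    """Independent natural-spline construction: cubic B-spline basis with
    the zero-second-derivative-at-boundary constraint imposed via a null
    space projection.  Spans the same function space as any natural
    cubic spline basis on the same knots (plus the constant)."""
    t = np.r_[[boundary[0]] * 4, interior, [boundary[1]] * 4]
    nb = len(interior) + 4
    eye = np.eye(nb)
    d2 = np.array(
        [
            [BSpline(t, eye[i], 3).derivative(2)(b) for i in range(nb)]
            for b in boundary
        ]
    )
    Z = null_space(d2)
    B = BSpline.design_matrix(np.clip(x, *boundary), t, 3).toarray()
    return B @ Z


class TestNsBasis:
    def test_linear_beyond_boundary_knots(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, 300)
        _, basis = ns_basis(x, df=4)
        lo, hi = basis.boundary_knots
        for side in (np.linspace(hi + 0.5, hi + 6, 12), np.linspace(lo - 6, lo - 0.5, 12)):
            vals = basis.transform(side)
            second_diff = np.diff(vals, n=2, axis=0)
            assert np.allclose(second_diff, 0, atol=1e-8)

    def test_linear_functions_in_span(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-3, 7, 250)
        B, _ = ns_basis(x, df=4)
        design = np.column_stack([np.ones_like(x), B])
        target = 2.5 * x - 1.0
        resid = target - design @ np.linalg.lstsq(design, target, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

    def test_spans_independent_bspline_construction(self):
        """Both bases span the natural cubic spline space on the same
        knots: each is exactly reproduced by regression on the other."""
        rng = np.random.default_rng(2)
        x = rng.normal(10, 4, 200)
        B, basis = ns_basis(x, df=4)
        H = _ns_oracle_basis(x, list(basis.interior_knots), basis.boundary_knots)

        ours = np.column_stack([np.ones_like(x), B])
        theirs = np.column_stack([np.ones_like(x), H])
        for A, C in ((ours, theirs), (theirs, ours)):
            coef, *_ = np.linalg.lstsq(A, C, rcond=None)
            resid = C - A @ coef
            assert np.abs(resid).max() < 1e-7

    def test_df4_places_quartile_knots(self):
        x = np.arange(101, dtype=float)
        _, basis = ns_basis(x, df=4)
        assert basis.interior_knots == (25.0, 50.0, 75.0)
        assert basis.boundary_knots == (0.0, 100.0)
        assert basis.df == 4

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(DegenerateCovariateError):
            ns_basis([1.0, 2.0, 1.0, 2.0, 1.0], df=4)


# ---------------------------------------------------------------------------
# conditional likelihood


def _random_strata(rng, n_strata=100, p=3, size_choices=(2, 3, 4, 5)):
    rows_X, rows_y, rows_g = [], [], []
    for s in range(n_strata):
        m = rng.choice(size_choices)
        X = rng.normal(0, 1, (m, p))
        y = np.zeros(m, dtype=bool)
        y[rng.integers(0, m)] = True
        rows_X.append(X)
        rows_y.append(y)
        rows_g.append(np.full(m, s))
    return np.vstack(rows_X), np.concatenate(rows_y), np.concatenate(rows_g)


def _brute_loglik(X, y, groups, beta):
    ll = 0.0
    for g in np.unique(groups):
        idx = groups == g
        eta = X[idx] @ beta
        ll += eta[y[idx]][0] - np.log(np.exp(eta).sum())
    return ll


class TestConditionalLoglik:
    def test_null_beta_gives_log_stratum_size(self):
        X = np.zeros((4, 2))
        y = np.array([True, False, False, False])
        g = np.zeros(4)
        ll, _, _ = conditional_loglik(X, y, g, np.zeros(2))
        assert ll == pytest.approx(-np.log(4))

    def test_stratum_constant_covariate_has_zero_gradient(self):
        rng = np.random.default_rng(3)
        X, y, g = _random_strata(rng, n_strata=40, p=2)
        # append a column constant within each stratum (a redlined main effect)
        const = np.array([hash(int(s)) % 2 for s in g], dtype=float)
        Xc = np.column_stack([X, const])
        beta = rng.normal(0, 0.5, 3)
        _, grad, _ = conditional_loglik(Xc, y, g, beta)
        assert grad[-1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_enumeration_and_finite_differences(self):
        rng = np.random.default_rng(4)
        X, y, g = _random_strata(rng, n_strata=100, p=3)
        beta = rng.normal(0, 0.4, 3)
        ll, grad, hess = conditional_loglik(X, y, g, beta)
        assert ll == pytest.approx(_brute_loglik(X, y, g, beta), rel=1e-12)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            fd = (_brute_loglik(X, y, g, beta + e) - _brute_loglik(X, y, g, beta - e)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)
            fd_h = (
                conditional_loglik(X, y, g, beta + e)[1]
                - conditional_loglik(X, y, g, beta - e)[1]
            ) / (2 * eps)
            assert np.allclose(hess[j], fd_h, rtol=1e-5, atol=1e-6)

    def test_requires_exactly_one_case(self):
        X = np.zeros((4, 1))
        y = np.array([True, True, False, False])
        with pytest.raises(ValueError):
            conditional_loglik(X, y, np.zeros(4), np.zeros(1))

    def test_overflow_guarded(self):
        X = np.array([[1000.0], [0.0]])
        y = np.array([True, False])
        ll, grad, _ = conditional_loglik(X, y, np.zeros(2), np.array([1.0]))
        assert np.isfinite(ll) and np.isfinite(grad).all()


# ---------------------------------------------------------------------------
# fitting


def _matched_pairs(n_case_exposed, n_control_exposed):
    rows = []
    s = 0
    for _ in range(n_case_exposed):
        rows += [(s, 1.0, True), (s, 0.0, False)]
        s += 1
    for _ in range(n_control_exposed):
        rows += [(s, 0.0, True), (s, 1.0, False)]
        s += 1
    g, x, y = map(np.array, zip(*rows))
    return x[:, None], y.astype(bool), g


class TestFitClogit:
    def test_matched_pair_closed_form_or(self):
        """1:1 strata with 40 case-exposed-only vs 20 control-exposed-only
        discordant pairs: conditional MLE OR equals 40/20 = 2."""
        X, y, g = _matched_pairs(40, 20)
        res = fit_clogit(X, y, g)
        assert res.converged
        assert np.exp(res.beta[0]) == pytest.approx(2.0, abs=1e-6)

    def test_agrees_with_statsmodels_conditional_logit(self):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(5)
        X, y, g = _random_strata(rng, n_strata=150, p=3, size_choices=(4, 5))
        # plant a real effect so the comparison is away from zero
        bump = rng.normal(0.8, 0.1)
        for s in np.unique(g):
            idx = np.flatnonzero(g == s)
            pick = idx[np.argmax(X[idx, 0] * bump + rng.gumbel(size=idx.size))]
            y[idx] = False
            y[pick] = True
        ours = fit_clogit(X, y, g)
        ref = ConditionalLogit(y.astype(int), X, groups=g).fit(disp=False)
        assert ours.converged
        # agreement limited by statsmodels' own optimizer tolerance
        assert np.allclose(ours.beta, ref.params, atol=1e-4)
        assert np.allclose(ours.se, ref.bse, rtol=1e-3)

    def test_score_zero_and_hessian_negative_definite_at_optimum(self):
        rng = np.random.default_rng(6)
        X, y, g = _random_strata(rng, n_strata=120, p=3, size_choices=(4, 5))
        res = fit_clogit(X, y, g)
        _, grad, hess = conditional_loglik(X, y, g, res.beta)
        assert np.abs(grad).max() < 1e-6
        assert (np.linalg.eigvalsh(hess) < 0).all()
        assert np.allclose(res.covariance, res.covariance.T)

    def test_separation_reported_not_silent(self):
        # exposure perfectly predicts the case in every stratum
        rows = []
        for s in range(30):
            rows += [(s, 1.0, True), (s, 0.0, False)]
        g, x, y = map(np.array, zip(*rows))
        res = fit_clogit(x[:, None], y.astype(bool), g)
        assert not res.converged
        assert res.message != "converged"


class TestModelSpecs:
    def test_pm25_design_has_expected_terms(self, strata_set):
        X, y, groups, names, info = build_design(strata_set, ModelSpec.pm25())
        assert names[0] == "pm25" and names[-1] == "redlined_x_pm25"
        assert sum(n.startswith("ns_tmean") for n in names) == 4
        assert sum(n.startswith("ns_vp") for n in names) == 4
        assert X.shape[1] == 10

    def test_heat_design_omits_temperature_spline(self, strata_set):
        X, _, _, names, _ = build_design(strata_set, ModelSpec.heat())
        assert not any(n.startswith("ns_tmean") for n in names)
        assert X.shape[1] == 6

    def test_per10_scaling_equivalence(self, strata_set):
        """Fitting PM2.5 in ug/m3 and rescaling the coefficient equals
        fitting PM2.5/10 directly."""
        res10 = fit_model(strata_set, ModelSpec.pm25())
        raw = fit_model(
            strata_set,
            ModelSpec(exposure="pm25", scale=1.0, adjust_tmean=True),
        )
        assert res10.beta[0] == pytest.approx(10 * raw.beta[0], rel=1e-5)
        assert res10.beta[-1] == pytest.approx(10 * raw.beta[-1], rel=1e-5)

    def test_stratum_constant_offset_leaves_fit_unchanged(self, strata_set):
        """Injecting a fake redlined main effect (stratum-constant column
        cancels in the conditional likelihood) must not move the MLE."""
        spec = ModelSpec.heat()
        X, y, g, names, _ = build_design(strata_set, spec)
        base = fit_clogit(X, y, g, names)
        # a stratum-constant covariate entering eta with coefficient 1
        shift = pd.Series(g).map(lambda s: (hash(s) % 5) - 2.0).to_numpy()
        Xa = np.column_stack([X, shift])
        beta_a = np.r_[base.beta, 1.0]
        ll_shifted, grad_a, _ = conditional_loglik(Xa, y, g, beta_a)
        assert ll_shifted == pytest.approx(base.loglik)
        assert grad_a[-1] == pytest.approx(0.0, abs=1e-8)

    def test_missing_moving_average_strata_dropped_whole(self, strata_set):
        spec = ModelSpec.pm25("pm25_ma_5")
        X, y, g, _, info = build_design(strata_set, spec)
        assert info["n_strata"] + info["n_strata_dropped_missing"] == strata_set["record_id"].nunique()
        # remaining strata are intact (4 or 5 rows, one case)
        sizes = pd.Series(g).groupby(pd.Series(g)).size()
        assert sizes.isin([4, 5]).all()


class TestOrToPercent:
    @pytest.mark.parametrize(
        "orv,pct", [(1.0093, 0.93), (1.0, 0.0), (2.0, 100.0), (1.0218, 2.18)]
    )
    def test_percent_excess_transform(self, orv, pct):
        assert or_to_percent(orv) == pytest.approx(pct, abs=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            or_to_percent(0.0)
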