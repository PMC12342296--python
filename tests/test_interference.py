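"""Gamma interference fit, CoC curve, and interference distance."""

import math

import numpy as np
import pytest
from scipy import stats

import meioco as m
from meioco.interference import CoCCurve

from conftest import make_cell


def grid_search_gamma_shape(x, lo=0.5, hi=20.0, step=0.01):
    """Brute-force profile-likelihood grid over the shape parameter.

    For each candidate shape k the rate is profiled out analytically
    (rate = k / mean), leaving a 1-D scan — the independent oracle for
    the digamma-equation solver.
    """
    x = np.asarray(x, dtype=float)
    ks = np.arange(lo, hi + step / 2, step)
    n, sx, slx = len(x), x.sum(), np.log(x).sum()
    mean = sx / n
    ll = n * (ks * np.log(ks / mean) - [math.lgamma(k) for k in ks]) + (ks - 1) * slx - ks / mean * sx
    return float(ks[np.argmax(ll)])


def naive_coc(occ):
    """Double-loop counting CoC oracle (mirrors the definition literally)."""
    occ = np.asarray(occ, dtype=bool)
    n_arms, n_int = occ.shape
    by_sep = {}
    for i in range(n_int):
        for j in range(i + 1, n_int):
            fi = sum(occ[a, i] for a in range(n_arms)) / n_arms
            fj = sum(occ[a, j] for a in range(n_arms)) / n_arms
            if fi * fj == 0:
                continue
            obs = sum(occ[a, i] and occ[a, j] for a in range(n_arms)) / n_arms
            by_sep.setdefault((j - i) / n_int, []).append(obs / (fi * fj))
    seps = sorted(by_sep)
    return seps, [float(np.mean(by_sep[s])) for s in seps]


def two_co_cells(pairs, length=100.0):
    """One 17-SC cell per pair of focus positions (on SC rank 5)."""
    cells = []
    for k, (a, b) in enumerate(pairs):
        specs = []
        for i, L in enumerate(m.DEFAULT_SC_PROFILE_UM):
            morph = "metacentric" if (i + 1) in (1, 4) else "acrocentric"
            cen = 0.45 * L if morph == "metacentric" else 0.0
            foci = sorted([a, b]) if i == 4 else []
            specs.append((L, foci, cen, morph))
        cells.append(make_cell(f"c{k}", specs))
    return m.rank_dataset(m.Dataset(cells))[0]


class TestInterFocusDistances:
    def test_hand_distance_raw_and_normalized(self):
        L5 = m.DEFAULT_SC_PROFILE_UM[4]
        ds = two_co_cells([(0.2 * L5, 0.7 * L5)])
        assert m.inter_focus_distances(ds)[0] == pytest.approx(0.5 * L5)
        assert m.inter_focus_distances(ds, normalize=True)[0] == pytest.approx(0.5)

    def test_only_two_focus_scs_contribute(self, ds28):
        d = m.inter_focus_distances(ds28)
        n_two = sum(sc.n_foci == 2 for r in ds28.records for sc in r.scs)
        assert len(d) == n_two

    def test_no_two_focus_scs_is_empty_result_error(self):
        ds = two_co_cells([])
        with pytest.raises(m.EmptySelectionError):
            m.inter_focus_distances(two_co_cells([(1.0, 2.0)]).select(temperature=99.0))
        with pytest.raises(m.EmptySelectionError):
            # cells exist but carry no two-focus SC
            m.inter_focus_distances(
                m.rank_dataset(m.Dataset([make_cell("c0", [
                    (L, [], 0.45 * L if (i + 1) in (1, 4) else 0.0,
                     "metacentric" if (i + 1) in (1, 4) else "acrocentric")
                    for i, L in enumerate(m.DEFAULT_SC_PROFILE_UM)])]))[0]
            )


class TestGammaFit:
    def test_exponential_draws_fit_shape_one(self):
        rng = np.random.default_rng(61)
        fit = m.fit_gamma_ml(rng.exponential(1.0, 3000))
        assert fit.shape == pytest.approx(1.0, rel=0.1)

    def test_gamma_8_16_recovered_and_matches_grid_oracle(self):
        rng = np.random.default_rng(62)
        x = rng.gamma(8.0, 1.0 / 16.0, 3000)
        fit = m.fit_gamma_ml(x)
        assert fit.shape == pytest.approx(8.0, rel=0.1)
        assert fit.rate == pytest.approx(fit.shape / x.mean())
        assert abs(fit.shape - grid_search_gamma_shape(x)) <= 0.01

    def test_matches_grid_oracle_on_random_samples(self):
        rng = np.random.default_rng(63)
        for _ in range(20):
            true_shape = rng.uniform(0.8, 15.0)
            x = rng.gamma(true_shape, rng.uniform(0.05, 2.0), size=200)
            fit = m.fit_gamma_ml(x)
            assert abs(fit.shape - grid_search_gamma_shape(x)) <= 0.011

    def test_agrees_with_independent_ml_implementation(self):
        rng = np.random.default_rng(64)
        x = rng.gamma(5.0, 0.2, 1500)
        fit = m.fit_gamma_ml(x)
        a, _, scale = stats.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(a, rel=1e-4)
        assert fit.rate == pytest.approx(1.0 / scale, rel=1e-4)

    def test_loglik_is_maximal_near_estimate(self):
        rng = np.random.default_rng(65)
        x = rng.gamma(4.0, 0.5, 500)
        fit = m.fit_gamma_ml(x)

        def ll(shape, rate):
            return float(len(x) * (shape * np.log(rate) - math.lgamma(shape))
                         + (shape - 1) * np.log(x).sum() - rate * x.sum())

        assert fit.loglik == pytest.approx(ll(fit.shape, fit.rate))
        assert fit.loglik >= ll(fit.shape * 1.05, fit.rate)
        assert fit.loglik >= ll(fit.shape * 0.95, fit.rate)

    def test_ci_covers_truth_here(self):
        rng = np.random.default_rng(66)
        fit = m.fit_gamma_ml(rng.gamma(6.0, 0.1, 2000))
        lo, hi = fit.shape_ci
        assert lo < 6.0 < hi

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(m.DegenerateFitError):
            m.fit_gamma_ml([1.0] * 100)
        with pytest.raises(m.InsufficientDataError):
            m.fit_gamma_ml([1.0, 2.0])
        with pytest.raises(m.DegenerateFitError):
            m.fit_gamma_ml([0.0] + [1.0, 2.0] * 20)


class TestCoC:
    def test_hand_enumerated_toy(self):
        occ = np.array([[1, 1], [1, 0], [0, 1], [1, 1]], dtype=bool)
        curve = m.coc_from_occupancy(occ)
        assert curve.separations == (0.5,)
        assert curve.coc[0] == pytest.approx(0.5 / 0.5625)  # 0.888…

    def test_single_co_per_arm_gives_zero_everywhere(self):
        rng = np.random.default_rng(71)
        occ = np.zeros((400, 20), dtype=bool)
        occ[np.arange(400), rng.integers(0, 20, 400)] = True
        curve = m.coc_from_occupancy(occ)
        assert all(v == 0.0 for v in curve.coc)

    def test_poisson_arms_have_unit_coc(self):
        """Independently placed COs show no interference: CoC ≈ 1."""
        rng = np.random.default_rng(72)
        occ = []
        for _ in range(5000):
            pos = m.simulate_gamma_renewal(1.0, 2.0, rng)
            row = np.zeros(20, dtype=bool)
            row[np.minimum((pos * 20).astype(int), 19)] = True
            occ.append(row)
        curve = m.coc_from_occupancy(np.array(occ))
        assert curve.mean_coc() == pytest.approx(1.0, abs=0.05)
        assert max(abs(v - 1.0) for v in curve.coc) < 0.45  # sparse distal pairs

    def test_vectorized_equals_naive_loop_exactly(self):
        rng = np.random.default_rng(73)
        for _ in range(50):
            occ = rng.random((rng.integers(4, 30), rng.integers(2, 8))) < 0.4
            if not occ.any():
                continue
            seps, vals = naive_coc(occ)
            curve = m.coc_from_occupancy(occ)
            assert curve.separations == tuple(seps)
            assert np.allclose(curve.coc, vals, atol=1e-12)

    def test_dataset_route_matches_occupancy_route(self, ds28):
        occ = m.arm_occupancy(ds28, n_intervals=20)
        a = m.coc_from_occupancy(occ)
        b = m.coc_curve(ds28, n_intervals=20)
        assert a.separations == b.separations and np.allclose(a.coc, b.coc)
        # arms: 15 acrocentric + 2×2 metacentric arms per cell
        assert occ.shape[0] == 19 * len(ds28.pachytene_cells())

    def test_empty_occupancy_rejected(self):
        with pytest.raises(m.EmptySelectionError):
            m.coc_from_occupancy(np.empty((0, 20), dtype=bool))
        with pytest.raises(m.DegenerateFitError):
            m.coc_from_occupancy(np.zeros((10, 20), dtype=bool))


class TestInterferenceDistance:
    def test_already_above_threshold(self):
        curve = CoCCurve((0.1, 0.2), (1.2, 1.3), (1, 1), 10)
        assert m.interference_distance(curve) == (0.1, True)

    def test_linear_interpolation(self):
        curve = CoCCurve((0.5, 0.6), (0.8, 1.2), (1, 1), 10)
        dist, reached = m.interference_distance(curve)
        assert reached and dist == pytest.approx(0.55)

    def test_never_reached_flag(self):
        curve = CoCCurve((0.1, 0.5, 0.9), (0.2, 0.5, 0.8), (1, 1, 1), 10)
        dist, reached = m.interference_distance(curve)
        assert not reached and dist == 0.9

    def test_single_point_curve_rejected(self):
        with pytest.raises(m.MeiocoError):
            m.interference_distance(CoCCurve((0.5,), (0.9,), (1,), 10))

    def test_stronger_interference_pushes_distance_out(self):
        """ν=12 arms stay below CoC=1 out to larger separations than ν=4.

        Holds in the study-like density regime (≲1 CO per arm), where the
        crossing sits in the rising tail of the curve; at much higher CO
        densities the crossing instead tracks the mean inter-CO spacing.
        """
        wins = 0
        reps = 7
        for r in range(reps):
            curves = {}
            for nu in (4.0, 12.0):
                rng = np.random.default_rng(1000 + r)
                occ = []
                for _ in range(2500):
                    pos = m.simulate_gamma_renewal(nu, 0.8, rng)
                    row = np.zeros(20, dtype=bool)
                    if len(pos):
                        row[np.minimum((pos * 20).astype(int), 19)] = True
                    occ.append(row)
                curves[nu] = m.coc_from_occupancy(np.array(occ))
            d4, _ = m.interference_distance(curves[4.0])
            d12, _ = m.interference_distance(curves[12.0])
            if d12 > d4:
                wins += 1
        assert wins > reps / 2
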