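"""SC ranking, morphometry and centromere-referenced CO positions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meioco as m

from conftest import full_cell, make_cell


def reference_cell(cell_id="c1", scale=1.0, permute=None):
    """A cell whose SC lengths are the reference profile (optionally shuffled)."""
    specs = []
    for i, L in enumerate(m.DEFAULT_SC_PROFILE_UM):
        morph = "metacentric" if (i + 1) in (1, 4) else "acrocentric"
        cen = 0.45 * L * scale if morph == "metacentric" else 0.0
        specs.append((L * scale, [], cen, morph))
    if permute is not None:
        specs = [specs[i] for i in permute]
    return make_cell(cell_id, specs)


class TestRanking:
    def test_identity_on_reference_order(self):
        cell = reference_cell()
        ranked = m.rank_scs(cell)
        assert [sc.sc_rank for sc in ranked] == list(range(1, 18))

    def test_shuffled_input_recovers_length_order(self):
        rng = np.random.default_rng(1)
        perm = rng.permutation(17)
        cell = reference_cell(permute=perm)
        ranked = m.rank_scs(cell)
        by_rank = sorted(ranked, key=lambda sc: sc.sc_rank)
        assert [sc.length_um for sc in by_rank] == sorted(
            (sc.length_um for sc in cell.scs), reverse=True
        )
        assert [sc.morphology == "metacentric" for sc in by_rank] == [
            r in (1, 4) for r in range(1, 18)
        ]

    def test_metacentrics_pinned_to_reference_ranks_in_length_order(self):
        # make the 'shorter' metacentric longer than two acrocentrics
        specs = [
            (100.0, [], 45.0, "metacentric"),
            (120.0, [], 0.0, "acrocentric"),
            (110.0, [], 0.0, "acrocentric"),
            (90.0, [], 40.5, "metacentric"),
        ] + [(80.0 - 4 * i, [], 0.0, "acrocentric") for i in range(13)]
        ranked = m.rank_scs(make_cell("c1", specs))
        assert ranked[0].sc_rank == 1 and ranked[3].sc_rank == 4  # metacentrics
        assert ranked[1].sc_rank == 2 and ranked[2].sc_rank == 3

    def test_tie_broken_by_metacentricity_then_input_order(self):
        specs = [(100.0, [], 45.0, "metacentric"), (100.0, [], 30.0, "metacentric")] + [
            (80.0, [], 0.0, "acrocentric") for _ in range(15)
        ]
        ranked = m.rank_scs(make_cell("c1", specs))
        # equal lengths: the more metacentric SC (arm ratio nearer 1/2) wins rank 1
        assert ranked[0].sc_rank == 1 and ranked[1].sc_rank == 4
        # acrocentric tie falls back to input order
        assert [sc.sc_rank for sc in ranked[2:]] == list(range(2, 4)) + list(range(5, 18))

    def test_partial_cell_is_rejected_and_logged(self):
        cell = make_cell("bad", [(50.0, [], 0.0, "acrocentric")] * 10)
        with pytest.raises(m.PartialCellError):
            m.rank_scs(cell)
        good = reference_cell("good")
        ds, excluded = m.rank_dataset(m.Dataset([cell, good]))
        assert "bad" in excluded and len(ds.pachytene_cells()) == 1

    def test_size_classes_frozen_against_reference(self):
        ref = m.DEFAULT_REFERENCE
        assert [ref.size_class(r) for r in (1, 4, 5, 17)] == ["large", "large", "short", "short"]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(perm=st.permutations(list(range(17))))
    def test_ranking_is_a_permutation_and_deterministic(self, perm):
        cell = reference_cell(permute=perm)
        ranks = [sc.sc_rank for sc in m.rank_scs(cell)]
        ranks2 = [sc.sc_rank for sc in m.rank_scs(cell)]
        assert sorted(ranks) == list(range(1, 18)) and ranks == ranks2


class TestLengthSummary:
    def test_single_cell_summary(self):
        ds, _ = m.rank_dataset(m.Dataset([reference_cell()]))
        summ = m.sc_length_summary(ds)
        assert summ.per_rank["mean_um"].tolist() == list(m.DEFAULT_SC_PROFILE_UM)
        assert (summ.per_rank["sd_um"] == 0).all()
        assert summ.per_cell_totals["total_um"].iloc[0] == pytest.approx(1025.27)

    def test_shrinkage_scales_grand_mean(self):
        base = dict(intensity_per_um=0.0197, target_mean_foci_per_cell=None,
                    obligate_co=False, centromere_suppression_p=0.0,
                    length_cv=0.0, n_cells=40)
        full = m.simulate_dataset(m.SimConfig(axis_shrinkage=1.0, seed=41, **base))
        shrunk = m.simulate_dataset(m.SimConfig(axis_shrinkage=0.8, seed=41, **base))
        g_full = m.sc_length_summary(m.rank_dataset(full)[0]).grand_mean_um
        g_shrunk = m.sc_length_summary(m.rank_dataset(shrunk)[0]).grand_mean_um
        assert g_shrunk / g_full == pytest.approx(0.8, rel=1e-9)

    def test_reference_condition_recovers_published_grand_mean(self, ds28):
        summ = m.sc_length_summary(ds28)
        assert summ.grand_mean_um == pytest.approx(60.31, rel=0.05)


class TestDensity:
    def test_hand_density(self):
        cell = full_cell("c1", foci_per_sc=1)
        ds, _ = m.rank_dataset(m.Dataset([cell]))
        dens = m.co_density(ds)
        row = dens[dens.sc_rank == 5].iloc[0]
        assert row.density_per_um == pytest.approx(1.0 / m.DEFAULT_SC_PROFILE_UM[4])

    def test_shrinkage_with_fixed_counts_scales_density(self):
        cell = full_cell("c1", foci_per_sc=1)
        shrunk = full_cell("c2", foci_per_sc=1)
        shrunk.scs = [
            m.SCObservation(sc.cell_id, sc.length_um * 0.8, sc.centromere_um * 0.8,
                            sc.morphology, tuple(f * 0.8 for f in sc.foci_um), sc.sc_rank)
            for sc in shrunk.scs
        ]
        d1 = m.co_density(m.rank_dataset(m.Dataset([cell]))[0])
        d2 = m.co_density(m.rank_dataset(m.Dataset([shrunk]))[0])
        assert np.allclose(d2.density_per_um, d1.density_per_um * 1.25)

    def test_fixed_intensity_density_is_rank_free_but_obligate_is_not(self, ds_poisson, ds28):
        flat = m.co_density(ds_poisson)
        # stationary renewal at constant intensity: density independent of rank
        spread = flat.density_per_um.max() - flat.density_per_um.min()
        assert spread < 0.35 * flat.density_per_um.mean()
        oblig = m.co_density(ds28)
        # obligate CO inflates density on the shortest SCs
        corr = np.corrcoef(oblig.mean_length_um, oblig.density_per_um)[0, 1]
        assert corr < -0.8


class TestRelativePositions:
    def test_acrocentric_endpoints(self):
        cell = reference_cell()
        sc = cell.scs[6]  # an acrocentric: centromeric end is the origin
        cell.scs[6] = m.SCObservation(
            sc.cell_id, sc.length_um, 0.0, "acrocentric", (0.0, sc.length_um), sc.sc_rank
        )
        ds, _ = m.rank_dataset(m.Dataset([cell]))
        rel = m.relative_positions(ds)
        assert set(rel["pos_frac"].round(9)) == {0.0, 1.0}

    def test_metacentric_hand_example(self):
        specs = [(100.0, [70.0], 40.0, "metacentric")] + [
            (80.0 - i, [], 0.0, "acrocentric") for i in range(15)
        ] + [(90.0, [], 40.0, "metacentric")]
        ds, _ = m.rank_dataset(m.Dataset([make_cell("c1", specs)]))
        rel = m.relative_positions(ds)
        assert len(rel) == 1
        row = rel.iloc[0]
        assert row.arm == "q" and row.pos_frac == pytest.approx(0.5)

    def test_focus_at_metacentric_centromere_goes_to_q_arm(self):
        specs = [(100.0, [40.0], 40.0, "metacentric")] + [
            (80.0 - i, [], 0.0, "acrocentric") for i in range(15)
        ] + [(90.0, [], 40.0, "metacentric")]
        ds, _ = m.rank_dataset(m.Dataset([make_cell("c1", specs)]))
        row = m.relative_positions(ds).iloc[0]
        assert row.arm == "q" and row.pos_frac == 0.0

    def test_every_focus_maps_to_one_row(self, ds28):
        rel = m.relative_positions(ds28)
        total = sum(r.total_foci for r in ds28.records)
        assert len(rel) == total
        assert rel["pos_frac"].between(0, 1).all()

    def test_scale_free_under_pure_shrinkage(self, ds28):
        shrunk_records = []
        for rec in ds28.records:
            scs = [
                m.SCObservation(sc.cell_id, sc.length_um * 0.8, sc.centromere_um * 0.8,
                                sc.morphology, tuple(f * 0.8 for f in sc.foci_um), sc.sc_rank)
                for sc in rec.scs
            ]
            shrunk_records.append(
                m.CellRecord(rec.cell_id, rec.animal_id, rec.temperature_C, rec.stage, scs)
            )
        rel_a = m.relative_positions(ds28)
        rel_b = m.relative_positions(m.Dataset(shrunk_records))
        assert np.allclose(rel_a["pos_frac"], rel_b["pos_frac"])


class TestBinningAndKS:
    def test_uniform_bins(self, rng):
        h = m.bin_positions(rng.random(100_000))
        assert np.allclose(h, 0.1, atol=0.01)

    def test_point_mass_in_last_bin(self):
        h = m.bin_positions([0.95] * 7)
        assert h[9] == 1.0

    def test_hand_binning(self):
        h = m.bin_positions([0.05, 0.15, 0.15, 0.95])
        assert h[0] == 0.25 and h[1] == 0.5 and h[9] == 0.25

    def test_boundary_one_is_counted(self):
        assert m.bin_positions([1.0])[9] == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(m.EmptySelectionError):
            m.bin_positions([])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(xs=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_bin_frequencies_sum_to_one(self, xs):
        h = m.bin_positions(xs)
        assert h.sum() == pytest.approx(1.0)

    def test_ks_self_comparison(self, rng):
        x = rng.random(50)
        d, p = m.compare_position_distributions_ks(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_ks_disjoint_masses(self):
        d, _ = m.compare_position_distributions_ks([0.1] * 50, [0.9] * 50)
        assert d == 1.0

    def test_ks_matches_brute_force_ecdf_gap(self, rng):
        for _ in range(50):
            a = rng.random(rng.integers(5, 60))
            b = rng.random(rng.integers(5, 60))
            d, _ = m.compare_position_distributions_ks(a, b)
            grid = np.concatenate([a, b])
            ecdf_a = (a[:, None] <= grid[None, :]).mean(axis=0)
            ecdf_b = (b[:, None] <= grid[None, :]).mean(axis=0)
            assert d == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(m.InsufficientDataError):
            m.compare_position_distributions_ks([0.1, 0.2], [0.3] * 10)


class TestCentromereEffect:
    def test_uniform_index_near_one(self, rng):
        assert m.centromere_effect(rng.random(200_000)) == pytest.approx(1.0, abs=0.02)

    def test_full_suppression_gives_zero(self):
        cfg = m.SimConfig(
            intensity_per_um=0.0197, target_mean_foci_per_cell=None,
            centromere_radius_frac=0.1, centromere_suppression_p=1.0,
            n_cells=300, seed=51,
        )
        ds, _ = m.rank_dataset(m.simulate_dataset(cfg))
        rel = m.relative_positions(ds)
        assert m.centromere_effect(rel["pos_frac"]) == 0.0

    def test_half_suppression_matches_thinning_algebra(self):
        p, u = 0.5, 0.1
        cfg = m.SimConfig(
            nu=1.0, intensity_per_um=0.0197, target_mean_foci_per_cell=None,
            obligate_co=False, centromere_radius_frac=u, centromere_suppression_p=p,
            length_cv=0.0, n_cells=800, seed=52,
        )
        ds, _ = m.rank_dataset(m.simulate_dataset(cfg))
        rel = m.relative_positions(ds)
        # thinning only inside the window: index -> (1-p) / (1 - p·u)
        expected = (1 - p) / (1 - p * u)
        assert m.centromere_effect(rel["pos_frac"], u) == pytest.approx(expected, abs=0.05)

    def test_empty_positions_raise(self):
        with pytest.raises(m.EmptySelectionError):
            m.centromere_effect([])
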