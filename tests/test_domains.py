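import numpy as np
import pandas as pd
import pytest

from r3d import simulate as sim
from r3d.contact import ContactMatrix
from r3d.domains import (
    Boundary,
    Tad,
    aggregate_boundary_profile,
    boundaries_to_tads,
    call_boundaries,
    classify_tad_dynamics,
    consensus_boundaries,
    insulation_track,
    relative_tad_intensity,
    specific_tads,
)


def block_matrix(n=12, split=6, within=4.0, between=1.0, res=40_000):
    counts = np.full((n, n), between)
    counts[:split, :split] = within
    counts[split:, split:] = within
    return ContactMatrix("chrS", res, counts)


class TestInsulation:
    def test_uniform_matrix_zero_scores(self):
        m = ContactMatrix("chrS", 40_000, np.ones((20, 20)))
        t = insulation_track(m, window=120_000)  # w = 3
        defined = np.isfinite(t.score)
        assert defined.any()
        np.testing.assert_allclose(t.score[defined], 0.0, atol=1e-12)

    def test_hand_computed_two_block_toy(self):
        # 12 bins, blocks [0..5] and [6..11], within=4 between=1, w=2:
        # diamonds (bins 2..9) = 4, 4, 2.5, 1, 1, 2.5, 4, 4; mean 2.875
        m = block_matrix()
        t = insulation_track(m, window=80_000)
        expected_diamonds = np.array([4, 4, 2.5, 1, 1, 2.5, 4, 4])
        expected = np.log2(expected_diamonds / expected_diamonds.mean())
        np.testing.assert_allclose(t.score[2:10], expected, atol=1e-12)
        assert np.isnan(t.score[0]) and np.isnan(t.score[11])
        assert np.nanargmin(t.score) == 5  # unique minimum at the junction

    def test_scale_invariance(self):
        m = block_matrix()
        t1 = insulation_track(m, window=80_000)
        m2 = block_matrix()
        m2.counts *= 2.0
        t2 = insulation_track(m2, window=80_000)
        np.testing.assert_allclose(t1.score, t2.score, equal_nan=True, atol=1e-12)

    def test_window_validation(self):
        m = block_matrix()
        with pytest.raises(ValueError, match="2 bins"):
            insulation_track(m, window=40_000)
        with pytest.raises(ValueError, match="multiple"):
            insulation_track(m, window=100_000)

    def test_scores_average_near_zero(self):
        cfg = sim.SimulationConfig(seed=5, n_bins=200, resolution=40_000,
                                   tad_bins=(15, 25), depth=300)
        m, _ = sim.simulate_tad_matrix(cfg)
        t = insulation_track(m, window=480_000)
        assert abs(np.nanmean(t.score)) < 0.1


class TestCallBoundaries:
    def test_monotone_track_no_boundaries(self):
        t = insulation_track(
            ContactMatrix("chrS", 40_000, np.ones((20, 20))), window=120_000
        )
        t.score = np.where(np.isfinite(t.score),
                           np.linspace(0, 1, len(t.score)), np.nan)
        assert call_boundaries(t, min_delta=0.1) == []

    def test_all_undefined_errors(self):
        t = insulation_track(
            ContactMatrix("chrS", 40_000, np.ones((20, 20))), window=120_000
        )
        t.score = np.full_like(t.score, np.nan)
        with pytest.raises(ValueError):
            call_boundaries(t)

    def test_close_minima_merge_keeps_deeper(self):
        t = insulation_track(
            ContactMatrix("chrS", 40_000, np.ones((20, 20))), window=120_000
        )
        score = np.zeros(20)
        score[[0, 1, 2, 17, 18, 19]] = np.nan
        score[8] = -0.5
        score[9] = -0.8  # deeper, 1 bin away
        t.score = score
        bounds = call_boundaries(t, min_delta=0.1)
        assert [b.position for b in bounds] == [9]

    def test_planted_boundary_recovery(self):
        cfg = sim.SimulationConfig(seed=3, n_bins=300, resolution=40_000,
                                   tad_bins=(25, 35), depth=300)
        m, truth = sim.simulate_tad_matrix(cfg)
        from r3d.contact import balance_matrix

        t = insulation_track(balance_matrix(m), window=480_000)
        called = [b.position for b in call_boundaries(t, min_delta=0.1)]
        matched = sum(
            1 for p in truth.boundaries if any(abs(p - c) <= 1 for c in called)
        )
        false = sum(
            1 for c in called if not any(abs(p - c) <= 1 for p in truth.boundaries)
        )
        assert matched / len(truth.boundaries) >= 0.9
        assert false <= 1


class TestBoundariesToTads:
    def test_consecutive_pairs(self):
        bounds = [Boundary(p, 1.0, -1.0) for p in (10, 20, 30)]
        tads = boundaries_to_tads(bounds, resolution=40_000)
        assert [(t.start_bin, t.end_bin) for t in tads] == [(10, 20), (20, 30)]
        assert tads[0].start == 400_000 and tads[0].end == 800_000

    def test_short_domain_dropped(self):
        bounds = [Boundary(10, 1.0, -1.0), Boundary(11, 1.0, -1.0)]
        assert boundaries_to_tads(bounds) == []

    def test_exact_recovery_on_truth(self):
        planted = [0, 12, 25, 40]
        bounds = [Boundary(p, 1.0, -1.0) for p in planted]
        tads = boundaries_to_tads(bounds)
        assert [(t.start_bin, t.end_bin) for t in tads] == [(0, 12), (12, 25), (25, 40)]


class TestAggregateBoundaryProfile:
    def test_single_boundary_is_own_window(self):
        n = 40
        rng = np.random.default_rng(0)
        counts = rng.uniform(0.5, 2.0, (n, n))
        counts = (counts + counts.T) / 2
        oe = ContactMatrix("chrS", 40_000, counts, balanced=True)
        f = 5
        prof = aggregate_boundary_profile(oe, [Boundary(20, 1.0, -1.0)],
                                          flank=f * 40_000)
        np.testing.assert_allclose(prof, counts[15:26, 15:26])

    def test_uniform_oe_constant_aggregate(self):
        oe = ContactMatrix("chrS", 40_000, np.full((60, 60), 2.0), balanced=True)
        prof = aggregate_boundary_profile(
            oe, [Boundary(20, 1, -1), Boundary(35, 1, -1)], flank=200_000
        )
        np.testing.assert_allclose(prof, 2.0)

    def test_no_eligible_boundaries_errors(self):
        oe = ContactMatrix("chrS", 40_000, np.ones((20, 20)), balanced=True)
        with pytest.raises(ValueError):
            aggregate_boundary_profile(oe, [Boundary(1, 1, -1)], flank=600_000)

    def test_planted_insulation_depletes_cross_quadrants(self):
        cfg = sim.SimulationConfig(seed=9, n_bins=300, resolution=40_000,
                                   tad_bins=(25, 35), tad_enrichment=2.0,
                                   depth=300)
        m, truth = sim.simulate_tad_matrix(cfg)
        from r3d.contact import balance_matrix, expected_profile, observed_over_expected

        b = balance_matrix(m)
        oe = observed_over_expected(b, expected_profile(b))
        bounds = [Boundary(p, 1.0, -1.0) for p in truth.boundaries]
        f = 15
        prof = aggregate_boundary_profile(oe, bounds, flank=f * 40_000)
        # quadrant blocks adjacent to the boundary (within one TAD length)
        up = slice(f - 9, f - 1)
        dn = slice(f + 2, f + 10)
        cross = prof[up, dn].mean()  # upstream x downstream
        within = (prof[up, up].mean() + prof[dn, dn].mean()) / 2
        assert within / cross >= 1.5


class TestRti:
    def _oe_with_tad(self, n=9, a=3, b=6, intra=3.0):
        counts = np.ones((n, n))
        counts[a:b, a:b] = intra
        return ContactMatrix("chrS", 40_000, counts, balanced=True)

    def test_unit_oe_gives_one(self):
        oe = ContactMatrix("chrS", 40_000, np.ones((9, 9)), balanced=True)
        tad = Tad("chrS", 120_000, 240_000, 3, 6)
        assert relative_tad_intensity(oe, tad) == pytest.approx(1.0)

    def test_hand_computed_nine_bin_toy(self):
        # intra mean 3 over pairs in [3,6); flank rectangles all 1 -> RTI 3
        oe = self._oe_with_tad()
        tad = Tad("chrS", 120_000, 240_000, 3, 6)
        assert relative_tad_intensity(oe, tad) == pytest.approx(3.0)

    def test_monotone_in_intra_enrichment(self):
        tad = Tad("chrS", 120_000, 240_000, 3, 6)
        r1 = relative_tad_intensity(self._oe_with_tad(intra=2.0), tad)
        r2 = relative_tad_intensity(self._oe_with_tad(intra=3.5), tad)
        assert r2 > r1

    def test_masked_flanks_flagged(self):
        oe = self._oe_with_tad()
        oe.mask = np.array([True] * 3 + [False] * 3 + [True] * 3)
        tad = Tad("chrS", 120_000, 240_000, 3, 6)
        with pytest.warns(UserWarning, match="flanks"):
            assert np.isnan(relative_tad_intensity(oe, tad))

    def test_noiseless_generative_calibration(self):
        cfg = sim.SimulationConfig(n_bins=120, resolution=40_000)
        tads = pd.DataFrame({"start_bin": [50], "end_bin": [70]})
        values = []
        for q in (1.5, 2.0, 3.0, 4.0):
            oe = sim.noiseless_oe_matrix(cfg, tads=tads,
                                         tad_enrichments=np.array([q]))
            tad = Tad("chrS", 50 * 40_000, 70 * 40_000, 50, 70)
            values.append(relative_tad_intensity(oe, tad))
        assert values[2] == pytest.approx(3.0, abs=0.05)
        assert all(b > a for a, b in zip(values, values[1:]))


class TestTadDynamics:
    def test_static(self):
        assert classify_tad_dynamics(2.0, 2.0, 2.0, fold=1.5) == "Static"

    def test_repro_forced(self):
        assert classify_tad_dynamics(3.0, 1.55, 1.5, fold=1.5, delta=0.15) == "Repro"

    def test_resis(self):
        assert classify_tad_dynamics(3.0, 2.95, 1.2, fold=1.5) == "Resis"

    def test_hyper(self):
        assert classify_tad_dynamics(3.0, 0.5, 1.2, fold=1.5) == "Hyper"

    def test_intermediate_folds_to_nearest(self):
        # r = 0.4 -> Resis side; r = 0.6 -> Repro side
        assert classify_tad_dynamics(3.0, 3.0 + 0.4 * (-1.8), 1.2) == "Resis"
        assert classify_tad_dynamics(3.0, 3.0 + 0.6 * (-1.8), 1.2) == "Repro"

    def test_undefined_rti_errors(self):
        with pytest.raises(ValueError):
            classify_tad_dynamics(float("nan"), 1.0, 1.0)

    def test_planted_recovery(self):
        cfg = sim.SimulationConfig(seed=17)
        df = sim.simulate_rti_triples(cfg, n_tads=200, noise=0.05)
        labels = [
            classify_tad_dynamics(r.rti_cc, r.rti_nt, r.rti_f)
            for r in df.itertuples()
        ]
        acc = (np.array(labels) == df["true_class"].to_numpy()).mean()
        assert acc >= 0.90


class TestSpecificTads:
    def test_cc_specific(self):
        df = pd.DataFrame({"rti_cc": [3.0], "rti_f": [1.0]})
        assert specific_tads(df, fold=1.5).iloc[0] == "CC-specific"

    def test_unspecific(self):
        df = pd.DataFrame({"rti_cc": [1.0], "rti_f": [1.0]})
        assert specific_tads(df).iloc[0] == "unspecific"

    def test_exact_recovery_at_zero_noise(self):
        truth = ["CC-specific"] * 5 + ["ESC-specific"] * 5 + ["unspecific"] * 5
        cc = [3.0] * 5 + [1.0] * 5 + [2.0] * 5
        f = [1.0] * 5 + [3.0] * 5 + [2.0] * 5
        out = specific_tads(pd.DataFrame({"rti_cc": cc, "rti_f": f}), fold=1.5)
        assert list(out) == truth


class TestConsensusBoundaries:
    def test_requires_support(self):
        b1 = [Boundary(10, 1.0, -0.5), Boundary(30, 1.0, -0.4)]
        b2 = [Boundary(11, 1.0, -0.6)]
        b3 = [Boundary(50, 1.0, -0.3)]
        cons = consensus_boundaries([b1, b2, b3], min_support=2, tol_bins=1)
        assert [b.position for b in cons] == [11]  # deeper of 10/11

    def test_weakened_donor_boundaries_still_shared(self):
        # same planted TADs, shallower enrichment in ESC-like condition:
        # boundary insulation deeper (stronger) in the donor condition
        from r3d.contact import balance_matrix

        base = dict(seed=23, n_bins=300, resolution=40_000, tad_bins=(25, 35),
                    depth=300)
        cfg_cc = sim.SimulationConfig(**base, tad_enrichment=3.0)
        cfg_esc = sim.SimulationConfig(**base, tad_enrichment=1.8)
        m_cc, truth = sim.simulate_tad_matrix(cfg_cc)
        m_esc, _ = sim.simulate_tad_matrix(cfg_esc)
        t_cc = insulation_track(balance_matrix(m_cc), window=480_000)
        t_esc = insulation_track(balance_matrix(m_esc), window=480_000)
        at_bounds = [p for p in truth.boundaries
                     if np.isfinite(t_cc.score[p]) and np.isfinite(t_esc.score[p])]
        depth_cc = -np.mean([t_cc.score[p] for p in at_bounds])
        depth_esc = -np.mean([t_esc.score[p] for p in at_bounds])
        assert depth_cc > depth_esc
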