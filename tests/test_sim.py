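import numpy as np
import pytest

from admixwave.modwt import modwt_haar, wavelet_variance
from admixwave.sim import (
    HaplotypeAncestry,
    PopulationState,
    SelectionRegime,
    SimConfig,
    ancestry_proportion_signal,
    expected_neutral_wavelet_variance,
    haplotype_ancestry,
    individual_fitness,
    linear_fitness,
    recombination_rate_signal,
    run_selection_scenarios,
    simulate,
    tract_length_summary,
)

from conftest import make_hetero_map


def f1_state(n_loci=100, L=64):
    """One diploid: a pure-introgressed and a pure-recipient haplotype."""
    haps = np.zeros((2, L), dtype=np.uint8)
    haps[0] = 1
    return PopulationState(
        generation=1,
        haplotypes={"c1": haps},
        resolution=2.0**-6,
        chrom_lengths={"c1": 1.0},
        selected_loci={"c1": np.linspace(0, L - 1, n_loci).astype(int)},
    )


class TestFitnessModel:
    def test_f1_hybrid_fitness_is_half(self):
        state = f1_state()
        regime = SelectionRegime.continuous(S=1.0)
        w = individual_fitness(state, regime, multiplier=1.0)
        assert w[0] == pytest.approx(0.5)

    def test_linear_model_endpoints(self):
        assert linear_fitness(0.0, S=5.0) == pytest.approx(1.0)
        assert linear_fitness(1.0, S=1.0) == pytest.approx(0.0)
        # clamped below zero for strong S
        assert linear_fitness(1.0, S=2.0) == pytest.approx(0.0)

    def test_reversed_schedule_favours_introgressed(self):
        assert linear_fitness(0.8, S=1.0, multiplier=-1.0) == pytest.approx(1.8)

    def test_founders_reproduce_neutrally(self):
        regime = SelectionRegime.continuous(S=1.0)
        assert regime.multiplier(0) == 0.0
        assert regime.multiplier(1) == 1.0

    def test_schedule_constructors(self):
        early = SelectionRegime.early_only(n_generations=10)
        assert early.multiplier(10) == 1.0 and early.multiplier(11) == 0.0
        late = SelectionRegime.late_onset(neutral_generations=500)
        assert late.multiplier(500) == 0.0 and late.multiplier(501) == 1.0
        rev = SelectionRegime.reversal(flip_generation=100)
        assert rev.multiplier(100) == 1.0 and rev.multiplier(101) == -1.0

    def test_extinction_raises(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 0.1},
            alpha=0.9,  # rounds to every founder haplotype introgressed at 2N=4
            twoN=4,
            generations=5,
            selection=SelectionRegime.continuous(S=1.0, n_loci=10),
            resolution=0.05,
            seed=0,
        )
        with pytest.raises(RuntimeError, match="zero"):
            simulate(cfg)


class TestNeutralDynamics:
    def test_mean_ancestry_preserved_one_generation(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 0.01},
            twoN=20000,
            generations=1,
            resolution=0.005,
            seed=1,
        )
        state = simulate(cfg)[1]
        mean = np.mean([h.mean() for h in state.haplotypes.values()])
        se = np.sqrt(0.25 / 20000)
        assert abs(mean - 0.5) < 3 * se

    def test_determinism_under_seed(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 1.0}, twoN=200, generations=10,
            resolution=2.0**-7, seed=123,
        )
        a = simulate(cfg, record_generations=[5, 10])
        b = simulate(cfg, record_generations=[5, 10])
        for g in (5, 10):
            np.testing.assert_array_equal(
                a[g].haplotypes["c1"], b[g].haplotypes["c1"]
            )

    def test_generation_zero_is_exact_mixture(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 1.0}, alpha=0.3, twoN=100, generations=1,
            resolution=2.0**-6, seed=0,
        )
        state = simulate(cfg, record_generations=[0])[0]
        sig = ancestry_proportion_signal(state)["c1"]
        np.testing.assert_allclose(sig.values, 0.3)
        tracts = tract_length_summary(state)
        np.testing.assert_allclose(tracts["length_M"], 1.0)

    def test_junction_accrual_rate(self):
        # neutral large population: expected junctions per Morgan per
        # haplotype after t generations ~ t * 2a(1-a)
        t = 10
        cfg = SimConfig(
            chrom_lengths={"c1": 1.0}, twoN=20000, generations=t,
            resolution=2.0**-10, seed=7,
        )
        state = simulate(cfg)[t]
        haps = state.haplotypes["c1"]
        junctions = (np.diff(haps, axis=1) != 0).sum(axis=1)
        expected = t * 2 * 0.5 * 0.5
        assert abs(junctions.mean() - expected) / expected < 0.1

    def test_mean_tract_length(self):
        t = 10
        cfg = SimConfig(
            chrom_lengths={"c1": 1.0}, twoN=20000, generations=t,
            resolution=2.0**-10, seed=11,
        )
        tracts = tract_length_summary(simulate(cfg)[t])
        # ~ t*2a(1-a) junctions/Morgan -> mean tract ~ 1/(1 + t/2) on a
        # 1-Morgan chromosome (edges included)
        expected = 1.0 / (1.0 + t * 2 * 0.25)
        assert abs(tracts["length_M"].mean() - expected) / expected < 0.1

    def test_drift_slows_junction_accrual_after_fixation(self):
        # small population fixes ancestry, which halts junction accrual
        common = dict(chrom_lengths={"c1": 1.0}, generations=300, resolution=2.0**-8)
        small = simulate(SimConfig(twoN=100, seed=5, **common))[300]
        big = simulate(SimConfig(twoN=2000, seed=5, **common))[300]
        n_small = (np.diff(small.haplotypes["c1"], axis=1) != 0).sum(axis=1).mean()
        n_big = (np.diff(big.haplotypes["c1"], axis=1) != 0).sum(axis=1).mean()
        assert n_small < n_big

    def test_drift_law_unlinked_marker(self):
        # Var(p_t) = a(1-a)(1-(1-1/2N)^t) for an effectively unlinked locus
        reps, twoN, t = 400, 100, 20
        freqs = []
        for r in range(reps):
            cfg = SimConfig(
                chrom_lengths={"c1": 2e-6}, twoN=twoN, generations=t,
                resolution=1e-6, seed=r,
            )
            freqs.append(simulate(cfg)[t].haplotypes["c1"][:, 0].mean())
        freqs = np.asarray(freqs)
        expected = 0.25 * (1 - (1 - 1 / twoN) ** t)
        dev = (freqs - freqs.mean()) ** 2
        se = dev.std(ddof=1) / np.sqrt(reps)
        assert abs(freqs.var(ddof=1) - expected) < 3 * se


class TestStateSummaries:
    def test_single_haplotype_with_midpoint_junction(self):
        haps = np.zeros((2, 64), dtype=np.uint8)
        haps[0, 32:] = 1
        state = PopulationState(0, {"c1": haps}, 2.0**-6, {"c1": 1.0})
        hap = haplotype_ancestry(state, "c1", 0)
        assert hap.left_ancestry == 0
        np.testing.assert_allclose(hap.junctions, [31.5 * 2.0**-6])
        lengths, ancestries = hap.tract_lengths()
        assert list(ancestries) == [0, 1]
        sig = ancestry_proportion_signal(state)["c1"]
        np.testing.assert_allclose(sig.values[:32], 0.0)

    def test_junctions_alternate_and_increase(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 1.0}, twoN=50, generations=50,
            resolution=2.0**-8, seed=3,
        )
        state = simulate(cfg)[50]
        for i in range(10):
            hap = haplotype_ancestry(state, "c1", i)
            if len(hap.junctions) > 1:
                assert np.all(np.diff(hap.junctions) > 0)

    def test_invalid_junctions_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeAncestry("c1", 1.0, [0.5, 0.5], 0)

    def test_signal_block_averaging_and_resolution_guard(self):
        haps = np.tile(np.array([0, 1], dtype=np.uint8), (4, 32))
        state = PopulationState(0, {"c1": haps}, 2.0**-6, {"c1": 1.0})
        coarse = ancestry_proportion_signal(state, resolution=2.0**-5)["c1"]
        np.testing.assert_allclose(coarse.values, 0.5)
        with pytest.raises(ValueError, match="exceeds"):
            ancestry_proportion_signal(state, resolution=2.0)

    def test_subsampling_is_seeded(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 1.0}, twoN=100, generations=5,
            resolution=2.0**-6, seed=2,
        )
        state = simulate(cfg)[5]
        s1 = ancestry_proportion_signal(
            state, sample_size=20, rng=np.random.default_rng(0)
        )
        s2 = ancestry_proportion_signal(
            state, sample_size=20, rng=np.random.default_rng(0)
        )
        np.testing.assert_array_equal(s1["c1"].values, s2["c1"].values)


class TestNeutralTheory:
    def test_no_variance_before_recombination(self):
        out = expected_neutral_wavelet_variance(200, 0, [2.0**-5, 2.0**-3], 2.0**-7)
        np.testing.assert_allclose(out["variance"], 0.0, atol=1e-15)

    def test_matches_simulation_small_system(self):
        res, twoN, t, reps = 2.0**-7, 200, 10, 150
        levels = np.arange(1, 8)
        spectra = []
        for r in range(reps):
            cfg = SimConfig(
                chrom_lengths={"c1": 1.0}, twoN=twoN, generations=t,
                resolution=res, seed=r,
            )
            sig = ancestry_proportion_signal(simulate(cfg)[t])["c1"]
            spectra.append(
                wavelet_variance(modwt_haar(sig), "unbiased").variances[:7]
            )
        spectra = np.array(spectra)
        mean = spectra.mean(0)
        se = spectra.std(0, ddof=1) / np.sqrt(reps)
        theory = expected_neutral_wavelet_variance(
            twoN, t, (2.0**levels) * res, res
        )["variance"].to_numpy()
        assert np.all(np.abs(mean - theory) < 4 * se)

    def test_bottleneck_raises_broad_scale_theory(self):
        res = 2.0**-9
        traj = np.r_[np.full(11, 200), np.full(90, 2000)]
        scales = [2.0**8 * res, 2.0**9 * res]
        bott = expected_neutral_wavelet_variance(traj, 100, scales, res)["variance"]
        const = expected_neutral_wavelet_variance(2000, 100, scales, res)["variance"]
        assert np.all(bott.to_numpy() > const.to_numpy())

    def test_non_dyadic_scale_rejected(self):
        with pytest.raises(ValueError, match="dyadic"):
            expected_neutral_wavelet_variance(200, 10, [3 * 2.0**-7], 2.0**-7)
        with pytest.raises(ValueError):
            expected_neutral_wavelet_variance(200, 10, [2.0**-8], 2.0**-7)


class TestSelection:
    def test_selection_removes_introgressed_ancestry(self):
        # matched-seed neutral control: selected runs fall below it by gen 10
        wins = 0
        for r in range(20):
            common = dict(
                chrom_lengths={"c1": 1.0}, twoN=200, generations=10,
                resolution=2.0**-7, seed=1000 + r,
            )
            sel = SimConfig(
                selection=SelectionRegime.continuous(S=1.0, n_loci=50), **common
            )
            neu = SimConfig(**common)
            m_sel = simulate(sel)[10].haplotypes["c1"].mean()
            m_neu = simulate(neu)[10].haplotypes["c1"].mean()
            wins += m_sel < m_neu
        assert wins >= 19

    def test_matched_seed_founders_identical(self):
        common = dict(
            chrom_lengths={"c1": 1.0}, twoN=100, generations=2,
            resolution=2.0**-6, seed=9,
        )
        sel = simulate(
            SimConfig(selection=SelectionRegime.continuous(n_loci=10), **common),
            record_generations=[0],
        )[0]
        neu = simulate(SimConfig(**common), record_generations=[0])[0]
        np.testing.assert_array_equal(sel.haplotypes["c1"], neu.haplotypes["c1"])

    def test_scenario_driver_bundles(self):
        m1 = make_hetero_map("c1", 6, 1)
        cfg = SimConfig(
            rec_maps={"c1": m1},
            twoN=200,
            generations=12,
            selection=SelectionRegime.continuous(S=1.0, n_loci=100),
            resolution=2.0**-8,
            seed=4,
        )
        out = run_selection_scenarios(cfg, scenarios=("continuous", "early"))
        assert set(out) == {"continuous", "early"}
        for bundle in out.values():
            assert 12 in bundle["signals"]
            assert 12 in bundle["control_signals"]
            rec = bundle["recombination"]["c1"]
            assert len(rec) == len(bundle["signals"][12]["c1"])

    def test_scenario_driver_requires_selection(self):
        cfg = SimConfig(chrom_lengths={"c1": 1.0}, twoN=100, generations=5,
                        resolution=2.0**-6, seed=0)
        with pytest.raises(ValueError, match="S > 0"):
            run_selection_scenarios(cfg)

    def test_selected_loci_denser_in_low_recombination_regions(self):
        # uniform physical placement: loci per Morgan ~ 1/rate
        m1 = make_hetero_map("c1", 2, 3, lo=0.5, hi=0.6)
        rates = np.array([0.5, 5.0])
        starts = np.array([0.0, 50e6])
        from admixwave.signal_prep import RecombinationMap

        rmap = RecombinationMap("c1", starts, starts + 50e6, rates, units="cM_per_Mb")
        cfg = SimConfig(
            rec_maps={"c1": rmap},
            twoN=10,
            generations=1,
            selection=SelectionRegime.continuous(S=1.0, n_loci=2000),
            resolution=2.0**-9,
            seed=1,
        )
        state = simulate(cfg, record_generations=[0])[0]
        idx = state.selected_loci["c1"]
        grid = cfg.grid("c1")
        low_rec_morgans = 0.5 * 1e-8 * 50e6
        n_low = (grid[idx] < low_rec_morgans).sum()
        # physical halves get ~equal counts despite 10x different map lengths
        assert 0.4 < n_low / len(idx) < 0.6
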