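import numpy as np
import pytest

from ayescan.demography import PiecewiseDemography
from ayescan.forward_sim import (
    DFEConfig,
    ForwardSimulator,
    GenomeArchitecture,
    RestartLimitError,
    SelectionScenario,
    assign_rate_map,
    build_architecture,
    frequency_dependent_coefficient,
    frequency_dependent_trajectory,
    run_forward,
    sample_dfe,
)


class TestArchitecture:
    def test_default_total_length(self):
        assert build_architecture().length == 91_161

    def test_single_exon_gene(self):
        arch = build_architecture(n_genes=1, exons_per_gene=1, intergenic_len=0)
        assert arch.length == 130
        assert arch.elements == (("exon", 1, 130),)

    def test_exon_bp_fraction(self):
        arch = build_architecture()
        exon_bp = sum(e - s + 1 for s, e in arch.exons())
        assert exon_bp / arch.length == pytest.approx(3 * 9 * 130 / 91_161)
        assert exon_bp / arch.length == pytest.approx(0.0385, abs=1e-4)

    def test_gene_layout_alternates_and_tiles(self):
        arch = build_architecture(n_genes=2, exons_per_gene=2, exon_len=10,
                                  intron_len=5, intergenic_len=7)
        kinds = [e[0] for e in arch.elements]
        assert kinds == ["exon", "intron", "exon", "intergenic"] * 2
        assert arch.length == 2 * (2 * 10 + 5 + 7)

    def test_site_classes_cover_region(self):
        arch = build_architecture()
        classes = arch.site_classes()
        assert len(classes) == arch.length
        assert (classes == 2).sum() == 3 * 9 * 130

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            build_architecture(n_genes=0)

    def test_non_tiling_elements_rejected(self):
        with pytest.raises(ValueError):
            GenomeArchitecture((("exon", 1, 10), ("intron", 12, 20)), 20)


class TestDFE:
    def test_effectively_neutral_class_bounds(self, rng):
        cfg = DFEConfig(proportions=(1.0, 0.0, 0.0, 0.0))
        for _ in range(500):
            s = sample_dfe(cfg, rng)
            assert 0 <= 2 * cfg.reference_N * s < 1

    def test_moderate_class_mean(self, rng):
        cfg = DFEConfig(proportions=(0.0, 0.0, 1.0, 0.0))
        draws = np.array([sample_dfe(cfg, rng) for _ in range(20_000)])
        two_ns = 2 * cfg.reference_N * draws
        assert np.all((two_ns >= 10) & (two_ns < 100))
        assert two_ns.mean() == pytest.approx(55, abs=1.0)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            DFEConfig(proportions=(0.5, 0.6, -0.1, 0.0))
        with pytest.raises(ValueError):
            DFEConfig(proportions=(0.5, 0.2, 0.2, 0.2))


class TestRateMaps:
    def test_degenerate_bounds_give_constant_map(self, rng):
        rates = assign_rate_map(
            91_161, target_mean=1e-8, lo=1e-8, hi=1e-8, rng=rng
        )
        assert len(rates) == 92
        assert np.allclose(rates, 1e-8)

    def test_recombination_bounds_respected(self, rng):
        rates = assign_rate_map(
            1_000_000, target_mean=1e-8, lo=1e-10, hi=1e-7,
            mode="uniform", rng=rng,
        )
        assert np.all((rates >= 1e-10) & (rates <= 1e-7))

    def test_mean_matched_mode_hits_target(self, rng):
        rates = assign_rate_map(
            1_000_000, target_mean=1e-8, lo=1e-10, hi=1e-7, rng=rng
        )
        assert rates.mean() == pytest.approx(1e-8, rel=0.01)
        assert np.all((rates >= 1e-10) & (rates <= 1e-7))

    def test_target_outside_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_rate_map(10_000, target_mean=5e-7, lo=1e-10, hi=1e-7, rng=rng)


class TestFrequencyDependence:
    @pytest.mark.parametrize(
        "f_eq,f_bp,expected", [(0.5, 0.5, 0.0), (0.5, 0.2, 0.3), (0.5, 0.9, -0.4)]
    )
    def test_coefficient_examples(self, f_eq, f_bp, expected):
        assert frequency_dependent_coefficient(f_eq, f_bp) == pytest.approx(expected)

    def test_frequencies_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            frequency_dependent_coefficient(1.5, 0.5)

    def test_trajectory_is_mean_reverting_around_equilibrium(self):
        freqs = frequency_dependent_trajectory(500, 6000, seed=11)
        late = freqs[1000:]
        assert late.mean() == pytest.approx(0.5, abs=0.02)
        dev = late - 0.5
        lag1 = np.corrcoef(dev[:-1], dev[1:])[0, 1]
        lag20 = np.corrcoef(dev[:-20], dev[20:])[0, 1]
        assert abs(lag20) < abs(lag1)  # deviations decorrelate

    def test_trajectory_reproducible(self):
        a = frequency_dependent_trajectory(200, 500, seed=3)
        b = frequency_dependent_trajectory(200, 500, seed=3)
        assert np.array_equal(a, b)


class TestScenarioValidation:
    def test_neutral_takes_no_selection_parameters(self):
        with pytest.raises(ValueError):
            SelectionScenario("neutral", tau=1.0)

    def test_sweep_needs_strength(self):
        with pytest.raises(ValueError):
            SelectionScenario("sweep", tau=0.1)

    def test_sweep_tau_within_run_span(self):
        with pytest.raises(ValueError):
            SelectionScenario("sweep", tau=20, s2N=100)

    def test_balancing_equilibrium_domain(self):
        with pytest.raises(ValueError):
            SelectionScenario("balancing", tau=10, f_eq=0.9)


MODEL = PiecewiseDemography.default_aye_aye()
ARCH = build_architecture()


class TestForwardEngine:
    def test_zero_mutation_rate_gives_no_records(self):
        mu = np.zeros(-(-ARCH.length // 1000))
        res = run_forward(
            MODEL, ARCH, DFEConfig(), SelectionScenario("neutral"),
            mu_rates=mu, Q=100, seed=1,
        )
        assert res.records == ()

    def test_same_seed_is_reproducible(self):
        runs = [
            run_forward(
                MODEL, ARCH, DFEConfig(), SelectionScenario("neutral"),
                Q=200, seed=77,
            )
            for _ in range(2)
        ]
        assert runs[0].records == runs[1].records
        assert np.array_equal(runs[0].haplotypes, runs[1].haplotypes)

    def test_retained_sweep_replicates_are_fixed(self):
        res = run_forward(
            MODEL, ARCH, DFEConfig(),
            SelectionScenario("sweep", tau=0.1, s2N=10_000),
            Q=100, seed=5,
        )
        assert res.final_state == "fixed"
        # a fixed mutation is invisible among polymorphic sites
        assert all(r.position != res.selected_pos or r.x < 10 for r in res.records)

    def test_retained_balancing_replicates_still_segregate(self):
        res = run_forward(
            MODEL, ARCH, DFEConfig(),
            SelectionScenario("balancing", tau=10, f_eq=0.5),
            Q=100, seed=6,
        )
        assert res.final_state == "segregating"
        assert 0.0 < res.final_freq < 1.0

    def test_infeasible_sweep_hits_restart_cap(self):
        # an effectively neutral "beneficial" mutation cannot fix within
        # 0.1 N generations from a single copy
        with pytest.raises(RestartLimitError):
            run_forward(
                MODEL, ARCH, DFEConfig(),
                SelectionScenario("sweep", tau=0.1, s2N=0.5),
                Q=100, seed=7, restart_cap=5,
            )

    def test_sample_output_is_folded_polymorphic_sorted(self):
        res = run_forward(
            MODEL, ARCH, DFEConfig(), SelectionScenario("neutral"),
            Q=100, seed=8,
        )
        positions = [r.position for r in res.records]
        assert positions == sorted(positions)
        assert all(1 <= r.x <= 5 and r.n == 10 for r in res.records)
        counts = res.haplotypes.sum(axis=0)
        assert np.all((counts > 0) & (counts < 10))


class TestEquilibriumProperties:
    def test_burn_in_diversity_near_ancestral_equilibrium(self):
        """After a 10N burn-in at constant size, mean pairwise diversity
        should sit within 10% of the neutral expectation 4*N*mu."""
        model = PiecewiseDemography.constant(23_706)
        arch = GenomeArchitecture((("intergenic", 1, 91_161),), 91_161)
        pis = []
        for i in range(25):
            sim = ForwardSimulator(model, arch, DFEConfig(), Q=100, seed=600 + i)
            sim.burn_in()
            _, haps, _ = sim.sample(10)
            c = haps.sum(axis=0)
            pis.append((2 * c * (10 - c) / 90).sum() / arch.length)
        expected = 4 * 23_706 * 1.52e-8
        assert np.mean(pis) == pytest.approx(expected, rel=0.10)

    def test_rescaling_consistency_between_Q50_and_Q100(self):
        """Neutral diversity is invariant to the rescaling factor within
        Monte-Carlo error."""
        model = PiecewiseDemography.constant(23_706)
        arch = GenomeArchitecture((("intergenic", 1, 91_161),), 91_161)

        def mean_pi(Q, seeds):
            vals = []
            for seed in seeds:
                sim = ForwardSimulator(model, arch, DFEConfig(), Q=Q, seed=seed)
                sim.burn_in()
                _, haps, _ = sim.sample(10)
                c = haps.sum(axis=0)
                vals.append((2 * c * (10 - c) / 90).sum() / arch.length)
            return np.array(vals)

        a = mean_pi(100, range(100, 108))
        b = mean_pi(50, range(200, 206))
        se = np.hypot(a.std(ddof=1) / np.sqrt(len(a)), b.std(ddof=1) / np.sqrt(len(b)))
        assert abs(a.mean() - b.mean()) < 3 * se
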