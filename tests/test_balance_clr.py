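import numpy as np
import pytest
from scipy.stats import binom

from ayescan.balance_clr import (
    b0maf_window,
    balanced_class_spectrum,
    scan_balancing,
)
from ayescan.io_formats import AlleleFrequencyRecord
from ayescan.sfs_stats import SNPWindow, snp_windows


def _window(classes, spacing=100, start=1000):
    records = tuple(
        AlleleFrequencyRecord(start + spacing * i, int(x), 10)
        for i, x in enumerate(classes)
    )
    center = (records[0].position + records[-1].position) / 2
    return SNPWindow(records, center)


class TestBalancedClassSpectrum:
    def test_normalized(self):
        for x_eq in (0.05, 0.2, 0.5):
            assert balanced_class_spectrum(x_eq, 10).probs.sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_perfectly_balanced_mode_at_intermediate_class(self):
        f = balanced_class_spectrum(0.5, 10)
        assert np.argmax(f.probs) + 1 == 5

    def test_low_equilibrium_favors_rare_class(self):
        f = balanced_class_spectrum(0.1, 10)
        assert f.prob(1) > f.prob(5)

    def test_matches_direct_binomial_evaluation(self):
        x = 0.3
        k = np.arange(1, 6)
        raw = binom.pmf(k, 10, x) + binom.pmf(k, 10, 1 - x)
        assert np.allclose(balanced_class_spectrum(x, 10).probs, raw / raw.sum())

    @pytest.mark.parametrize("x_eq", [0.0, -0.1, 0.6])
    def test_equilibrium_frequency_domain(self, x_eq):
        with pytest.raises(ValueError):
            balanced_class_spectrum(x_eq, 10)


class TestWindowCLR:
    def test_intermediate_heavy_window_detected_with_balanced_estimate(
        self, background_g
    ):
        win = _window([5] * 100)
        rec = b0maf_window(win, background_g)
        assert rec.clr > 0
        assert rec.x_hat == pytest.approx(0.5)

    def test_background_modal_class_window_estimates_lowest_grid_point(
        self, background_g
    ):
        # all sites at the background's modal (rarest) class: if a mixture
        # helps at all, the best balanced spectrum is the most skewed one
        win = _window([1] * 100)
        rec = b0maf_window(win, background_g)
        if rec.x_hat is not None:
            assert rec.x_hat == pytest.approx(0.05)

    def test_exact_background_composition_unlinked_is_zero(self, background_g):
        # spread sites so far apart that every mixture weight underflows to 0
        # for every grid A: the statistic reduces to the null exactly
        classes = [1] * 5 + [2] * 3 + [3, 4] + [5]
        counts = [50, 30, 10, 6, 4]
        classes = sum(([k] * c for k, c in zip(range(1, 6), counts)), [])
        win = _window(classes, spacing=10**13)
        rec = b0maf_window(win, background_g)
        assert rec.clr <= 1e-6

    def test_infinite_A_only_grid_gives_null_exactly(self, background_g, rng):
        classes = rng.integers(1, 6, size=20)
        win = _window(list(classes))
        rec = b0maf_window(win, background_g, A_grid=np.array([np.inf]))
        assert rec.clr == 0.0
        assert rec.x_hat is None

    def test_clr_non_negative_on_random_windows(self, background_g, rng):
        for _ in range(200):
            classes = rng.choice(np.arange(1, 6), size=10, p=background_g.probs)
            rec = b0maf_window(_window(list(classes)), background_g)
            assert rec.clr >= -1e-9

    def test_empty_background_class_rejected(self, rng):
        from ayescan.sfs_stats import FoldedSFS

        G = FoldedSFS(10, np.array([0.5, 0.5, 0.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            b0maf_window(_window([1] * 10), G)


class TestScanBalancing:
    def _records(self, classes, spacing=100):
        return [
            AlleleFrequencyRecord(spacing * (i + 1), int(x), 10)
            for i, x in enumerate(classes)
        ]

    def test_window_count_matches_snp_windows(self, background_g, rng):
        records = self._records(rng.integers(1, 6, size=20))
        out = scan_balancing(records, 10, 5, background_g)
        assert len(out) == len(snp_windows(records, 10, 5)) == 3

    def test_deterministic_and_order_invariant(self, background_g, rng):
        records = self._records(rng.integers(1, 6, size=35))
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = scan_balancing(records, 10, 5, background_g)
        b = scan_balancing(shuffled, 10, 5, background_g)
        assert [(r.position, r.clr, r.x_hat) for r in a] == [
            (r.position, r.clr, r.x_hat) for r in b
        ]

    def test_window_records_carry_span(self, background_g, rng):
        records = self._records(rng.integers(1, 6, size=10))
        (rec,) = scan_balancing(records, 10, 5, background_g)
        assert (rec.start, rec.end) == (100, 1000)
        assert rec.position == (100 + 1000) / 2

    def test_matches_single_window_evaluation(self, background_g, rng):
        records = self._records(rng.integers(1, 6, size=10))
        (scanned,) = scan_balancing(records, 10, 5, background_g)
        direct = b0maf_window(snp_windows(records, 10, 5)[0], background_g)
        assert scanned.clr == direct.clr

    def test_implanted_balancing_scores_above_neutral(self):
        """A long-established balanced polymorphism should raise the maximum
        window CLR well above a matched neutral chromosome."""
        from ayescan.demography import PiecewiseDemography
        from ayescan.forward_sim import (
            DFEConfig,
            SelectionScenario,
            build_architecture,
            run_forward,
        )
        from ayescan.sfs_stats import background_spectrum

        model = PiecewiseDemography.default_aye_aye()
        arch = build_architecture()
        sel = [
            run_forward(
                model, arch, DFEConfig(),
                SelectionScenario("balancing", tau=10, f_eq=0.5),
                Q=100, seed=40 + i,
            )
            for i in range(3)
        ]
        neu = [
            run_forward(
                model, arch, DFEConfig(), SelectionScenario("neutral"),
                Q=100, seed=70 + i,
            )
            for i in range(3)
        ]
        G = background_spectrum(
            [r for rep in neu for r in rep.records], pseudocount=0.5
        )

        def score(rep):
            return max(r.clr for r in scan_balancing(list(rep.records), 10, 5, G))

        assert np.median([score(r) for r in sel]) > np.median(
            [score(r) for r in neu]
        )
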