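import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ayescan.io_formats import AlleleFrequencyRecord
from ayescan.sfs_stats import FoldedSFS
from ayescan.sweep_clr import (
    ScanRecord,
    SweepScanTable,
    escape_probability,
    scan_sweep,
    sweep_clr_at,
    sweep_spectrum,
)

from .oracles import sweep_spectrum_by_enumeration


class TestEscapeProbability:
    def test_fully_linked_clamps_to_floor(self):
        assert escape_probability(0.01, 0.0) == pytest.approx(1e-12)

    def test_unlinked_limit(self):
        assert escape_probability(1.0, 1e6) == 1.0

    def test_closed_form_half(self):
        assert escape_probability(1.0, math.log(2)) == pytest.approx(0.5, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            escape_probability(0.0, 1.0)
        with pytest.raises(ValueError):
            escape_probability(1.0, -1.0)


@st.composite
def folded_spectra(draw, n):
    weights = draw(
        st.lists(st.floats(0.05, 1.0), min_size=n // 2, max_size=n // 2)
    )
    w = np.array(weights)
    return FoldedSFS(n, w / w.sum())


class TestSweepSpectrum:
    def test_full_escape_recovers_background(self, background_g):
        out = sweep_spectrum(background_g, 1.0)
        assert np.allclose(out.probs, background_g.probs, atol=1e-12)

    def test_conserves_probability(self, background_g):
        for p_e in (1e-6, 0.01, 0.3, 0.9):
            assert sweep_spectrum(background_g, p_e).probs.sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_uniform_n4_matches_enumeration(self):
        G = FoldedSFS(4, np.array([0.5, 0.5]))
        for p_e in (0.1, 0.5, 0.9):
            expected = sweep_spectrum_by_enumeration(G.probs, 4, p_e)
            assert np.allclose(sweep_spectrum(G, p_e).probs, expected, atol=1e-12)

    @given(folded_spectra(6), st.floats(0.01, 0.99))
    def test_matches_enumeration_oracle_n6(self, G, p_e):
        expected = sweep_spectrum_by_enumeration(G.probs, 6, p_e)
        assert np.allclose(sweep_spectrum(G, p_e).probs, expected, atol=1e-12)

    def test_rare_class_mass_approaches_background_as_pe_grows(self, background_g):
        # near the sweep the spectrum piles up on the rarest folded class;
        # the excess over G(1) decays with escape and vanishes at p_e = 1
        grid = [0.02, 0.1, 0.3, 0.6]
        mass = [sweep_spectrum(background_g, p).probs[0] for p in grid]
        assert all(a >= b - 1e-12 for a, b in zip(mass, mass[1:]))
        g1 = background_g.probs[0]
        tail = [abs(sweep_spectrum(background_g, p).probs[0] - g1)
                for p in (0.6, 0.9, 0.99, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(tail, tail[1:]))
        assert tail[-1] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_escape_probability(self, background_g):
        for p_e in (0.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                sweep_spectrum(background_g, p_e)


def _iid_records(G, m, rng, spacing=1000):
    classes = rng.choice(np.arange(1, G.n // 2 + 1), size=m, p=G.probs)
    return [
        AlleleFrequencyRecord(spacing * (i + 1), int(x), G.n)
        for i, x in enumerate(classes)
    ]


class TestSweepScan:
    def test_single_class_data_has_zero_clr_everywhere(self):
        # n = 2: only folded class 1 exists, both models are certain
        G = FoldedSFS(2, np.array([1.0]))
        records = [AlleleFrequencyRecord(100, 1, 2)]
        rec = sweep_clr_at(50.0, records, G)
        assert rec.clr == pytest.approx(0.0, abs=1e-9)

    def test_unlinked_test_position_has_zero_clr(self, background_g, rng):
        records = _iid_records(background_g, 50, rng)
        far = 1e13  # alpha*d beyond the table for every grid alpha
        rec = sweep_clr_at(far, records, background_g)
        assert rec.clr == pytest.approx(0.0, abs=1e-9)

    def test_exact_background_composition_unlinked_is_exactly_zero(
        self, background_g
    ):
        # beyond the linkage cutoff every per-site spectrum equals G, so with
        # class counts exactly proportional to G the CLR is identically 0
        records = []
        pos = 1
        for x, count in [(1, 50), (2, 30), (3, 10), (4, 6), (5, 4)]:
            for _ in range(count):
                records.append(AlleleFrequencyRecord(pos, x, 10))
                pos += 137
        assert sweep_clr_at(1e13, records, background_g).clr == 0.0

    def test_one_record_per_grid_position(self, background_g, rng):
        records = _iid_records(background_g, 3, rng)
        assert len(scan_sweep(records, background_g)) == 3

    def test_input_order_invariance(self, background_g, rng):
        records = _iid_records(background_g, 30, rng)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = scan_sweep(records, background_g)
        b = scan_sweep(shuffled, background_g)
        assert [(r.position, r.clr) for r in a] == [(r.position, r.clr) for r in b]

    def test_grid_override_restricts_positions(self, background_g, rng):
        records = _iid_records(background_g, 30, rng)
        grid = np.array([5000.0, 15000.0])
        out = scan_sweep(records, background_g, grid=grid)
        assert [r.position for r in out] == [5000.0, 15000.0]

    def test_empty_inputs_rejected(self, background_g, rng):
        with pytest.raises(ValueError):
            scan_sweep([], background_g)
        with pytest.raises(ValueError):
            scan_sweep(
                _iid_records(background_g, 3, rng), background_g, grid=np.array([])
            )

    def test_background_with_empty_class_rejected(self):
        G = FoldedSFS(10, np.array([0.5, 0.5, 0.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            SweepScanTable(G)

    def test_clr_non_negative_on_random_data(self, background_g, rng):
        table = SweepScanTable(background_g)
        for _ in range(50):
            records = _iid_records(background_g, 25, rng, spacing=500)
            for rec in scan_sweep(records, background_g, table=table):
                assert rec.clr >= -1e-9

    def test_strong_sweep_spectrum_is_detected(self, background_g):
        # all sites at the rarest class near the test position: sweep-like
        records = [AlleleFrequencyRecord(1000 + 10 * i, 1, 10) for i in range(40)]
        rec = sweep_clr_at(1200.0, records, background_g)
        assert rec.clr > 10.0
        assert rec.alpha_hat is not None


class TestScanRecordInvariant:
    def test_negative_clr_rejected(self):
        with pytest.raises(ValueError):
            ScanRecord(position=1.0, clr=-1e-3)


class TestImplantedSweepDetection:
    def test_strong_recent_sweeps_score_above_neutral_replicates(self):
        """Strong recent sweeps erase variation across the whole simulated
        region (the sweep footprint exceeds the region length), so the scan's
        signature is a region-wide elevated CLR rather than a localized peak:
        sweep replicates should separate cleanly from matched neutral ones by
        their maximum CLR."""
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
        scenario = SelectionScenario("sweep", tau=0.1, s2N=10_000)
        sel = [
            run_forward(model, arch, DFEConfig(), scenario, Q=100, seed=300 + i)
            for i in range(8)
        ]
        neu = [
            run_forward(
                model, arch, DFEConfig(), SelectionScenario("neutral"),
                Q=100, seed=800 + i,
            )
            for i in range(8)
        ]
        G = background_spectrum(
            [r for rep in neu for r in rep.records], pseudocount=0.5
        )
        table = SweepScanTable(G)

        def score(rep):
            return max(r.clr for r in scan_sweep(list(rep.records), G, table=table))

        sweep_scores = np.array([score(r) for r in sel])
        neutral_scores = np.array([score(r) for r in neu])
        auc = np.mean(sweep_scores[:, None] > neutral_scores[None, :])
        assert auc > 0.65
        assert np.median(sweep_scores) > np.median(neutral_scores)
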