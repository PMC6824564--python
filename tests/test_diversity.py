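import numpy as np
import pytest

from oracles import naive_pi_windows
from plastoflip import (GeneBlock, SimConfig, hotspot_rank, pi_sliding,
                        revcomp, simulate_dataset)
from plastoflip.diversity import PiWindow
from plastoflip.io import Alignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _aln(rows):
    return Alignment(labels=[f"t{i}" for i in range(len(rows))], rows=rows)


def _mutate(seq, positions):
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestPiSliding:
    def test_identical_rows_give_zero(self):
        rows = ["ACGT" * 150] * 3
        assert all(w.pi == 0 for w in pi_sliding(_aln(rows)))

    def test_six_differences_over_600_sites(self):
        base = "ACGT" * 150
        rows = [base, _mutate(base, range(0, 60, 10))]
        windows = pi_sliding(_aln(rows))
        assert len(windows) == 1
        assert windows[0].pi == pytest.approx(0.01)
        assert windows[0].n_valid_sites == 600

    def test_three_row_nei_average(self):
        # pairwise differences 2, 4 and 6 -> pi = ((2+4+6)/3)/600
        base = "ACGT" * 150
        r2 = _mutate(base, [10, 20])            # d(1,2) = 2
        r3 = _mutate(base, [100, 110, 120, 130])  # d(1,3) = 4; d(2,3) = 6
        windows = pi_sliding(_aln([base, r2, r3]))
        assert windows[0].pi == pytest.approx(0.006667, abs=1e-6)

    def test_gapped_columns_excluded_from_denominator(self):
        base = "ACGT" * 150
        gapped = "-" * 100 + _mutate(base, [200])[100:]
        windows = pi_sliding(_aln([base, gapped]))
        assert windows[0].n_valid_sites == 500
        assert windows[0].pi == pytest.approx(1 / 500)

    def test_all_gap_window_reports_missing_not_zero(self):
        rows = ["-" * 600 + "ACGT" * 150, "N" * 600 + "ACGT" * 150]
        windows = pi_sliding(_aln(rows), window=600, step=600)
        assert windows[0].pi is None
        assert windows[1].pi == 0

    def test_matches_naive_computation(self):
        rng = np.random.default_rng(77)
        base = _BASES[rng.integers(0, 4, 1500)].tobytes().decode()
        rows = [base]
        for _ in range(4):
            rows.append(_mutate(base, rng.choice(1500, 40, replace=False)))
        got = [w.pi for w in pi_sliding(_aln(rows), window=400, step=150)]
        want = naive_pi_windows(rows, window=400, step=150)
        assert got == pytest.approx(want)

    def test_row_permutation_and_revcomp_invariance(self):
        rng = np.random.default_rng(5)
        base = _BASES[rng.integers(0, 4, 800)].tobytes().decode()
        rows = [base, _mutate(base, [3, 77, 500]), _mutate(base, [10, 600])]
        ref = [w.pi for w in pi_sliding(_aln(rows), 200, 200)]
        perm = [w.pi for w in pi_sliding(_aln(rows[::-1]), 200, 200)]
        rc = [w.pi for w in pi_sliding(_aln([revcomp(r) for r in rows]),
                                       200, 200)]
        assert ref == perm
        assert ref == pytest.approx(rc[::-1])

    def test_fewer_than_two_rows_fatal(self):
        with pytest.raises(ValueError):
            pi_sliding(_aln(["ACGT" * 200]))

    def test_jc_simulation_recovers_expected_divergence(self):
        # two taxa, total expected divergence t = 0.03 subs/site; the
        # expected proportion of differing sites under Jukes-Cantor is
        # p = 3/4 (1 - exp(-4t/3)) ~ 0.0294
        t = 0.03
        reps, pis = 30, []
        for seed in range(reps):
            cfg = SimConfig(seed=seed, newick=f"(a:{t / 2},b:{t / 2});",
                            lsc_blocks=[GeneBlock("sp", 2000)],
                            ssc_blocks=[GeneBlock("ssp", 500)], ir_len=300,
                            ir_rate_scale=1.0)
            _, aln, _ = simulate_dataset(cfg)
            for w in pi_sliding(aln, window=600, step=600):
                pis.append(w.pi)
        p_expected = 0.75 * (1 - np.exp(-4 * t / 3))
        mean = np.mean(pis)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(mean - p_expected) < 3 * se + 1e-4


class TestHotspots:
    def _windows(self, pis):
        return [PiWindow(i * 200, i * 200 + 600, i * 200 + 300, p, 600)
                for i, p in enumerate(pis)]

    def test_all_below_threshold_gives_empty(self):
        assert hotspot_rank(self._windows([0.001, 0.01, 0.0])) == []

    def test_threshold_zero_spans_all_defined_windows(self):
        regions = hotspot_rank(self._windows([0.001, 0.01, 0.0]),
                               threshold=0.0)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 1000)

    def test_regions_ranked_by_peak(self):
        regions = hotspot_rank(
            self._windows([0.02, 0.001, 0.05, 0.03, 0.001, 0.016]))
        assert [r.peak_pi for r in regions] == [0.05, 0.02, 0.016]

    def test_planted_divergent_spacer_found(self):
        # taxa differ only inside one spacer: the single hotspot covers it
        rng = np.random.default_rng(12)
        base = _BASES[rng.integers(0, 4, 4000)].tobytes().decode()
        other = _mutate(base, 1500 + rng.choice(400, 30, replace=False))
        windows = pi_sliding(_aln([base, other]), window=600, step=200)
        regions = hotspot_rank(windows, threshold=0.015)
        assert len(regions) == 1
        assert regions[0].start <= 1500 < 1900 <= regions[0].end


class TestIRConservation:
    def test_ir_windows_depressed_relative_to_single_copy(
            self, survey_like_dataset):
        # IR copies evolve concertedly, so IRa mirrors IRb and the IR
        # tract contributes no extra divergence relative to single copy
        records, aln, truth = survey_like_dataset
        part = records[0].partition
        windows = pi_sliding(aln, window=600, step=200)
        ir_pis, sc_pis = [], []
        for w in windows:
            if w.pi is None:
                continue
            regions = [part.compartment_of(c)
                       for c in (w.window_start, w.window_end - 1)]
            if set(regions) <= {"IRa", "IRb"}:
                ir_pis.append(w.pi)
            elif set(regions) <= {"LSC", "SSC"}:
                sc_pis.append(w.pi)
        assert ir_pis and sc_pis
        assert np.mean(ir_pis) <= np.mean(sc_pis)
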