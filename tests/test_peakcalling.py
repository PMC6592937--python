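"""Window counting, the Fisher/BH/ES statistics, and peak merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

import meripscan as ms
from meripscan.peakcalling import (
    GeneWindowTable,
    fisher_pvalues,
    merge_windows,
    window_starts,
)


def make_model(length, gene_id="g", cds=None):
    cds = cds or (0, 0)
    return ms.TranscriptModel(
        gene_id=gene_id, transcript_id=gene_id + ".1", chrom="c", strand="+",
        exons=((0, length),), cds_start=cds[0], cds_end=cds[1],
    )


def make_table(ip, inp, gene_id="g", length=None, window=100, step=10):
    ip = np.asarray(ip)
    inp = np.asarray(inp)
    length = length or (len(ip) - 1) * step + window
    return GeneWindowTable(
        gene_id=gene_id, length=length, window=window, step=step,
        starts=np.arange(len(ip)) * step, ip_counts=ip, input_counts=inp,
        n_ip_fragments=int(ip.sum()), n_input_fragments=int(inp.sum()),
    )


class TestWindowArithmetic:
    @pytest.mark.parametrize(
        "length,expected",
        [(1000, 91), (100, 1), (109, 1), (110, 2), (99, 1), (5, 1)],
    )
    def test_window_count(self, length, expected):
        assert len(window_starts(length)) == expected

    def test_starts_are_multiples_of_step(self):
        s = window_starts(1000)
        assert s[0] == 0 and set(np.diff(s)) == {10}

    def test_fragment_hits_every_window_it_overlaps(self):
        model = make_model(1000)
        table = ms.count_windows(model, (np.array([0]), np.array([150])),
                                 (np.array([], int), np.array([], int)))
        # window [w, w+100) overlaps [0, 150) iff w < 150
        expected = (table.starts < 150).astype(int)
        assert np.array_equal(table.ip_counts, expected)
        assert table.ip_counts[table.starts == 60][0] == 1
        assert table.ip_counts[table.starts == 150][0] == 0

    def test_short_transcript_single_full_window(self):
        model = make_model(99)
        table = ms.count_windows(model, (np.array([0, 90]), np.array([99, 99])),
                                 (np.array([], int), np.array([], int)))
        assert len(table.starts) == 1 and table.ip_counts[0] == 2

    def test_median_is_over_all_windows(self):
        table = make_table([2, 4, 6], [0, 0, 1])
        assert table.ip_median == 4
        norm_ip, _ = ms.normalize_counts(
            make_table([2, 4, 6], [1, 1, 1])
        )
        assert np.allclose(norm_ip, [0.5, 1.0, 1.5])

    def test_zero_reads_table_is_valid_zeros(self):
        model = make_model(500)
        empty = (np.array([], int), np.array([], int))
        table = ms.count_windows(model, empty, empty)
        assert table.ip_counts.sum() == 0 and len(table.starts) == 41


class TestLowWindowFilter:
    def test_excluded_only_if_low_in_both(self):
        # tops: ip 200, input 100 -> thresholds 10 and 5
        table = make_table([200, 5, 15, 10], [100, 3, 2, 4])
        retained = ms.filter_low_windows(table)
        # (5,3): both below -> excluded; (15,2): ip side suffices -> retained
        # (10,4): ip at threshold (10 >= 10) -> retained
        assert retained.tolist() == [True, False, True, True]

    def test_medians_unchanged_by_filtering(self):
        table = make_table([200, 5, 15, 10], [100, 3, 2, 4])
        before = (table.ip_median, table.input_median)
        ms.filter_low_windows(table)
        assert (table.ip_median, table.input_median) == before


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 5, 5, 5), 0.6718591006516704),
            ((10, 0, 0, 10), 1 / 184756),
            ((0, 0, 0, 0), 1.0),
        ],
    )
    def test_reference_values(self, table, expected):
        assert ms.fisher_window_test(*table) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_one_sided(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, c, ar, cr = rng.integers(0, 40, size=4)
            ours = ms.fisher_window_test(int(a), int(c), int(ar), int(cr))
            _, ref = fisher_exact([[a, c], [ar, cr]], alternative="greater")
            assert ours == pytest.approx(ref, abs=1e-10)

    @given(a=st.integers(0, 20), c=st.integers(1, 20), ar=st.integers(1, 20),
           cr=st.integers(0, 20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_ip_count(self, a, c, ar, cr):
        """More IP fragments in the window (margins fixed) never raises p."""
        p_lo = ms.fisher_window_test(a, c, ar, cr)
        # shift one unit along the diagonal: margins unchanged, window IP +1
        p_hi = ms.fisher_window_test(a + 1, c - 1, ar - 1, cr + 1)
        assert p_hi <= p_lo + 1e-12

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ms.fisher_window_test(-1, 0, 0, 0)


class TestBH:
    def hand_bh(self, p):
        """Independent step-up oracle."""
        p = list(p)
        n = len(p)
        order = sorted(range(n), key=lambda i: p[i])
        q = [None] * n
        best = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            best = min(best, p[i] * n / rank)
            q[i] = best
        return q

    @pytest.mark.parametrize(
        "p",
        [
            [0.01, 0.02, 0.03],
            [0.05],
            [1.0, 1.0, 1.0],
            [0.001, 0.5, 0.9, 0.02, 0.04],
            [0.5, 0.01, 0.01, 0.8],
        ],
    )
    def test_matches_hand_step_up(self, p):
        assert np.allclose(ms.bh_fdr(p), self.hand_bh(p))

    def test_known_example(self):
        assert np.allclose(ms.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        q = ms.bh_fdr(p)
        assert np.all(q >= p - 1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(ms.bh_fdr(p)[perm], ms.bh_fdr(p[perm]))

    def test_empty(self):
        assert len(ms.bh_fdr([])) == 0


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "args,expected",
        [((40, 10, 8, 10), 5.0), ((7, 7, 3, 3), 1.0), ((20, 10, 0, 10), 41.0)],
    )
    def test_values(self, args, expected):
        assert ms.enrichment_score(*args) == expected

    @given(st.integers(0, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50),
           st.floats(0.1, 10), st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_per_sample_rescaling(self, a, b, c, d, s, t):
        """Holds whenever the input count is nonzero (no pseudocount applied)."""
        base = ms.enrichment_score(a, b, c, d)
        scaled = ms.enrichment_score(a * s, b * s, c * t, d * t)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_median_is_contract_violation(self):
        with pytest.raises(ValueError):
            ms.enrichment_score(1, 0, 1, 1)


class TestPositivity:
    @pytest.mark.parametrize(
        "q,es,expected",
        [(0.005, 2.0, True), (0.005, 1.9, False), (0.02, 8.0, False),
         (0.01, 4.0, False)],  # FDR threshold is strict
    )
    def test_thresholds(self, q, es, expected):
        assert ms.call_positive_windows([q], [es])[0] == expected


class TestMergeWindows:
    def test_overlapping_windows_merge(self):
        peaks = merge_windows("g", [0, 10], [3.0, 4.0], [1e-3, 1e-4])
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end, p.n_windows) == (0, 110, 2)
        assert p.min_q == 1e-4
        assert p.summit == 60  # midpoint of the higher-ES window at 10

    def test_gap_makes_two_peaks(self):
        peaks = merge_windows("g", [0, 200], [3.0, 3.0], [1e-3, 1e-3])
        assert [(p.start, p.end) for p in peaks] == [(0, 100), (200, 300)]

    def test_single_window_peak(self):
        (p,) = merge_windows("g", [40], [2.5], [1e-3])
        assert (p.start, p.end, p.summit) == (40, 140, 90)

    def test_merge_is_idempotent(self):
        peaks = merge_windows("g", [0, 10, 20, 200, 210], [1, 2, 3, 4, 5],
                              [0.001] * 5)
        again = merge_windows(
            "g", [p.start for p in peaks], [p.peak_es for p in peaks],
            [p.min_q for p in peaks], window=100,
        )
        # re-merging peak starts cannot split or join anything further
        assert [(p.start) for p in again] == [p.start for p in peaks]

    def test_peaks_disjoint(self):
        rng = np.random.default_rng(5)
        starts = np.unique(rng.integers(0, 200, size=20)) * 10
        peaks = merge_windows("g", starts, rng.random(len(starts)),
                              rng.random(len(starts)))
        for p1, p2 in zip(peaks, peaks[1:]):
            assert p1.end <= p2.start


class TestCallPeaks:
    def _sim_one_gene(self, enrichment=8.0, seed=1):
        params = ms.SimulationParams(
            n_genes=1, sites_per_gene=1, site_enrichment=enrichment,
            coverage=30.0, seed=seed,
        )
        return ms.simulate_dataset(params)

    def test_planted_site_recovered(self):
        ds = self._sim_one_gene()
        result = ms.call_peaks(ds.models, *ds.reads["control"])
        site = ds.sites[0]
        assert any(
            p.start - 50 <= site.position < p.end + 50 for p in result.peaks
        )

    def test_input_equals_ip_gives_no_peaks(self):
        ds = self._sim_one_gene(enrichment=1.0)
        ip, inp = ds.reads["control"]
        result = ms.call_peaks(ds.models, ip, ip)
        assert result.peaks == []

    def test_zero_reads_no_crash(self):
        ds = self._sim_one_gene()
        result = ms.call_peaks(ds.models, [], [])
        assert result.peaks == [] and "G0001" in result.skipped

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            ms.call_peaks({}, [], [])

    def test_every_peak_contains_positive_window(self):
        ds = self._sim_one_gene()
        result = ms.call_peaks(ds.models, *ds.reads["control"])
        pos = result.window_stats[result.window_stats["positive"]]
        for p in result.peaks:
            inside = pos[(pos["gene_id"] == p.gene_id)
                         & (pos["start"] >= p.start)
                         & (pos["start"] < p.end)]
            assert len(inside) >= 1

    def test_deterministic(self):
        ds = self._sim_one_gene()
        r1 = ms.call_peaks(ds.models, *ds.reads["control"])
        r2 = ms.call_peaks(ds.models, *ds.reads["control"])
        assert r1.peaks == r2.peaks
        pd.testing.assert_frame_equal(r1.window_stats, r2.window_stats)
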