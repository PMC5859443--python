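import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chi2

from paraseg.dmr_caller import (
    DMR,
    BinFilterConfig,
    DmrThresholds,
    GeneRecord,
    adjust_bh,
    all_context_dmrs,
    annotate_dmrs,
    call_differential_bins,
    exclude_regions,
    filter_bins,
    merge_bins_to_dmrs,
    promoter_window,
    shared_dmrs,
    test_bin as bin_test,
    test_bins as bins_test,
)
from paraseg.intervals import GenomicInterval

from conftest import long_bins_frame


def lrt_oracle(m1, u1, m2, u2):
    """Independent two-proportion likelihood-ratio p-value by direct
    log-likelihood summation."""
    def ll(k, n, p):
        if p in (0.0, 1.0) and not (k / n == p):
            return -np.inf
        return float(binom.logpmf(k, n, p))

    n1, n2 = m1 + u1, m2 + u2
    full = ll(m1, n1, m1 / n1) + ll(m2, n2, m2 / n2)
    null = ll(m1, n1, (m1 + m2) / (n1 + n2)) + ll(m2, n2, (m1 + m2) / (n1 + n2))
    return float(chi2.sf(2 * (full - null), 1))


class TestFilterBins:
    def test_low_count_bin_removed_in_any_library(self):
        bins = long_bins_frame([
            ("c", 1, 300, "CG", "a", 4, 5),   # total 9 < 10
            ("c", 1, 300, "CG", "b", 10, 5),  # total 15
            ("c", 201, 500, "CG", "a", 10, 0),
            ("c", 201, 500, "CG", "b", 12, 0),
        ])
        kept = filter_bins(bins, BinFilterConfig(min_counts=10, coverage_percentile=100))
        assert set(kept["start"]) == {201}

    def test_boundary_exactly_min_counts_retained(self):
        bins = long_bins_frame([
            ("c", 1, 300, "CG", "a", 5, 5),
            ("c", 1, 300, "CG", "b", 0, 10),
        ])
        kept = filter_bins(bins, BinFilterConfig(min_counts=10, coverage_percentile=100))
        assert len(kept) == 4 - 2  # both library rows of the one bin retained

    def test_high_coverage_bins_removed_by_percentile(self):
        rows = []
        for i in range(960):
            rows.append(("c", 1 + i * 300, (i + 1) * 300, "CG", "a", 10, 10))
        for i in range(4):
            rows.append(("c", 288001 + i * 300, 288300 + i * 300, "CG", "a", 500, 500))
        bins = long_bins_frame(rows)
        # 99th percentile of {960 x 20, 4 x 1000} is 20, so the 4 extreme
        # bins exceed it and the 20-call bins sit exactly at it (retained)
        assert np.percentile(bins.groupby("start")["n_meth"].sum() * 2, 99) == 20
        kept = filter_bins(bins, BinFilterConfig(min_counts=10))
        assert len(kept) == 960
        assert kept["n_meth"].max() == 10

    def test_empty_input(self):
        kept = filter_bins(long_bins_frame([]))
        assert kept.empty


class TestBinTest:
    def test_identical_groups_p_is_one(self):
        res = bin_test(
            {"a1": (5, 5), "a2": (5, 5), "b1": (5, 5), "b2": (5, 5)},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            "A", "B",
        )
        assert res.p_value == pytest.approx(1.0)
        assert res.diff == pytest.approx(0.0)

    def test_strong_difference_matches_oracle(self):
        res = bin_test({"a": (2, 18), "b": (18, 2)}, {"a": "A", "b": "B"}, "A", "B")
        assert res.direction == "hyper"
        assert res.p_value < 1e-4
        assert res.p_value == pytest.approx(lrt_oracle(2, 18, 18, 2), rel=0.10)

    def test_quarter_shift_with_replicates(self):
        res = bin_test(
            {"a1": (30, 70), "a2": (28, 72), "b1": (55, 45), "b2": (53, 47)},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            "A", "B",
        )
        assert res.diff == pytest.approx(0.25, abs=0.01)
        assert res.p_value < 1e-3
        assert res.p_value == pytest.approx(lrt_oracle(58, 142, 108, 92), rel=0.10)

    def test_complete_separation_wald_does_not_crash(self):
        res = bin_test({"a": (0, 20), "b": (20, 0)}, {"a": "A", "b": "B"},
                       "A", "B", method="wald")
        assert 0 <= res.p_value < 0.05

    def test_wald_agrees_with_lrt_on_regular_table(self):
        kwargs = dict(counts={"a": (30, 70), "b": (55, 45)},
                      genotypes={"a": "A", "b": "B"},
                      ref_genotype="A", alt_genotype="B")
        lrt = bin_test(**kwargs, method="lrt").p_value
        wald = bin_test(**kwargs, method="wald").p_value
        # the two flavours agree asymptotically; at p ~ 1e-4 they may
        # differ by tens of percent but stay within a factor of two
        assert 0.5 < wald / lrt < 2.0

    def test_vectorised_matches_single_bin(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(20):
            for lib, g in (("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")):
                m, u = int(rng.integers(1, 60)), int(rng.integers(1, 60))
                rows.append(("c", 1 + 300 * i, 300 * (i + 1), "CG", lib, m, u))
        bins = long_bins_frame(rows)
        res = bins_test(bins, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, "A", "B")
        for row in res.itertuples():
            sub = bins[bins["start"] == row.start]
            single = bin_test(
                {r.library: (r.n_meth, r.n_unmeth) for r in sub.itertuples()},
                {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, "A", "B",
            )
            assert row.p_value == pytest.approx(single.p_value, rel=1e-9)


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5, 0.5], [0.5, 0.5]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert adjust_bh(p) == pytest.approx(expected)

    def test_never_decreases_p_and_preserves_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = adjust_bh(p)
        assert np.all(q >= p)
        assert np.all(q <= 1)

    def test_empty(self):
        assert adjust_bh([]).size == 0


class TestCallDifferential:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "context", "p_value",
                     "mean_prop_ref", "mean_prop_alt", "diff", "direction"],
        )

    def test_fdr_and_effect_thresholds(self):
        res = self._frame([
            ("c", 1, 300, "CG", 1e-4, 0.2, 0.5, 0.30, "hyper"),
            ("c", 201, 500, "CG", 1e-4, 0.2, 0.4, 0.20, "hyper"),
            ("c", 401, 700, "CHH", 0.20, 0.1, 0.6, 0.50, "hyper"),
        ])
        out = call_differential_bins(res, DmrThresholds())
        assert list(out["flagged"]) == [True, False, False]

    def test_flagged_set_shrinks_as_min_diff_grows(self):
        rng = np.random.default_rng(5)
        n = 200
        res = self._frame([
            ("c", 1 + i, 300 + i, "CG", float(rng.uniform(0, 0.05)),
             0.2, 0.2 + d, d, "hyper")
            for i, d in enumerate(rng.uniform(0, 0.6, size=n))
        ])
        sizes = []
        for cut in (0.1, 0.25, 0.4, 0.55):
            out = call_differential_bins(res, DmrThresholds(min_diff={"CG": cut}))
            sizes.append(out["flagged"].sum())
        assert sizes == sorted(sizes, reverse=True)


class TestMergeAndShare:
    def _flagged(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "context", "direction",
                     "mean_prop_ref", "mean_prop_alt"],
        ).assign(flagged=True)

    def test_overlapping_bins_merge(self):
        dmrs = merge_bins_to_dmrs(self._flagged([
            ("c", 1, 300, "CG", "hyper", 0.1, 0.6),
            ("c", 201, 500, "CG", "hyper", 0.1, 0.6),
        ]))
        assert len(dmrs) == 1
        assert (dmrs[0].interval.start, dmrs[0].interval.end) == (1, 500)
        assert dmrs[0].n_bins == 2

    def test_directions_never_merge(self):
        dmrs = merge_bins_to_dmrs(self._flagged([
            ("c", 1, 300, "CG", "hyper", 0.1, 0.6),
            ("c", 201, 500, "CG", "hypo", 0.6, 0.1),
        ]))
        assert len(dmrs) == 2

    def test_transitive_chain(self):
        dmrs = merge_bins_to_dmrs(self._flagged([
            ("c", 1, 300, "CG", "hyper", 0.1, 0.6),
            ("c", 201, 500, "CG", "hyper", 0.1, 0.6),
            ("c", 401, 700, "CG", "hyper", 0.1, 0.6),
        ]))
        assert len(dmrs) == 1
        assert dmrs[0].interval.end == 700

    def test_idempotent(self):
        first = merge_bins_to_dmrs(self._flagged([
            ("c", 1, 300, "CG", "hyper", 0.1, 0.6),
            ("c", 201, 500, "CG", "hyper", 0.1, 0.6),
            ("c", 900, 1200, "CG", "hyper", 0.1, 0.6),
        ]))
        again = merge_bins_to_dmrs(pd.DataFrame([
            {"chrom": d.interval.chrom, "start": d.interval.start,
             "end": d.interval.end, "context": d.context,
             "direction": d.direction, "n_bins": d.n_bins,
             "mean_prop_ref": d.mean_meth["ref"], "mean_prop_alt": d.mean_meth["alt"],
             "flagged": True}
            for d in first
        ]))
        assert [(d.interval, d.n_bins) for d in again] == [
            (d.interval, d.n_bins) for d in first
        ]

    def test_exclusion_regions(self):
        df = pd.DataFrame({
            "chrom": ["ch01", "ch03", "ch02"],
            "start": [5_000_001, 100, 43_999_900],
            "end": [5_000_300, 399, 44_000_200],
        })
        out = exclude_regions(df)
        assert list(out["chrom"]) == ["ch03"]

    def test_exclusion_allow_list(self):
        df = pd.DataFrame({"chrom": ["ch02"], "start": [48_226_401], "end": [48_226_800]})
        assert exclude_regions(df).empty
        kept = exclude_regions(
            df, allow=[GenomicInterval("ch02", 48_226_401, 48_226_800)]
        )
        assert len(kept) == 1

    def _dmr(self, chrom, start, end, context="CG", direction="hyper"):
        return DMR(GenomicInterval(chrom, start, end), context, direction, 1,
                   {"ref": 0.1, "alt": 0.6})

    def test_shared_consensus_across_three_lines(self):
        sets = {
            "L1": [self._dmr("c", 100, 400)],
            "L2": [self._dmr("c", 300, 600)],
            "L3": [self._dmr("c", 350, 500)],
        }
        shared = shared_dmrs(sets)
        assert len(shared) == 1
        s = shared[0]
        assert (s.interval.start, s.interval.end) == (100, 600)
        assert all(len(s.support[ln]) == 1 for ln in sets)

    def test_two_of_three_lines_not_shared(self):
        sets = {
            "L1": [self._dmr("c", 100, 400)],
            "L2": [self._dmr("c", 300, 600)],
            "L3": [],
        }
        assert shared_dmrs(sets) == []

    def test_direction_mismatch_not_shared(self):
        sets = {
            "L1": [self._dmr("c", 100, 400, direction="hyper")],
            "L2": [self._dmr("c", 100, 400, direction="hyper")],
            "L3": [self._dmr("c", 100, 400, direction="hypo")],
        }
        assert shared_dmrs(sets) == []

    def test_order_invariance(self):
        sets = {
            "L1": [self._dmr("c", 100, 400), self._dmr("c", 900, 1200)],
            "L2": [self._dmr("c", 300, 600), self._dmr("c", 1000, 1100)],
            "L3": [self._dmr("c", 350, 500), self._dmr("c", 950, 1250)],
        }
        a = shared_dmrs(sets, ["L1", "L2", "L3"])
        b = shared_dmrs(sets, ["L3", "L1", "L2"])
        assert [s.interval for s in a] == [s.interval for s in b]

    def test_missing_required_line_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            shared_dmrs({"L1": []}, ["L1", "L2"])

    def test_all_context_requires_every_context(self):
        def sh(ctx, start, end):
            from paraseg.dmr_caller import SharedDMR
            return SharedDMR(GenomicInterval("c", start, end), ctx, "hyper", {})

        by_ctx = {"CG": [sh("CG", 100, 400)], "CHG": [sh("CHG", 300, 500)],
                  "CHH": [sh("CHH", 350, 450)]}
        out = all_context_dmrs(by_ctx, "hyper")
        assert len(out) == 1 and out[0].end == 500
        by_ctx["CHH"] = []
        assert all_context_dmrs(by_ctx, "hyper") == []


class TestAnnotation:
    GENES = [
        GeneRecord("geneA", "c", 10_000, 12_000, "+"),
        GeneRecord("geneB", "c", 30_000, 32_000, "-"),
    ]

    def test_promoter_window_strand_aware(self):
        pw = promoter_window(self.GENES[0])
        assert (pw.start, pw.end) == (8000, 9999)
        pw = promoter_window(self.GENES[1])
        assert (pw.start, pw.end) == (32_001, 34_000)

    def test_dmr_in_promoter(self):
        ann = annotate_dmrs([GenomicInterval("c", 9400, 9700)], self.GENES)
        assert ann.iloc[0].tolist() == ["c:9400-9700", "geneA", "promoter"]

    def test_dmr_3kb_upstream_not_associated(self):
        ann = annotate_dmrs([GenomicInterval("c", 6500, 6900)], self.GENES)
        assert ann.empty

    def test_dmr_in_transcribed_sequence(self):
        ann = annotate_dmrs([GenomicInterval("c", 11_000, 11_100)], self.GENES)
        assert ann.iloc[0]["relation"] == "gene_body"

    def test_strandless_gene_skips_promoter(self, caplog):
        gene = GeneRecord("geneC", "c", 100_000, 101_000, ".")
        with caplog.at_level("WARNING"):
            ann = annotate_dmrs([GenomicInterval("c", 99_000, 99_500)], [gene])
        assert ann.empty
        assert "promoter window skipped" in caplog.text

    def test_locus_overlap(self):
        ann = annotate_dmrs(
            [GenomicInterval("c", 500, 700)],
            loci={"sRNA_cluster_1": GenomicInterval("c", 600, 900)},
        )
        assert ann.iloc[0]["relation"] == "locus"
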