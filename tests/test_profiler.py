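import numpy as np
import pandas as pd
import pytest

from bsmethy.profiler import (
    annotate_dmrs,
    context_spectrum,
    correlate_with_array,
    evaluate_dmr_calls,
    fixed_window_profile,
    gold_standard_regions,
    region_profile,
)

from conftest import make_calls


class TestFixedWindowProfile:
    def test_single_window_md(self):
        calls = make_calls([("c", 5, "W", "CGT", 8, 2)])
        prof = fixed_window_profile(calls, window_len=1000)
        assert len(prof) == 1
        assert prof.iloc[0]["md"] == pytest.approx(80.0)
        assert prof.iloc[0]["window_start"] == 1

    def test_windows_tile_and_split_by_strand(self):
        calls = make_calls(
            [
                ("c", 5, "W", "CGT", 1, 1),
                ("c", 1001, "W", "CGT", 1, 0),
                ("c", 6, "C", "CGA", 0, 1),
            ]
        )
        prof = fixed_window_profile(calls, window_len=1000)
        keys = set(zip(prof["window_start"], prof["strand"]))
        assert keys == {(1, "W"), (1001, "W"), (1, "C")}

    def test_pooling_conservation(self):
        rng = np.random.default_rng(4)
        calls = make_calls(
            [("c", int(p), "W", "CGT", int(rng.integers(0, 9)), int(rng.integers(0, 9)))
             for p in rng.choice(50_000, 300, replace=False) + 1]
        )
        prof = fixed_window_profile(calls, window_len=10_000)
        total_c = calls["c_count"].sum()
        total_t = calls["t_count"].sum()
        pooled = (prof["md"] / 100 * prof["depth"]).sum() / prof["depth"].sum() * 100
        assert pooled == pytest.approx(100 * total_c / (total_c + total_t))


class TestContextSpectrum:
    def test_only_cpg_methylated_gives_cpg_fraction_one(self):
        calls = make_calls(
            [("c", 1, "W", "CGT", 5, 0), ("c", 9, "W", "CAG", 0, 5), ("c", 17, "W", "CAA", 0, 5)]
        )
        spectrum, fractions = context_spectrum(calls)
        assert fractions.set_index("context_class")["fraction"]["CpG"] == 1.0
        assert spectrum.set_index("context3")["md"]["CGT"] == 100.0

    def test_uniform_counts_fraction_proportional_to_context_count(self):
        # 2 CpG sites, 1 CHG, 1 CHH, all with c=3
        calls = make_calls(
            [
                ("c", 1, "W", "CGA", 3, 1),
                ("c", 9, "W", "CGT", 3, 1),
                ("c", 17, "W", "CAG", 3, 1),
                ("c", 25, "W", "CTT", 3, 1),
            ]
        )
        _, fractions = context_spectrum(calls)
        f = fractions.set_index("context_class")["fraction"]
        assert f["CpG"] == pytest.approx(0.5)
        assert f["CHG"] == pytest.approx(0.25)
        assert f["CHH"] == pytest.approx(0.25)

    def test_no_methylated_c_gives_missing_fractions(self):
        calls = make_calls([("c", 1, "W", "CGT", 0, 5)])
        _, fractions = context_spectrum(calls)
        assert fractions["fraction"].isna().all()


class TestRegionProfile:
    def test_pooled_md_and_per_site_table(self):
        calls = make_calls([("c", 5, "W", "CGT", 3, 1), ("c", 8, "W", "CGT", 1, 3)])
        regions = pd.DataFrame([{"chrom": "c", "start": 1, "end": 10, "label": "roi"}])
        per_region, per_site = region_profile(calls, regions)
        assert per_region.iloc[0]["md"] == pytest.approx(50.0)
        assert list(per_site["md"]) == [75.0, 25.0]

    def test_uncovered_region_missing(self):
        calls = make_calls([("c", 5, "W", "CGT", 3, 1)])
        regions = pd.DataFrame([{"chrom": "c", "start": 100, "end": 200, "label": "roi"}])
        per_region, _ = region_profile(calls, regions)
        assert np.isnan(per_region.iloc[0]["md"])

    def test_labels_aggregate_independently(self):
        calls = make_calls([("c", 5, "W", "CGT", 4, 0), ("c", 105, "W", "CGT", 0, 4)])
        regions = pd.DataFrame(
            [
                {"chrom": "c", "start": 1, "end": 50, "label": "a"},
                {"chrom": "c", "start": 101, "end": 150, "label": "b"},
            ]
        )
        per_region, _ = region_profile(calls, regions)
        assert dict(zip(per_region["label"], per_region["md"])) == {"a": 100.0, "b": 0.0}

    def test_region_off_chromosome_rejected(self):
        calls = make_calls([("c", 5, "W", "CGT", 3, 1)])
        regions = pd.DataFrame([{"chrom": "c", "start": 90, "end": 200, "label": "x"}])
        with pytest.raises(ValueError):
            region_profile(calls, regions, chrom_lengths={"c": 100})


class TestAnnotateDmrs:
    GENES = pd.DataFrame(
        [
            {"chrom": "c", "start": 10_000, "end": 15_000, "label": "geneA", "strand": "+"},
            {"chrom": "c", "start": 30_000, "end": 35_000, "label": "geneB", "strand": "-"},
        ]
    )

    def _dmr(self, start, end):
        return pd.DataFrame([{"chrom": "c", "start": start, "end": end, "direction": "hyper"}])

    def test_promoter_flag_within_2kb_upstream(self):
        out = annotate_dmrs(self._dmr(8_300, 8_500), self.GENES)  # 1500 bp upstream of geneA
        assert out.iloc[0]["closest_gene"] == "geneA"
        assert bool(out.iloc[0]["promoter"]) is True

    def test_beyond_2kb_not_promoter(self):
        out = annotate_dmrs(self._dmr(7_200, 7_500), self.GENES)  # 2500 bp upstream
        assert bool(out.iloc[0]["promoter"]) is False

    def test_minus_strand_tss_is_gene_end(self):
        out = annotate_dmrs(self._dmr(36_000, 36_400), self.GENES)  # 1 kb upstream of geneB TSS
        assert out.iloc[0]["closest_gene"] == "geneB"
        assert bool(out.iloc[0]["promoter"]) is True

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = pd.DataFrame(
            [
                {"chrom": "c", "start": 1_000, "end": 2_000, "label": "zeta", "strand": "+"},
                {"chrom": "c", "start": 5_000, "end": 6_000, "label": "alpha", "strand": "+"},
            ]
        )
        out = annotate_dmrs(self._dmr(2_900, 3_100), genes)  # TSSs 1900 and 1900 away
        assert out.iloc[0]["closest_gene"] == "alpha"


class TestArrayConcordance:
    def test_perfect_agreement(self):
        calls = make_calls(
            [("c", p, "W", "CGT", c, 12 - c) for p, c in [(10, 12), (20, 6), (30, 0), (40, 9)]]
        )
        beta = pd.DataFrame(
            {"chrom": "c", "pos": [10, 20, 30, 40], "beta": [1.0, 0.5, 0.0, 0.75]}
        )
        r, n, joined = correlate_with_array(calls, beta, min_depth=10)
        assert n == 4 and r == pytest.approx(1.0)

    def test_min_depth_excludes_shallow_loci(self):
        calls = make_calls(
            [("c", 10, "W", "CGT", 9, 0), ("c", 20, "W", "CGT", 10, 0), ("c", 30, "W", "CGT", 0, 10), ("c", 40, "W", "CGT", 5, 5)]
        )
        beta = pd.DataFrame({"chrom": "c", "pos": [10, 20, 30, 40], "beta": [0.9, 1.0, 0.0, 0.5]})
        r, n, joined = correlate_with_array(calls, beta, min_depth=10)
        assert n == 3 and 10 not in set(joined["pos"])

    def test_strands_pool_per_dinucleotide(self):
        # Watson C at 10 and its Crick partner at 11 combine into one locus
        calls = make_calls(
            [("c", 10, "W", "CGT", 3, 2), ("c", 11, "C", "CGA", 4, 3),
             ("c", 20, "W", "CGT", 0, 6), ("c", 30, "W", "CGT", 6, 0)]
        )
        beta = pd.DataFrame({"chrom": "c", "pos": [10, 20, 30], "beta": [7 / 12, 0.0, 1.0]})
        r, n, joined = correlate_with_array(calls, beta, min_depth=5)
        assert n == 3
        locus = joined[joined["pos"] == 10].iloc[0]
        assert locus["depth"] == 12 and locus["md_fraction"] == pytest.approx(7 / 12)
        assert r == pytest.approx(1.0)

    def test_anticorrelated_fixture(self):
        calls = make_calls(
            [("c", p, "W", "CGT", c, 10 - c) for p, c in [(10, 10), (20, 5), (30, 0)]]
        )
        beta = pd.DataFrame({"chrom": "c", "pos": [10, 20, 30], "beta": [0.0, 0.5, 1.0]})
        r, _, _ = correlate_with_array(calls, beta, min_depth=5)
        assert r == pytest.approx(-1.0)

    def test_too_few_loci_gives_missing_r(self):
        calls = make_calls([("c", 10, "W", "CGT", 10, 0), ("c", 20, "W", "CGT", 0, 10)])
        beta = pd.DataFrame({"chrom": "c", "pos": [10, 20], "beta": [1.0, 0.0]})
        r, n, _ = correlate_with_array(calls, beta, min_depth=5)
        assert r is None and n == 2


class TestGoldStandard:
    def _beta(self, values):
        return pd.DataFrame(
            {"chrom": "c", "pos": [v[0] for v in values], "beta": [v[1] for v in values]}
        )

    def test_window_classification(self):
        a = self._beta([(100, 0.10), (600, 0.50), (1100, 0.50), (1600, 0.40)])
        b = self._beta([(120, 0.40), (620, 0.52), (1120, 0.60), (1620, 0.10)])
        gold = gold_standard_regions(a, b)
        assert list(gold.hyper["start"]) == [1]       # 0.10 -> 0.40
        assert list(gold.unchanged["start"]) == [501]  # 0.50 -> 0.52
        assert list(gold.hypo["start"]) == [1501]      # 0.40 -> 0.10
        # 0.50 -> 0.60 is between thresholds: unassigned
        assert 1001 not in set(gold.hyper["start"]) | set(gold.hypo["start"]) | set(
            gold.unchanged["start"]
        )

    def test_window_without_probes_in_both_samples_dropped(self):
        a = self._beta([(100, 0.1)])
        b = self._beta([(600, 0.9)])
        gold = gold_standard_regions(a, b)
        assert len(gold.hyper) == len(gold.hypo) == len(gold.unchanged) == 0

    def test_evaluation_counts_overlaps(self):
        gold = gold_standard_regions(
            self._beta([(i * 500 + 100, 0.1) for i in range(10)]),
            self._beta([(i * 500 + 100, 0.6) for i in range(10)]),
        )
        assert len(gold.hyper) == 10
        dmrs = pd.DataFrame(
            [
                {"chrom": "c", "start": i * 500 + 50, "end": i * 500 + 200, "direction": "hyper"}
                for i in range(9)
            ]
        )
        unchanged = pd.DataFrame(columns=["chrom", "start", "end"])
        out = evaluate_dmr_calls(dmrs, unchanged, gold)
        assert out["hyper"] == pytest.approx(90.0)
        assert out["hypo"] is None  # empty gold class

    def test_direction_must_match(self):
        gold = gold_standard_regions(
            self._beta([(100, 0.1)]), self._beta([(100, 0.6)])
        )
        dmrs = pd.DataFrame([{"chrom": "c", "start": 1, "end": 500, "direction": "hypo"}])
        out = evaluate_dmr_calls(dmrs, pd.DataFrame(columns=["chrom", "start", "end"]), gold)
        assert out["hyper"] == 0.0
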