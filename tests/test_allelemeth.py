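"""Per-CpG allele-specific methylation testing and feature enrichment."""

from math import comb

import numpy as np
import pytest

from derivachrom import allelemeth as am
from derivachrom import simtrio as st


def exact_fisher_oracle(a, b, c, d):
    """Independent oracle: sum hypergeometric point probabilities not
    exceeding that of the observed table, over all tables with the same
    margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_fully_separated_table(self):
        # (10 methylated maternal, 0, 0, 10 unmethylated paternal)
        call = am.test_cpg(am.CpgSiteCounts("c", 1, 10, 0, 0, 10))
        assert call.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert call.significant and call.direction == "maternal"

    def test_equal_proportions_p_one(self):
        call = am.test_cpg(am.CpgSiteCounts("c", 1, 5, 5, 5, 5))
        assert call.p_value == pytest.approx(1.0)
        assert call.direction == "none"

    def test_coverage_filter_excludes_nine_reads(self):
        calls, excluded = am.test_sites(
            [am.CpgSiteCounts("c", 1, 3, 2, 2, 2)]  # total 9
        )
        assert calls == [] and excluded["low_coverage"] == 1

    def test_zero_margin_excluded(self):
        calls, excluded = am.test_sites(
            [am.CpgSiteCounts("c", 1, 0, 0, 6, 6)]
        )
        assert calls == [] and excluded["zero_margin"] == 1

    def test_zero_margin_raises_directly(self):
        with pytest.raises(ValueError):
            am.test_cpg(am.CpgSiteCounts("c", 1, 0, 0, 6, 6))

    def test_matches_exhaustive_enumeration_small_tables(self):
        """Spot-check against the hypergeometric enumeration oracle on a
        grid of tables (the full sweep to total 40 runs in acceptance)."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            got = am.fisher_p(a, b, c, d)
            want = exact_fisher_oracle(a, b, c, d)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)


class TestFeatureEnrichment:
    def test_l1_worked_example(self):
        e = am.enrich_feature(90, 58, "L1")
        assert round(e.p_value, 2) == 0.01
        assert e.chi2 == pytest.approx(2 * 16**2 / 74)
        assert e.significant

    def test_balanced_counts_p_one(self):
        assert am.enrich_feature(50, 50).p_value == pytest.approx(1.0)

    def test_gene_counts_example(self):
        e = am.enrich_feature(196, 145, "gene")
        assert e.chi2 == pytest.approx(2 * 25.5**2 / 170.5)
        assert round(e.p_value, 3) == 0.006

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            am.enrich_feature(0, 0)


def _call(chrom, pos, direction="maternal", p=1e-5):
    site = am.CpgSiteCounts(chrom, pos, 9, 1, 1, 9)
    return am.HypermethylationCall(site, p, direction, True)


class TestAnnotateSites:
    def test_promoter_strand_aware(self):
        calls = [_call("c", 1500), _call("c", 2500)]
        out, _ = am.annotate_sites(
            calls, tss_table=[("c", 2000, "+")], promoter_bp=1000
        )
        assert out[0].feature == "promoter"
        assert out[1].feature == am.NON_REPEAT_INTERGENIC

    def test_centromeric_window(self):
        calls = [_call("c", 1_900_000), _call("c", 2_100_000)]
        out, _ = am.annotate_sites(calls, centromere_positions={"c": 0})
        assert out[0].centromeric and not out[1].centromeric

    def test_priority_repeat_over_gene(self):
        calls = [_call("c", 100)]
        out, _ = am.annotate_sites(
            calls,
            annotation_intervals=[("c", 0, 200, "Alu"), ("c", 0, 200, "gene")],
        )
        assert out[0].feature == "Alu"

    def test_off_chromosome_dropped(self):
        out, dropped = am.annotate_sites(
            [_call("weird", 5)], known_chroms=["c"]
        )
        assert out == [] and dropped == 1


class TestCompareChromosomes:
    def test_effect_confined_to_one_chromosome(self, rng):
        """A maternal effect simulated on one chromosome is enriched only
        there; the null chromosome stays non-significant."""
        effect = st.simulate_null_cpg_counts(rng, 600, 58, 0.5, effect=0.35)
        null = st.simulate_null_cpg_counts(rng, 600, 58, 0.5, effect=0.0)
        sites = [
            am.CpgSiteCounts("chrEff", s.pos, s.mat_meth, s.mat_unmeth,
                             s.pat_meth, s.pat_unmeth)
            for s in effect
        ] + [
            am.CpgSiteCounts("chrNull", s.pos, s.mat_meth, s.mat_unmeth,
                             s.pat_meth, s.pat_unmeth)
            for s in null
        ]
        calls, _ = am.test_sites(sites)
        table = am.compare_chromosomes(calls, control_chroms=["chrNull"])
        eff = table.set_index("chrom").loc["chrEff"]
        ctl = table.set_index("chrom").loc["chrNull"]
        assert bool(eff["significant"]) and eff["mat_sites"] > eff["pat_sites"]
        assert not bool(ctl["significant"])

    def test_label_swap_flips_direction_keeps_p(self, rng):
        sites = st.simulate_null_cpg_counts(rng, 100, 58, 0.5, effect=0.3)
        swapped = [
            am.CpgSiteCounts(s.chrom, s.pos, s.pat_meth, s.pat_unmeth,
                             s.mat_meth, s.mat_unmeth)
            for s in sites
        ]
        calls, _ = am.test_sites(sites)
        calls_sw, _ = am.test_sites(swapped)
        flip = {"maternal": "paternal", "paternal": "maternal", "none": "none"}
        for c1, c2 in zip(calls, calls_sw):
            assert c1.p_value == pytest.approx(c2.p_value)
            assert flip[c1.direction] == c2.direction

    def test_single_chromosome_rejected(self, rng):
        sites = st.simulate_null_cpg_counts(rng, 20, 58, 0.5)
        calls, _ = am.test_sites(sites)
        with pytest.raises(ValueError):
            am.compare_chromosomes(calls)


class TestCalibrationAndPower:
    def test_null_false_positive_rate_small(self, rng):
        """Sanity-size null check; the full 3-SE calibration band runs in
        the acceptance suite."""
        sites = st.simulate_null_cpg_counts(rng, 2000, 58, 0.55, effect=0.0)
        calls, _ = am.test_sites(sites)
        fpr = np.mean([c.p_value < 0.001 for c in calls])
        assert fpr <= 0.004  # ~3 binomial SE above nominal at this n

    def test_power_at_moderate_effect(self):
        """With a 0.4 methylation-rate shift from the generator's baseline
        rate, at the aneusomic coverage it produces (four-copy: ~117x, 3:1
        maternal), at least 80% of truly differential sites are detected
        at alpha 0.001."""
        rng = np.random.default_rng(77)
        sites = st.simulate_null_cpg_counts(
            rng, 500, 117, 0.55, effect=0.4, mat_frac=0.75
        )
        sites = [s for s in sites if s.total >= 30]
        calls, _ = am.test_sites(sites)
        power = np.mean(
            [c.significant and c.direction == "maternal" for c in calls]
        )
        assert power >= 0.8

    def test_simulated_reads_maternal_hypermethylation(self, default_sim):
        """End-to-end: per-read methylation aggregated by true parent shows
        maternal hypermethylation on the derivative chromosome only."""
        paths, truth = default_sim["paths"], default_sim["truth"]
        sites = am.site_counts_from_reads(
            st.meth_records_from_tsv(paths["methylation"]),
            truth["read_parent"],
        )
        calls, _ = am.test_sites(sites)
        table = am.compare_chromosomes(calls)
        row = table.set_index("chrom").loc[truth["main_chrom"]]
        assert row["mat_sites"] > row["pat_sites"]
        assert bool(row["significant"])
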