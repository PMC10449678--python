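"""Informative-SNV selection, read phasing and BAF copy inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from derivachrom import triophase as tp
from derivachrom import simtrio as st


class TestSelectInformative:
    def select_one(self, child, father, mother):
        snvs, skipped = tp.select_informative_snvs(
            [("chr", 100, child, father, mother)]
        )
        return snvs, skipped

    def test_parents_homozygous_for_different_alleles(self):
        snvs, _ = self.select_one("A/B", "A/A", "B/B")
        (s,) = snvs
        assert s.configuration == tp.CONFIG_HOM_HOM
        assert s.allele_to_parent == {"A": "paternal", "B": "maternal"}

    def test_father_het_mother_hom(self):
        snvs, _ = self.select_one("A/B", "A/B", "B/B")
        (s,) = snvs
        assert s.configuration == tp.CONFIG_FATHER_HET
        assert s.allele_to_parent == {"A": "paternal", "B": "either"}

    def test_mother_het_father_hom(self):
        snvs, _ = self.select_one("A/B", "A/A", "A/B")
        (s,) = snvs
        assert s.configuration == tp.CONFIG_MOTHER_HET
        assert s.allele_to_parent == {"B": "maternal", "A": "either"}

    def test_all_het_not_informative(self):
        snvs, skipped = self.select_one("A/B", "A/B", "A/B")
        assert snvs == [] and skipped["not_informative"] == 1

    def test_missing_genotype_skipped_with_count(self):
        snvs, skipped = self.select_one("A/B", None, "B/B")
        assert snvs == [] and skipped["missing_genotype"] == 1

    def test_child_homozygous_excluded(self):
        snvs, skipped = self.select_one("A/A", "A/A", "A/B")
        assert snvs == [] and skipped["child_homozygous"] == 1


class TestClassifyReads:
    @pytest.fixture()
    def snvs(self):
        snvs, _ = tp.select_informative_snvs(
            [
                ("chr", 10, "A/B", "A/A", "B/B"),
                ("chr", 20, "A/B", "A/A", "B/B"),
                ("chr", 30, "A/B", "A/B", "B/B"),  # B is 'either'
            ]
        )
        return snvs

    def test_unanimous_votes(self, snvs):
        (a,) = tp.classify_reads({"r1": [("chr", 10, "B"), ("chr", 20, "B")]}, snvs)
        assert a.call == "maternal"

    def test_inconsistent_votes_conflict(self, snvs):
        (a,) = tp.classify_reads({"r1": [("chr", 10, "B"), ("chr", 20, "A")]}, snvs)
        assert a.call == "conflicting"

    def test_either_votes_abstain(self, snvs):
        (a,) = tp.classify_reads({"r1": [("chr", 10, "B"), ("chr", 30, "B")]}, snvs)
        assert a.call == "maternal"

    def test_no_covered_snv_unclassified(self, snvs):
        (a,) = tp.classify_reads({"r1": [("chr", 999, "A")]}, snvs)
        assert a.call == "unclassified"


class TestBaf:
    @pytest.mark.parametrize(
        "b,total,expected",
        [(5, 10, 0.5), (100, 120, 0.833), (1, 6, 0.167)],
    )
    def test_ratio(self, b, total, expected):
        assert tp.compute_baf(b, total).baf == pytest.approx(expected, abs=5e-4)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tp.compute_baf(0, 0)

    def test_peaks_hexasomic(self):
        peaks = tp.expected_baf_peaks(6)
        assert [round(p, 2) for p in peaks] == [0.17, 0.33, 0.5, 0.67, 0.83]

    def test_peaks_tetrasomic_and_disomic(self):
        assert [round(p, 2) for p in tp.expected_baf_peaks(4)] == [0.25, 0.5, 0.75]
        assert tp.expected_baf_peaks(2) == [0.5]

    @pytest.mark.parametrize(
        "baf,n,m", [(0.17, 6, 1), (0.5, 4, 2), (0.125, 4, 0), (0.83, 6, 5)]
    )
    def test_infer_allelic_copy(self, baf, n, m):
        """Nearest m/N wins; exact midpoints break toward the smaller m."""
        assert tp.infer_allelic_copy(baf, n) == m

    def test_identity_on_exact_fractions(self):
        for n in range(2, 8):
            for m in range(0, n + 1):
                assert tp.infer_allelic_copy(m / n, n) == m

    @settings(max_examples=200, deadline=None)
    @given(
        b=hst.integers(0, 200),
        extra=hst.integers(1, 200),
        n=hst.integers(2, 8),
    )
    def test_relabel_symmetry(self, b, extra, n):
        """Swapping the A/B labels maps baf -> 1-baf and m -> N-m (away
        from exact midpoints, where the low-m tie rule is intentionally
        asymmetric)."""
        from hypothesis import assume

        total = b + extra
        baf = tp.compute_baf(b, total).baf
        flipped = tp.compute_baf(total - b, total).baf
        assert flipped == pytest.approx(1 - baf)
        midpoint = abs((baf * 2 * n) - round(baf * 2 * n)) < 1e-9 and int(
            round(baf * 2 * n)
        ) % 2 == 1
        assume(not midpoint)
        assert tp.infer_allelic_copy(1 - baf, n) == n - tp.infer_allelic_copy(baf, n)


def _obs(ms, n, depth, rng):
    out = []
    for i, m in enumerate(ms):
        total = max(1, int(rng.poisson(depth)))
        b = int(rng.binomial(total, m / n))
        out.append(tp.compute_baf(b, total, "chr", i))
    return out


class TestHaplotypeShift:
    def test_single_shift_located(self, rng):
        obs = _obs([5] * 100 + [4] * 100, 6, 175, rng)
        cps = tp.detect_haplotype_shift(obs, 6)
        assert len(cps) == 1 and abs(cps[0] - 100) <= 5

    def test_constant_m_no_changepoint(self, rng):
        obs = _obs([4] * 120, 6, 175, rng)
        assert tp.detect_haplotype_shift(obs, 6) == []

    def test_two_shifts(self, rng):
        obs = _obs([1] * 80 + [4] * 80 + [1] * 80, 6, 175, rng)
        cps = tp.detect_haplotype_shift(obs, 6)
        assert len(cps) == 2
        assert abs(cps[0] - 80) <= 5 and abs(cps[1] - 160) <= 5

    def test_too_few_observations(self, rng):
        obs = _obs([5] * 10, 6, 175, rng)
        assert tp.detect_haplotype_shift(obs, 6) == []


class TestOnSimulation:
    def test_classification_accuracy(self, default_sim):
        """With the error-free allele model, every classified read matches
        its true parent and nothing conflicts."""
        paths, truth = default_sim["paths"], default_sim["truth"]
        snvs, _ = tp.select_informative_snvs(
            tp.read_trio_vcf(paths["vcf"], "PATIENT", "FATHER", "MOTHER")
        )
        assert snvs, "simulation produced informative SNVs"
        records = st.read_records_from_tsv(paths["reads"])
        assignments = tp.classify_reads(records, snvs)
        classified = [a for a in assignments if a.call in ("maternal", "paternal")]
        assert len(classified) > 100
        correct = sum(
            truth["read_parent"][a.read_id] == a.call for a in classified
        )
        assert correct / len(classified) >= 0.99
        assert sum(a.call == "conflicting" for a in assignments) == 0
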