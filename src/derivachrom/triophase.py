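"""Trio-based read phasing and B-allele-frequency copy inference.

A heterozygous SNV in the child is *informative* when the parental genotypes
determine the parental origin of at least one of its alleles.  Three trio
configurations qualify (child always het, alleles written A/B):

1. AA/BB — parents homozygous for different alleles: both child alleles are
   unambiguous (one per parent).
2. AB/BB — father het, mother hom: only the allele absent from the mother is
   unambiguously paternal; the shared allele could come from either parent.
3. AA/AB — father hom, mother het: mirror of (2), maternal-unambiguous.

Long reads covering informative SNVs vote for a parent; unanimous votes
classify the read, mixed votes mark it conflicting (removed downstream), and
'either' votes abstain.  The B-allele frequency (BAF) at a site with total
copy N and m copies of the B allele concentrates near m/N, so modal BAF maps
back to allelic copy number, and changes in the inferred m along a
constant-copy region flag haplotype shifts (recombination on the derivative).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

PATERNAL = "paternal"
MATERNAL = "maternal"
EITHER = "either"

CONFIG_HOM_HOM = "AA/BB"
CONFIG_FATHER_HET = "AB/BB"
CONFIG_MOTHER_HET = "AA/AB"


@dataclass(frozen=True)
class InformativeSnv:
    chrom: str
    pos: int  # 1-based, VCF convention
    configuration: str
    allele_to_parent: Mapping[str, str]  # allele base -> paternal/maternal/either

    def parent_of(self, base: str) -> str | None:
        return self.allele_to_parent.get(base)


@dataclass
class ReadAssignment:
    read_id: str
    votes: list[tuple[tuple[str, int], str]]  # ((chrom, pos), parent-or-either)
    call: str  # maternal / paternal / unclassified / conflicting


@dataclass(frozen=True)
class BafObservation:
    chrom: str
    pos: int
    b_count: int
    total: int

    @property
    def baf(self) -> float:
        return self.b_count / self.total


def _genotype_alleles(gt: Sequence[str] | str) -> tuple[str, str] | None:
    if gt is None:
        return None
    if isinstance(gt, str):
        sep = "|" if "|" in gt else "/"
        parts = gt.split(sep)
    else:
        parts = list(gt)
    if len(parts) != 2 or any(p in (None, ".", "") for p in parts):
        return None
    return (str(parts[0]), str(parts[1]))


def select_informative_snvs(
    trio_genotypes: Iterable[tuple],
) -> tuple[list[InformativeSnv], dict[str, int]]:
    """Pick child-het SNVs whose parental origin is resolvable from the trio.

    ``trio_genotypes`` yields ``(chrom, pos, child_gt, father_gt, mother_gt)``
    with genotypes as allele pairs (e.g. ``"A/B"`` or ``("A", "B")``).
    Returns the informative sites plus counts of skipped records.
    """
    out: list[InformativeSnv] = []
    skipped = Counter()
    for chrom, pos, child, father, mother in trio_genotypes:
        c = _genotype_alleles(child)
        f = _genotype_alleles(father)
        m = _genotype_alleles(mother)
        if c is None or f is None or m is None:
            skipped["missing_genotype"] += 1
            continue
        if c[0] == c[1]:
            skipped["child_homozygous"] += 1
            continue
        a1, a2 = c
        f_set, m_set = set(f), set(m)
        f_hom, m_hom = len(f_set) == 1, len(m_set) == 1
        mapping: dict[str, str] | None = None
        config = None
        if f_hom and m_hom and f_set != m_set:
            # each child allele traces to one parent
            if f_set == {a1}:
                mapping = {a1: PATERNAL, a2: MATERNAL}
            elif f_set == {a2}:
                mapping = {a2: PATERNAL, a1: MATERNAL}
            if mapping and m_set != {next(k for k, v in mapping.items() if v == MATERNAL)}:
                mapping = None
            config = CONFIG_HOM_HOM
        elif not f_hom and m_hom:
            # the allele absent from the mother must be paternal
            absent = [a for a in (a1, a2) if a not in m_set]
            if len(absent) == 1 and absent[0] in f_set:
                mapping = {absent[0]: PATERNAL}
                mapping[a1 if absent[0] == a2 else a2] = EITHER
            config = CONFIG_FATHER_HET
        elif f_hom and not m_hom:
            absent = [a for a in (a1, a2) if a not in f_set]
            if len(absent) == 1 and absent[0] in m_set:
                mapping = {absent[0]: MATERNAL}
                mapping[a1 if absent[0] == a2 else a2] = EITHER
            config = CONFIG_MOTHER_HET
        if mapping is None:
            skipped["not_informative"] += 1
            continue
        out.append(InformativeSnv(chrom, int(pos), config, mapping))
    return out, dict(skipped)


def read_trio_vcf(path, child: str, father: str, mother: str):
    """Yield (chrom, pos, child_gt, father_gt, mother_gt) allele tuples."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue

            def bases(sample):
                gt = rec.samples[sample].alleles
                if gt is None or any(a is None for a in gt):
                    return None
                return tuple(gt)

            yield rec.chrom, rec.pos, bases(child), bases(father), bases(mother)


def classify_reads(
    read_records: Mapping[str, Sequence[tuple[str, int, str]]],
    informative_snvs: Sequence[InformativeSnv],
) -> list[ReadAssignment]:
    """Assign each read a parental origin from its informative-SNV alleles.

    ``read_records`` maps read id to observed ``(chrom, pos, base)`` calls.
    Unanimous parental votes classify the read; reads voting for both parents
    are conflicting (excluded downstream per the inconsistency rule); reads
    with no informative vote (none covered, or only shared 'either' alleles)
    are unclassified.
    """
    index = {(s.chrom, s.pos): s for s in informative_snvs}
    out = []
    for read_id in read_records:
        votes = []
        for chrom, pos, base in read_records[read_id]:
            snv = index.get((chrom, int(pos)))
            if snv is None:
                continue
            parent = snv.parent_of(base)
            if parent is not None:
                votes.append(((chrom, int(pos)), parent))
        parents = {p for _, p in votes if p != EITHER}
        if not parents:
            call = "unclassified"
        elif len(parents) > 1:
            call = "conflicting"
        else:
            call = parents.pop()
        out.append(ReadAssignment(read_id, votes, call))
    return out


def compute_baf(b_count: int, total: int, chrom: str = "chr", pos: int = 0) -> BafObservation:
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= b_count <= total:
        raise ValueError("b_count must be in [0, total]")
    return BafObservation(chrom, pos, int(b_count), int(total))


def expected_baf_peaks(n_total: int) -> list[float]:
    """Candidate BAF peak positions m/N for heterozygous sites, m=1..N-1."""
    if n_total < 2:
        raise ValueError("total copy number must be >= 2")
    return [m / n_total for m in range(1, n_total)]


def infer_allelic_copy(baf: float, n_total: int) -> int:
    """The B-allele copy count m in 0..N minimizing |baf - m/N| (ties: low m)."""
    if not 0.0 <= baf <= 1.0:
        raise ValueError("baf must be in [0, 1]")
    if n_total < 2:
        raise ValueError("total copy number must be >= 2")
    best_m, best_d = 0, abs(baf)
    for m in range(1, n_total + 1):
        d = abs(baf - m / n_total)
        if d < best_d - 1e-12:
            best_m, best_d = m, d
    return best_m


def detect_haplotype_shift(
    observations: Sequence[BafObservation],
    n_total: int,
    min_seg: int = 10,
) -> list[int]:
    """Changepoints in the allelic-copy sequence along a constant-N region.

    Each observation is mapped to its nearest allelic copy number m, then the
    m sequence is binary-segmented: the split minimizing the summed squared
    deviation from segment means is accepted when the modal m differs
    between the flanks and both flanks hold at least ``min_seg``
    observations, and the two halves are segmented recursively.  Returns
    changepoint indices (position of the first observation of the right
    segment).  Fewer than 2*min_seg (or <20) observations yield no calls.
    """
    if len(observations) < max(20, 2 * min_seg):
        return []
    m = np.array([infer_allelic_copy(o.baf, n_total) for o in observations])
    cps: list[int] = []

    def seg(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_seg:
            return
        x = m[lo:hi]
        best_i, best_cost = None, None
        csum = np.concatenate(([0.0], np.cumsum(x)))
        csq = np.concatenate(([0.0], np.cumsum(x.astype(float) ** 2)))

        def sse(a, b):  # sum of squared deviations from the segment mean
            s, q = csum[b] - csum[a], csq[b] - csq[a]
            return q - s * s / (b - a)

        for i in range(min_seg, n - min_seg + 1):
            cost = sse(0, i) + sse(i, n)
            if best_cost is None or cost < best_cost - 1e-12:
                best_i, best_cost = i, cost
        if best_i is None:
            return
        left_mode = Counter(x[:best_i].tolist()).most_common(1)[0][0]
        right_mode = Counter(x[best_i:].tolist()).most_common(1)[0][0]
        if left_mode == right_mode:
            return
        seg(lo, lo + best_i)
        cps.append(lo + best_i)
        seg(lo + best_i, hi)

    seg(0, len(m))
    return sorted(cps)
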