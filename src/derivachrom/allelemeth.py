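"""Allele-specific CpG methylation testing.

Per CpG site, reads phased to the maternal and paternal haplotypes give a
2x2 table (parent x methylated/unmethylated) tested with a two-sided
Fisher's exact test at alpha = 0.001; a significant site is called
maternally or paternally hypermethylated according to which parent has the
higher methylated proportion.  Sites covered by fewer than 10 reads in
total are excluded, as is any site with a zero parental margin (the
proportion is undefined).  Hypermethylated-site counts are then compared
between parents within genomic feature classes by a 1-df chi-square
goodness-of-fit against a 50:50 split (alpha = 0.05), per chromosome as
well, with the other acrocentric chromosomes serving as controls.

No multiple-testing correction is applied; the fixed alpha thresholds are
the decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_SITE = 0.001
ALPHA_FEATURE = 0.05
MIN_READS = 10

# when intervals overlap, the most specific repeat class wins
FEATURE_PRIORITY = (
    "alpha_satellite",
    "simple_repeat",
    "Alu",
    "L1",
    "LTR",
    "promoter",
    "gene",
)
NON_REPEAT_INTERGENIC = "non_repeat_intergenic"


@dataclass(frozen=True)
class CpgSiteCounts:
    chrom: str
    pos: int
    mat_meth: int
    mat_unmeth: int
    pat_meth: int
    pat_unmeth: int

    def __post_init__(self):
        if min(self.mat_meth, self.mat_unmeth, self.pat_meth, self.pat_unmeth) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.mat_meth + self.mat_unmeth + self.pat_meth + self.pat_unmeth

    @property
    def mat_total(self) -> int:
        return self.mat_meth + self.mat_unmeth

    @property
    def pat_total(self) -> int:
        return self.pat_meth + self.pat_unmeth


@dataclass
class HypermethylationCall:
    site: CpgSiteCounts
    p_value: float
    direction: str  # maternal / paternal / none
    significant: bool
    feature: str | None = None
    centromeric: bool = False


def fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def test_cpg(counts: CpgSiteCounts, alpha: float = ALPHA_SITE) -> HypermethylationCall:
    """Fisher's exact test of maternal vs paternal methylated proportion.

    Callers are expected to have applied the coverage filter; a zero
    parental margin raises because the comparison is undefined.
    """
    if counts.mat_total == 0 or counts.pat_total == 0:
        raise ValueError("zero parental margin: proportion undefined")
    p = fisher_p(counts.mat_meth, counts.mat_unmeth, counts.pat_meth, counts.pat_unmeth)
    significant = p < alpha
    if not significant:
        direction = "none"
    else:
        mat_rate = counts.mat_meth / counts.mat_total
        pat_rate = counts.pat_meth / counts.pat_total
        direction = "maternal" if mat_rate > pat_rate else "paternal"
    return HypermethylationCall(counts, p, direction, significant)


def test_sites(
    sites: Iterable[CpgSiteCounts],
    alpha: float = ALPHA_SITE,
    min_reads: int = MIN_READS,
) -> tuple[list[HypermethylationCall], dict[str, int]]:
    """Apply the coverage filter and test every remaining site.

    Sites with fewer than ``min_reads`` total reads, or with no reads from
    one parent, are excluded; the returned counter reports how many fell to
    each rule.
    """
    calls = []
    excluded = {"low_coverage": 0, "zero_margin": 0}
    for s in sites:
        if s.total < min_reads:
            excluded["low_coverage"] += 1
            continue
        if s.mat_total == 0 or s.pat_total == 0:
            excluded["zero_margin"] += 1
            continue
        calls.append(test_cpg(s, alpha))
    return calls, excluded


def site_counts_from_reads(
    meth_records: Iterable[tuple[str, str, int, int]],
    read_parent: Mapping[str, str],
) -> list[CpgSiteCounts]:
    """Aggregate per-read methylation calls into per-site 2x2 tables.

    ``meth_records`` yields (read_id, chrom, pos, methylated); reads whose
    phased parent is not maternal/paternal are ignored.
    """
    acc: dict[tuple[str, int], list[int]] = {}
    for read_id, chrom, pos, m in meth_records:
        parent = read_parent.get(read_id)
        if parent not in ("maternal", "paternal"):
            continue
        key = (chrom, pos)
        if key not in acc:
            acc[key] = [0, 0, 0, 0]
        idx = (0 if parent == "maternal" else 2) + (0 if m else 1)
        acc[key][idx] += 1
    return [
        CpgSiteCounts(chrom, pos, *vals) for (chrom, pos), vals in sorted(acc.items())
    ]


@dataclass
class FeatureEnrichment:
    feature: str
    mat_sites: int
    pat_sites: int
    chi2: float
    p_value: float
    significant: bool


def enrich_feature(
    mat_sites: int, pat_sites: int, feature: str = "", alpha: float = ALPHA_FEATURE
) -> FeatureEnrichment:
    """1-df chi-square goodness-of-fit of (mat, pat) site counts vs 50:50.

    No continuity correction; the statistic is (mat - pat)^2 / (mat + pat).
    """
    total = mat_sites + pat_sites
    if total <= 0:
        raise ValueError("no hypermethylated sites to compare")
    chi2 = (mat_sites - pat_sites) ** 2 / total
    p = float(stats.chi2.sf(chi2, 1))
    return FeatureEnrichment(feature, mat_sites, pat_sites, chi2, p, p < alpha)


def annotate_sites(
    calls: Sequence[HypermethylationCall],
    annotation_intervals: Sequence[tuple[str, int, int, str]] = (),
    tss_table: Sequence[tuple[str, int, str]] = (),
    centromere_positions: Mapping[str, int] | None = None,
    promoter_bp: int = 1000,
    centromere_radius: int = 2_000_000,
    known_chroms: Sequence[str] | None = None,
) -> tuple[list[HypermethylationCall], int]:
    """Label each call with a feature class and a centromeric flag.

    Features follow a fixed priority when intervals overlap (alpha satellite
    > simple repeat > Alu > L1 > LTR > promoter > gene); sites in no
    interval are non-repeat intergenic.  Promoters are the strand-aware
    ``promoter_bp`` upstream of a TSS; centromeric means within
    ``centromere_radius`` of the chromosome's centromere midpoint.  Sites on
    chromosomes outside ``known_chroms`` (when given) are dropped; the drop
    count is returned.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in annotation_intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    for chrom, tss, strand in tss_table:
        if strand == "+":
            start, end = tss - promoter_bp, tss
        else:
            start, end = tss, tss + promoter_bp
        trees.setdefault(chrom, IntervalTree()).addi(max(0, start), end, "promoter")
    rank = {name: i for i, name in enumerate(FEATURE_PRIORITY)}
    out = []
    dropped = 0
    for call in calls:
        chrom, pos = call.site.chrom, call.site.pos
        if known_chroms is not None and chrom not in known_chroms:
            dropped += 1
            continue
        names = set()
        if chrom in trees:
            names = {iv.data for iv in trees[chrom][pos]}
        named = sorted((n for n in names if n in rank), key=rank.get)
        call.feature = named[0] if named else NON_REPEAT_INTERGENIC
        if centromere_positions and chrom in centromere_positions:
            call.centromeric = abs(pos - centromere_positions[chrom]) <= centromere_radius
        out.append(call)
    return out, dropped


def enrichment_by_feature(
    calls: Sequence[HypermethylationCall], alpha: float = ALPHA_FEATURE
) -> pd.DataFrame:
    """Maternal vs paternal hypermethylated-site counts per feature class."""
    rows = []
    features = sorted({c.feature for c in calls if c.feature is not None})
    for feat in features:
        mat = sum(1 for c in calls if c.feature == feat and c.direction == "maternal")
        pat = sum(1 for c in calls if c.feature == feat and c.direction == "paternal")
        if mat + pat == 0:
            continue
        e = enrich_feature(mat, pat, feat, alpha)
        rows.append(
            {
                "feature": feat, "mat_sites": mat, "pat_sites": pat,
                "chi2": e.chi2, "p_value": e.p_value, "significant": e.significant,
            }
        )
    return pd.DataFrame(rows)


def compare_chromosomes(
    calls: Sequence[HypermethylationCall],
    control_chroms: Sequence[str] | None = None,
    alpha: float = ALPHA_FEATURE,
) -> pd.DataFrame:
    """Per-chromosome hypermethylation direction summary.

    For each chromosome, counts maternally and paternally hypermethylated
    sites and tests the 50:50 split; chromosomes listed in
    ``control_chroms`` are flagged as controls.
    """
    chroms = sorted({c.site.chrom for c in calls})
    if len(chroms) < 2:
        raise ValueError("need calls on at least two chromosomes")
    rows = []
    for chrom in chroms:
        sub = [c for c in calls if c.site.chrom == chrom]
        mat = sum(1 for c in sub if c.direction == "maternal")
        pat = sum(1 for c in sub if c.direction == "paternal")
        if mat + pat > 0:
            e = enrich_feature(mat, pat, chrom, alpha)
            p, chi2, sig = e.p_value, e.chi2, e.significant
        else:
            p, chi2, sig = float("nan"), float("nan"), False
        rows.append(
            {
                "chrom": chrom, "sites_tested": len(sub), "mat_sites": mat,
                "pat_sites": pat, "chi2": chi2, "p_value": p,
                "significant": sig,
                "control": bool(control_chroms and chrom in control_chroms),
            }
        )
    return pd.DataFrame(rows)
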