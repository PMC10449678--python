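"""Breakpoint junction resolution and SV formation-mechanism calls.

An assembled breakpoint consensus spans an SV junction.  Aligning the
reference flank upstream of the junction to a consensus prefix and the
downstream flank to a consensus suffix yields two coordinates on the
consensus: where the left match ends and where the right match starts.
Overlap between them is microhomology; a gap is an untemplated (or
templated-elsewhere) insertion; exact abutment is a blunt join.  Junction
signatures then classify the causal mechanism: long insertions point to
replicative template switching (FoSTeS/MMBIR), short (2-100 bp)
microhomology to alternative end joining, very long homology to NAHR, and
blunt joins to NHEJ.  Insertions of at least 20 bp are searched against the
reference (exact-seed, both strands) to locate their origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

MECH_FOSTES = "FoSTeS/MMBIR"
MECH_ALTEJ = "alt-EJ"
MECH_NHEJ = "NHEJ"
MECH_NAHR = "NAHR-candidate"
MECH_UNKNOWN = "unknown"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class JunctionResolution:
    junction_id: str
    left_match_end: int  # position in consensus, exclusive
    right_match_start: int  # position in consensus
    insertion_seq: str = ""
    resolved: bool = True

    @property
    def microhomology_bp(self) -> int:
        return max(0, self.left_match_end - self.right_match_start)

    @property
    def insertion_bp(self) -> int:
        return len(self.insertion_seq)

    @property
    def blunt(self) -> bool:
        return self.resolved and self.microhomology_bp == 0 and self.insertion_bp == 0


@dataclass(frozen=True)
class MechanismCall:
    event_id: str
    mechanism: str
    evidence: tuple[JunctionResolution, ...]


@dataclass(frozen=True)
class InsertionOrigin:
    insertion_id: str
    hit: tuple[str, int, int, str, float] | None  # chrom, start, end, strand, identity


def _semiglobal_prefix(flank: str, consensus: str, match=1, mismatch=-2, gap=-3):
    """Best end position on the consensus of an alignment consuming the flank.

    The consensus is assumed to begin inside the flank: the flank's leading
    bases may be skipped for free, the consensus is aligned from its first
    base, and the alignment may stop before the consensus ends.  Returns
    (best_score, end_position_in_consensus).
    """
    m, n = len(flank), len(consensus)
    prev = np.zeros(n + 1, dtype=np.int32)
    prev[1:] = gap * np.arange(1, n + 1)
    fl = np.frombuffer(flank.upper().encode(), dtype=np.uint8)
    co = np.frombuffer(consensus.upper().encode(), dtype=np.uint8)
    cur = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur[0] = 0  # free flank-prefix skip
        sub = np.where(co == fl[i - 1], match, mismatch)
        best = prev[:-1] + sub  # diagonal
        np.maximum(best, prev[1:] + gap, out=best)  # gap in consensus
        # gap in flank needs a sequential pass
        run = cur[0]
        for j in range(1, n + 1):
            run = max(best[j - 1], run + gap)
            cur[j] = run
        prev, cur = cur, prev
    j_best = int(prev.argmax())
    return int(prev[j_best]), j_best


def resolve_junction(
    consensus: str,
    left_flank_ref: str,
    right_flank_ref: str,
    junction_id: str = "jct",
    match: int = 1,
    mismatch: int = -2,
    gap: int = -3,
    threshold_frac: float = 0.6,
) -> JunctionResolution:
    """Resolve a consensus against its reference flanks.

    ``left_flank_ref`` ends at the junction on the upstream side (oriented as
    it appears in the consensus); ``right_flank_ref`` starts at the junction
    on the downstream side.  Match-end overlap is microhomology; a gap
    between the matches is the inserted sequence.  Either flank scoring below
    ``threshold_frac`` x its alignable length leaves the junction unresolved.
    """
    ls, left_end = _semiglobal_prefix(left_flank_ref, consensus, match, mismatch, gap)
    rs, rev_end = _semiglobal_prefix(
        right_flank_ref[::-1], consensus[::-1], match, mismatch, gap
    )
    right_start = len(consensus) - rev_end
    lt = threshold_frac * min(len(left_flank_ref), len(consensus))
    rt = threshold_frac * min(len(right_flank_ref), len(consensus))
    if ls < lt or rs < rt:
        return JunctionResolution(junction_id, 0, 0, "", resolved=False)
    ins = consensus[left_end:right_start] if right_start > left_end else ""
    return JunctionResolution(junction_id, left_end, right_start, ins)


def classify_mechanism(
    event_resolutions: Sequence[JunctionResolution],
    event_id: str = "event",
    ins_threshold: int = 10,
    hom_low: int = 2,
    hom_high: int = 100,
) -> MechanismCall:
    """Mechanism for one event from its junction signatures.

    Insertions above ``ins_threshold`` dominate (FoSTeS/MMBIR), then
    microhomology in [hom_low, hom_high] (alt-EJ), then homology beyond
    ``hom_high`` (NAHR candidate); otherwise NHEJ.  Events with multiple
    junctions classify at event level in that dominance order.
    """
    if not event_resolutions:
        raise ValueError("at least one junction resolution required")
    if any(not r.resolved for r in event_resolutions):
        mech = MECH_UNKNOWN
    elif any(r.insertion_bp > ins_threshold for r in event_resolutions):
        mech = MECH_FOSTES
    elif any(hom_low <= r.microhomology_bp <= hom_high for r in event_resolutions):
        mech = MECH_ALTEJ
    elif any(r.microhomology_bp > hom_high for r in event_resolutions):
        mech = MECH_NAHR
    else:
        mech = MECH_NHEJ
    return MechanismCall(event_id, mech, tuple(event_resolutions))


def find_insertion_origin(
    insertion_seq: str,
    reference: Mapping[str, str],
    insertion_id: str = "ins",
    min_len: int = 20,
    min_identity: float = 0.9,
    seed_k: int = 15,
    min_cover: float = 0.9,
) -> InsertionOrigin | None:
    """Locate an inserted sequence in the reference by exact-seed search.

    Exact ``seed_k``-mers of the insertion are scanned against both strands
    of every reference sequence; each seed is extended to the full insertion
    window and scored by ungapped identity.  The best hit is reported when
    its identity is at least ``min_identity`` over at least ``min_cover`` of
    the insertion, else the origin is 'not found' (hit=None).  Insertions
    shorter than ``min_len`` are skipped (returns None).
    """
    L = len(insertion_seq)
    if L < min_len:
        return None
    ins = insertion_seq.upper()
    best: tuple[float, str, int, int, str] | None = None
    for chrom, seq in reference.items():
        for strand in ("+", "-"):
            target = seq.upper() if strand == "+" else revcomp(seq).upper()
            n = len(target)
            for off in range(0, L - seed_k + 1, max(1, seed_k // 2)):
                seed = ins[off : off + seed_k]
                start = 0
                while True:
                    hit = target.find(seed, start)
                    if hit < 0:
                        break
                    start = hit + 1
                    w0 = hit - off
                    w1 = w0 + L
                    c0, c1 = max(0, w0), min(n, w1)
                    if c1 <= c0:
                        continue
                    window = target[c0:c1]
                    frag = ins[c0 - w0 : c0 - w0 + len(window)]
                    matches = sum(a == b for a, b in zip(window, frag))
                    cover = len(window) / L
                    ident = matches / len(window)
                    if cover >= min_cover and ident >= min_identity:
                        if best is None or ident * cover > best[0]:
                            if strand == "+":
                                g0, g1 = c0, c1
                            else:
                                g0, g1 = n - c1, n - c0
                            best = (ident * cover, chrom, g0, g1, strand, ident)
    if best is None:
        return InsertionOrigin(insertion_id, None)
    _, chrom, g0, g1, strand, ident = best
    return InsertionOrigin(insertion_id, (chrom, g0, g1, strand, round(ident, 4)))


def paper_event_resolutions() -> dict[str, list[JunctionResolution]]:
    """The 12 junction-signature events of the dic(21;21) case study.

    Encodes the published homology/insertion signatures per event: SV 2/3/4
    with 4/5/5 bp microhomology, SV 14 with two junctions (3 and 2 bp
    homology), the SV 5-6-7-9 cluster counted as one event (46 and 407 bp
    insertions), SVs 8/10/11/12/13/15 with insertions of 42/49/93/2710 bp
    (and 35, 137, 138 bp for SV 15), and SV 1 blunt.
    """

    def hom(jid, h):
        return JunctionResolution(jid, h, 0)

    def ins(jid, n):
        return JunctionResolution(jid, 0, n, "N" * n)

    return {
        "SV1": [JunctionResolution("SV1.j1", 0, 0, "")],
        "SV2": [hom("SV2.j1", 4)],
        "SV3": [hom("SV3.j1", 5)],
        "SV4": [hom("SV4.j1", 5)],
        "SV5-6-7-9": [ins("SV5679.j1", 46), ins("SV5679.j2", 407)],
        "SV8": [ins("SV8.j1", 42)],
        "SV10": [ins("SV10.j1", 49)],
        "SV11": [ins("SV11.j1", 93)],
        "SV12": [ins("SV12.j1", 26)],
        "SV13": [ins("SV13.j1", 2710)],
        "SV14": [hom("SV14.j1", 3), hom("SV14.j2", 2)],
        "SV15": [ins("SV15.j1", 35), ins("SV15.j2", 137), ins("SV15.j3", 138)],
    }
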