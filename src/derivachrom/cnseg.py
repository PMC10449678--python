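"""Copy-number block segmentation from binned read depth.

Depth is averaged in fixed-size bins (default 500 bp), each bin is assigned a
total copy state by interval thresholding around a disomic baseline, and
maximal runs of a constant state become alphabetically labeled copy-number
blocks.  A block present at total copy ``c`` contributes ``c - 2`` copies to
the derivative chromosome (two copies reside on the normal homologs).

The copy-state interval for state ``k`` is ``[mu*k/2 - 2*sigma,
mu*k/2 + 2*sigma]`` where ``(mu, sigma)`` are the mean and SD of binned depth
over a disomic control region.  Every interval therefore has width ``4*sigma``
and is symmetric about ``mu*k/2``.  Depths falling in no interval are
UNASSIGNED; if intervals overlap (wide sigma) a depth in two intervals is
AMBIGUOUS rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"

DEFAULT_BIN_SIZE = 500
DEFAULT_COPY_STATES = (2, 4, 5, 6)


@dataclass(frozen=True)
class DepthBin:
    """Mean read depth over one genomic bin (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty bin {self.chrom}:{self.start}-{self.end}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")


@dataclass(frozen=True)
class CopyInterval:
    """Depth interval assigned to a total copy state."""

    copy_state: int
    lo: float
    hi: float

    def contains(self, depth: float) -> bool:
        return self.lo <= depth <= self.hi


@dataclass
class CopyBlock:
    """A maximal run of bins at one copy state, labeled in genomic order."""

    label: str
    chrom: str
    start: int
    end: int
    copy_state: int | str

    @property
    def derivative_multiplicity(self) -> int | None:
        """Copies carried by the derivative chromosome (total - 2)."""
        if isinstance(self.copy_state, int):
            return self.copy_state - 2
        return None


def block_labels() -> Iterable[str]:
    """Yield A, B, ..., Z, AA, AB, ... (spreadsheet-column order)."""
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def bin_depth(
    positions: Sequence[int],
    depths: Sequence[float],
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom: str = "chr",
    region_start: int | None = None,
    region_end: int | None = None,
) -> list[DepthBin]:
    """Average per-base depth records into fixed-size bins.

    ``positions``/``depths`` are sorted per-base records.  Bins tile the
    region from its start; a terminal partial bin contributes with its actual
    width, so its mean is still an arithmetic mean over covered bases.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    pos = np.asarray(positions, dtype=np.int64)
    dep = np.asarray(depths, dtype=float)
    if pos.size == 0:
        raise ValueError("empty input region")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    start = int(pos[0]) if region_start is None else int(region_start)
    end = int(pos[-1]) + 1 if region_end is None else int(region_end)
    bins: list[DepthBin] = []
    for b0 in range(start, end, bin_size):
        b1 = min(b0 + bin_size, end)
        sel = (pos >= b0) & (pos < b1)
        mean = float(dep[sel].sum() / (b1 - b0))
        bins.append(DepthBin(chrom, b0, b1, mean))
    return bins


def read_depth_bedgraph(path) -> list[DepthBin]:
    """Load already-binned depth from a bedGraph/TSV (chrom start end depth)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "depth"],
    )
    return [
        DepthBin(r.chrom, int(r.start), int(r.end), float(r.depth))
        for r in df.itertuples()
    ]


def estimate_baseline(
    bins: Sequence[DepthBin], region: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Disomic baseline (mu, sigma) from bins in a control region."""
    depths = np.array(
        [
            b.mean_depth
            for b in bins
            if region is None or (b.start >= region[0] and b.end <= region[1])
        ]
    )
    if depths.size < 2:
        raise ValueError("control region covers fewer than 2 bins")
    return float(depths.mean()), float(depths.std(ddof=1))


def copy_intervals(
    mu: float, sigma: float, k_values: Sequence[int] = DEFAULT_COPY_STATES
) -> list[CopyInterval]:
    """Depth interval [mu*k/2 - 2*sigma, mu*k/2 + 2*sigma] per copy state k."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = []
    for k in sorted(k_values):
        if k < 1:
            raise ValueError("copy states must be >= 1")
        center = mu * k / 2.0
        out.append(CopyInterval(k, center - 2.0 * sigma, center + 2.0 * sigma))
    return out


def call_copy_state(depth: float, intervals: Sequence[CopyInterval]):
    """The unique copy state whose interval contains ``depth``.

    Returns UNASSIGNED when no interval contains the depth and AMBIGUOUS when
    overlapping intervals both do.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    hits = [iv.copy_state for iv in intervals if iv.contains(depth)]
    if not hits:
        return UNASSIGNED
    if len(hits) > 1:
        return AMBIGUOUS
    return hits[0]


def segment_blocks(
    bins: Sequence[DepthBin],
    states: Sequence[int | str],
    merge_gap: int = 2,
    min_run_bins: int = 2,
    min_solid_bins: int = 4,
) -> list[CopyBlock]:
    """Merge maximal runs of identical copy state into labeled blocks.

    Three cleanups are applied to the run-length encoding before labeling:
    UNASSIGNED/AMBIGUOUS runs of at most ``merge_gap`` bins flanked by the
    same state are absorbed; stretches of consecutive sub-``min_solid_bins``
    runs in which a called state *recurs* (the oscillating signature of a
    copy state whose expected depth straddles two interval boundaries) are
    collapsed into a single uncalled segment for mean-depth refinement; and
    remaining called runs shorter than ``min_run_bins`` between agreeing
    flanks (single-bin outliers) are absorbed.  A genuine short block
    between two *different* flanking states survives untouched.  Labels
    follow genomic order.
    """
    if len(bins) != len(states):
        raise ValueError("bins and states differ in length")
    if not bins:
        return []
    runs: list[list] = []  # [state, first_idx, last_idx]
    for i, s in enumerate(states):
        if runs and runs[-1][0] == s:
            runs[-1][2] = i
        else:
            runs.append([s, i, i])

    def merge_same(rr):
        out = []
        for r in rr:
            if out and out[-1][0] == r[0]:
                out[-1][2] = r[2]
            else:
                out.append(r)
        return out

    def absorb(rr, test):
        changed = True
        while changed:
            changed = False
            for i in range(1, len(rr) - 1):
                s, a, b = rr[i]
                if rr[i - 1][0] == rr[i + 1][0] and test(s, b - a + 1):
                    rr[i - 1][2] = rr[i + 1][2]
                    del rr[i : i + 2]
                    changed = True
                    break
        return rr

    uncalled = (UNASSIGNED, AMBIGUOUS)
    runs = absorb(runs, lambda s, n: s in uncalled and n <= merge_gap)
    # collapse oscillation: consecutive short runs where a called state
    # recurs are one segment whose state only the mean depth can decide
    collapsed: list[list] = []
    i = 0
    while i < len(runs):
        j = i
        while j < len(runs) and (runs[j][2] - runs[j][1] + 1) < min_solid_bins:
            j += 1
        called = [runs[k][0] for k in range(i, j) if runs[k][0] not in uncalled]
        span = (runs[j - 1][2] - runs[i][1] + 1) if j > i else 0
        if j - i >= 2 and span >= min_solid_bins + 1 \
                and len(called) != len(set(called)):
            collapsed.append([UNASSIGNED, runs[i][1], runs[j - 1][2]])
        else:
            collapsed.extend(runs[i:j])
        if j == i:
            collapsed.append(runs[i])
            j += 1
        i = j
    runs = merge_same(collapsed)
    runs = absorb(runs, lambda s, n: s not in uncalled and n < min_run_bins)
    runs = absorb(runs, lambda s, n: s in uncalled and n <= merge_gap)
    runs = merge_same(runs)
    labels = block_labels()
    return [
        CopyBlock(next(labels), bins[a].chrom, bins[a].start, bins[b].end, s)
        for s, a, b in runs
    ]


def refine_block_states(
    blocks: Sequence[CopyBlock],
    bins: Sequence[DepthBin],
    mu: float,
    sigma: float,
    k_values: Sequence[int] = DEFAULT_COPY_STATES,
) -> list[CopyBlock]:
    """Assign copy states to uncalled segments from their mean depth.

    Per-bin calling must use non-overlapping intervals, which cannot place
    an odd copy state whose expected depth straddles two interval
    boundaries (five copies sit between the four- and six-copy bands).  A
    multi-bin segment's mean is far less noisy than one bin, so an
    UNASSIGNED/AMBIGUOUS segment is given the state whose expected depth
    mu*k/2 is nearest its mean — provided the residual is within 2*sigma.
    Called segments keep their thresholded state.  Adjacent same-state
    blocks are then re-merged and relabeled.
    """
    refined = []
    for b in blocks:
        state = b.copy_state
        if not isinstance(state, int):
            seg = [x.mean_depth for x in bins
                   if x.chrom == b.chrom and b.start <= x.start < b.end]
            if seg:
                mean = float(np.mean(seg))
                k = min(k_values, key=lambda k: abs(mean - mu * k / 2.0))
                if abs(mean - mu * k / 2.0) <= 2.0 * sigma:
                    state = k
                else:
                    state = UNASSIGNED
        refined.append(CopyBlock(b.label, b.chrom, b.start, b.end, state))
    merged: list[CopyBlock] = []
    for b in refined:
        if merged and merged[-1].copy_state == b.copy_state \
                and merged[-1].chrom == b.chrom and merged[-1].end == b.start:
            merged[-1].end = b.end
        else:
            merged.append(b)
    labels = block_labels()
    for b in merged:
        b.label = next(labels)
    return merged


def polish_boundaries(
    blocks: Sequence[CopyBlock],
    bins: Sequence[DepthBin],
    mu: float,
    window: int = 12,
) -> list[CopyBlock]:
    """Refit each internal boundary between called blocks by least squares.

    The run-length boundary can drift a few bins when the flanking states
    are close in expected depth (four vs five copies); sliding the cut
    within ``window`` bins to minimize the squared deviation of each side
    from its state's expected depth (mu*k/2) relocates it to the maximum-
    likelihood position under the Gaussian noise model.
    """
    out = [CopyBlock(b.label, b.chrom, b.start, b.end, b.copy_state) for b in blocks]
    by_chrom: dict[str, list[DepthBin]] = {}
    for x in bins:
        by_chrom.setdefault(x.chrom, []).append(x)
    for left, right in zip(out, out[1:]):
        if left.chrom != right.chrom:
            continue
        if not (isinstance(left.copy_state, int) and isinstance(right.copy_state, int)):
            continue
        if left.copy_state == right.copy_state:
            continue
        cb = by_chrom[left.chrom]
        idx = [i for i, x in enumerate(cb) if left.start <= x.start < right.end]
        if not idx:
            continue
        lo, hi = idx[0], idx[-1] + 1
        cut0 = next((i for i in idx if cb[i].start >= left.end), None)
        if cut0 is None:
            continue
        m1, m2 = mu * left.copy_state / 2.0, mu * right.copy_state / 2.0
        best_cut, best_cost = cut0, None
        for cut in range(max(lo + 1, cut0 - window), min(hi, cut0 + window + 1)):
            cost = sum((cb[i].mean_depth - m1) ** 2 for i in range(lo, cut)) + sum(
                (cb[i].mean_depth - m2) ** 2 for i in range(cut, hi)
            )
            if best_cost is None or cost < best_cost:
                best_cut, best_cost = cut, cost
        new_edge = cb[best_cut].start
        left.end = new_edge
        right.start = new_edge
    return [b for b in out if b.end > b.start]


def split_blocks_at_breakpoints(
    blocks: Sequence[CopyBlock],
    breakpoints: Sequence[int],
    chrom: str,
    tolerance: int = DEFAULT_BIN_SIZE,
) -> list[CopyBlock]:
    """Split depth-defined blocks at SV breakpoints falling inside them.

    Depth cannot separate genomically adjacent blocks that share a copy
    state; SV junction breakpoints supply those boundaries.  A breakpoint
    strictly inside a block (farther than ``tolerance`` from each existing
    boundary) splits it into two blocks of the same state.  Blocks are
    relabeled in genomic order afterwards.
    """
    cuts = sorted(set(int(bp) for bp in breakpoints))
    out: list[CopyBlock] = []
    for b in blocks:
        if b.chrom != chrom:
            out.append(CopyBlock(b.label, b.chrom, b.start, b.end, b.copy_state))
            continue
        inner = [
            c for c in cuts
            if b.start + tolerance < c < b.end - tolerance
        ]
        edges = [b.start] + inner + [b.end]
        for s, e in zip(edges, edges[1:]):
            out.append(CopyBlock(b.label, b.chrom, s, e, b.copy_state))
    labels = block_labels()
    for b in out:
        b.label = next(labels)
    return out


def harmonize_blocks_with_breakpoints(
    blocks: Sequence[CopyBlock],
    bins: Sequence[DepthBin],
    breakpoints: Sequence[int],
    chrom: str,
    mu: float,
    sigma: float,
    k_values: Sequence[int] = DEFAULT_COPY_STATES,
    bin_size: int = DEFAULT_BIN_SIZE,
    snap_bins: int = 6,
    min_final_bins: int = 5,
) -> list[CopyBlock]:
    """Reconcile depth-defined blocks with SV junction breakpoints.

    Junction breakpoints are base-precise while depth boundaries wander a
    few bins, so (1) depth boundaries within ``snap_bins`` of a breakpoint
    snap onto it, (2) remaining interior breakpoints split their block
    (depth cannot separate same-copy neighbours), and (3) called blocks
    shorter than ``min_final_bins`` whose boundaries are *not*
    junction-supported are merged into a neighbour across an unsupported
    boundary — they are segmentation noise, whereas a genuine short block
    has SV support at both ends.  States are finally re-assigned per block
    from its mean depth (without re-merging across junction boundaries)
    and blocks are relabeled in genomic order.
    """
    cuts = sorted(set(int(c) for c in breakpoints))
    work = [CopyBlock(b.label, b.chrom, b.start, b.end, b.copy_state)
            for b in blocks]
    mine = [b for b in work if b.chrom == chrom]
    other = [b for b in work if b.chrom != chrom]
    # snap depth boundaries to nearby breakpoints
    for left, right in zip(mine, mine[1:]):
        near = [c for c in cuts if abs(c - left.end) <= snap_bins * bin_size]
        if near:
            c = min(near, key=lambda c: abs(c - left.end))
            if c > left.start and c < right.end:
                left.end = c
                right.start = c
    mine = [b for b in mine if b.end > b.start]
    # split at interior breakpoints
    split: list[CopyBlock] = []
    for b in mine:
        inner = [c for c in cuts if b.start + bin_size < c < b.end - bin_size]
        edges = [b.start] + inner + [b.end]
        for s, e in zip(edges, edges[1:]):
            split.append(CopyBlock(b.label, b.chrom, s, e, b.copy_state))
    protected = set(cuts)

    def seg_mean(b: CopyBlock) -> float | None:
        d = [x.mean_depth for x in bins
             if x.chrom == b.chrom and b.start <= x.start < b.end]
        return float(np.mean(d)) if d else None

    def nearest_state(mean: float | None):
        if mean is None:
            return UNASSIGNED
        k = min(k_values, key=lambda k: abs(mean - mu * k / 2.0))
        return k if abs(mean - mu * k / 2.0) <= 2.0 * sigma else UNASSIGNED

    # merge short junction-unsupported blocks into a neighbour
    changed = True
    while changed:
        changed = False
        for i, b in enumerate(split):
            if (b.end - b.start) >= min_final_bins * bin_size:
                continue
            left_open = i > 0 and b.start not in protected
            right_open = i + 1 < len(split) and b.end not in protected
            if not (left_open or right_open):
                continue
            j = i - 1 if left_open else i + 1
            lo, hi = min(split[i].start, split[j].start), max(split[i].end, split[j].end)
            merged = CopyBlock(b.label, b.chrom, lo, hi, b.copy_state)
            split[min(i, j)] = merged
            del split[max(i, j)]
            changed = True
            break
    for b in split:
        b.copy_state = nearest_state(seg_mean(b))
    # a leftover depth boundary between same-state neighbours is not real
    # unless a junction supports it
    merged: list[CopyBlock] = []
    for b in split:
        if (
            merged
            and merged[-1].copy_state == b.copy_state
            and merged[-1].end == b.start
            and b.start not in protected
        ):
            merged[-1].end = b.end
        else:
            merged.append(b)
    split = merged
    out = other + split
    out.sort(key=lambda b: (b.chrom, b.start))
    labels = block_labels()
    for b in out:
        b.label = next(labels)
    return out


def block_boundaries(blocks: Sequence[CopyBlock]) -> list[int]:
    bounds = []
    for blk in blocks:
        bounds.extend((blk.start, blk.end))
    return sorted(set(bounds))


def check_breakpoint_concordance(
    blocks: Sequence[CopyBlock],
    sv_breakpoints: Sequence[int],
    tolerance: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Distance from each SV breakpoint to the nearest block boundary."""
    bounds = np.array(block_boundaries(blocks))
    rows = []
    for bp in sv_breakpoints:
        d = np.abs(bounds - bp)
        i = int(d.argmin())
        rows.append(
            {
                "breakpoint": int(bp),
                "nearest_boundary": int(bounds[i]),
                "distance": int(d[i]),
                "concordant": bool(d[i] <= tolerance),
            }
        )
    return pd.DataFrame(rows)


def write_blocks_bed(blocks: Sequence[CopyBlock], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.label}\t{b.copy_state}\n")


def read_blocks_bed(path) -> list[CopyBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, label, state = line.split("\t")
            state = state.strip()
            blocks.append(
                CopyBlock(
                    label,
                    chrom,
                    int(start),
                    int(end),
                    int(state) if state.isdigit() else state,
                )
            )
    return blocks
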