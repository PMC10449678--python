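"""Patient-specific structural-variant filtering for a trio.

A patient SV call is retained only if it is large enough (>= 100 bp),
well-supported (>= 5 reads), absent from both parents (no parental SV
breakpoint within +/- 300 bp of either patient breakpoint), and adequately
covered in both parents (depth >= 10 at both breakpoints), so that parental
absence is evidence of a de novo event rather than a coverage artifact.
Every rejected call carries the first rule it failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

SV_TYPES = ("DEL", "INS", "DUP", "INV", "BND")

RULE_SIZE = "min_size"
RULE_SUPPORT = "min_support"
RULE_PROXIMITY = "proximity"
RULE_PARENT_DEPTH = "parent_depth"


@dataclass(frozen=True)
class SvCall:
    id: str
    chrom: str
    pos: int
    end: int
    sv_type: str
    size: int
    support_reads: int

    def __post_init__(self):
        if self.size < 0 or self.support_reads < 0:
            raise ValueError("size and support must be >= 0")
        if self.pos > self.end:
            raise ValueError("pos must be <= end")

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.pos, self.end)


@dataclass
class ParentContext:
    """Parental SV calls plus a depth lookup per parent.

    ``depths`` maps parent name to a callable ``(chrom, pos) -> depth``.
    """

    parent_svs: Mapping[str, Sequence[SvCall]]
    depths: Mapping[str, Callable[[str, int], float]]


def depth_track_from_bedgraph(path) -> Callable[[str, int], float]:
    """Depth lookup backed by a bedGraph (0 outside covered intervals)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "depth"],
    )
    tracks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        tracks[str(chrom)] = (
            sub["start"].to_numpy(), sub["end"].to_numpy(), sub["depth"].to_numpy()
        )

    def lookup(chrom: str, pos: int) -> float:
        if chrom not in tracks:
            return 0.0
        starts, ends, depths = tracks[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(depths[i])
        return 0.0

    return lookup


def filter_patient_specific(
    patient_svs: Sequence[SvCall],
    parent_context: ParentContext,
    min_size: int = 100,
    min_support: int = 5,
    proximity: int = 300,
    min_parent_depth: int = 10,
) -> tuple[list[SvCall], list[tuple[SvCall, str]]]:
    """Keep patient SVs passing size, support, parental-proximity and
    parental-depth rules; rejections carry the first failing rule.

    Proximity compares breakpoints to breakpoints: a parental SV breakpoint
    within +/- ``proximity`` of either patient breakpoint rejects the call.
    Parental depth must reach ``min_parent_depth`` in *both* parents at
    *both* patient breakpoints.
    """
    parent_bps: dict[str, dict[str, np.ndarray]] = {}
    for parent, calls in parent_context.parent_svs.items():
        by_chrom: dict[str, list[int]] = {}
        for sv in calls:
            by_chrom.setdefault(sv.chrom, []).extend(sv.breakpoints)
        parent_bps[parent] = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}

    def near_parental(sv: SvCall) -> bool:
        for bps in parent_bps.values():
            arr = bps.get(sv.chrom)
            if arr is None or arr.size == 0:
                continue
            for bp in sv.breakpoints:
                i = int(np.searchsorted(arr, bp))
                for j in (i - 1, i):
                    if 0 <= j < arr.size and abs(int(arr[j]) - bp) <= proximity:
                        return True
        return False

    kept: list[SvCall] = []
    rejected: list[tuple[SvCall, str]] = []
    for sv in patient_svs:
        if sv.size < min_size:
            rejected.append((sv, RULE_SIZE))
        elif sv.support_reads < min_support:
            rejected.append((sv, RULE_SUPPORT))
        elif near_parental(sv):
            rejected.append((sv, RULE_PROXIMITY))
        elif any(
            depth(sv.chrom, bp) < min_parent_depth
            for depth in parent_context.depths.values()
            for bp in sv.breakpoints
        ):
            rejected.append((sv, RULE_PARENT_DEPTH))
        else:
            kept.append(sv)
    return kept, rejected


def annotate_boundary_distance(
    kept_svs: Sequence[SvCall],
    blocks,
    annotations: Sequence[tuple[str, int, int, str]] | None = None,
) -> pd.DataFrame:
    """Nearest copy-number block boundary (and optional annotation class)
    for each breakpoint of each kept SV."""
    from .cnseg import block_boundaries

    bounds = np.array(block_boundaries(blocks))
    tree = None
    if annotations:
        from intervaltree import IntervalTree

        trees: dict[str, IntervalTree] = {}
        for chrom, start, end, name in annotations:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
        tree = trees
    rows = []
    for sv in kept_svs:
        for side, bp in zip(("pos", "end"), sv.breakpoints):
            d = np.abs(bounds - bp)
            i = int(d.argmin())
            row = {
                "sv_id": sv.id,
                "side": side,
                "breakpoint": int(bp),
                "nearest_boundary": int(bounds[i]),
                "distance": int(d[i]),
            }
            if tree is not None:
                hits = tree.get(sv.chrom, None)
                names = sorted(iv.data for iv in hits[bp]) if hits else []
                row["annotation"] = ",".join(names) if names else "intergenic"
            rows.append(row)
    return pd.DataFrame(rows)


def read_sv_tsv(path) -> list[SvCall]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        SvCall(
            str(r.id), str(r.chrom), int(r.pos), int(r.end),
            str(r.sv_type), int(r.size), int(r.support_reads),
        )
        for r in df.itertuples()
    ]


def write_sv_tsv(svs: Sequence[SvCall], path) -> None:
    pd.DataFrame(
        [
            {
                "id": s.id, "chrom": s.chrom, "pos": s.pos, "end": s.end,
                "sv_type": s.sv_type, "size": s.size,
                "support_reads": s.support_reads,
            }
            for s in svs
        ]
    ).to_csv(path, sep="\t", index=False)
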