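"""Synthetic trio generator with a known derivative-chromosome ground truth.

Emulates the data a trio long-read study of an extra maternal dic(21;21)-like
chromosome produces: a reference sequence laid out as labeled copy-number
blocks, trio genotypes with the three informative-SNV configurations, DNA
read records carrying SNV alleles and per-read CpG methylation calls, binned
depth proportional to total copy number, patient/parent SV call sets,
assembled breakpoint consensus sequences with controlled microhomology or
insertion signatures, allelic RNA counts proportional to haplotype copies,
and a truth JSON from which every downstream stage can be validated.

The derivative chromosome is maternal: at total copy ``c`` a locus carries
one paternal and ``c - 1`` maternal copies, so depth scales as ``c/2`` times
the disomic mean, maternal reads outnumber paternal ``(c-1):1``, and the
B-allele frequency of an informative SNV sits near ``(c-1)/c`` or ``1/c``.
The structure itself is a palindrome ``arm + center + mirror(arm)`` around
the unique odd-copy block.

All randomness flows from a single :class:`numpy.random.Generator` seeded by
``SimConfig.seed``; identical configurations produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import permutations, product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import reconstruct as rc
from .junctionseq import revcomp

BASES = "ACGT"


@dataclass(frozen=True)
class BlockSpec:
    label: str
    length: int
    copy_state: int  # total copies: 2, 4, 5 or 6

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("block length must be positive")
        if self.copy_state < 2:
            raise ValueError("copy state must be >= 2")


@dataclass(frozen=True)
class JunctionSpec:
    """An oriented block adjacency with its junction signature.

    ``microhomology`` and ``insertion`` are mutually exclusive; an empty
    insertion with zero microhomology is a blunt join.  ``insertion_from``
    optionally names a reference interval (chrom, start, end, strand) the
    insertion is copied from (templated insertion).
    """

    junction_id: str
    from_block: str
    from_sign: int
    to_block: str
    to_sign: int
    microhomology: int = 0
    insertion: str = ""
    insertion_from: tuple[str, int, int, str] | None = None
    sv_id: str = ""

    def __post_init__(self):
        if self.microhomology and self.insertion:
            raise ValueError("a junction has microhomology or insertion, not both")

    @property
    def edge(self):
        return rc.adjacency_edge(
            (self.from_block, self.from_sign), (self.to_block, self.to_sign)
        )


@dataclass
class DerivativeDesign:
    blocks: list[BlockSpec]
    junctions: list[JunctionSpec]
    derivative_order: tuple[rc.Oriented, ...]
    center_block: str
    maternal_origin: bool = True

    def __post_init__(self):
        self.validate()

    @property
    def arm(self) -> tuple[rc.Oriented, ...]:
        n = len(self.derivative_order)
        return self.derivative_order[: (n - 1) // 2]

    def block(self, label: str) -> BlockSpec:
        return next(b for b in self.blocks if b.label == label)

    def validate(self) -> None:
        counts: dict[str, int] = {}
        for lbl, _ in self.derivative_order:
            counts[lbl] = counts.get(lbl, 0) + 1
        for b in self.blocks:
            if counts.get(b.label, 0) != b.copy_state - 2:
                raise ValueError(
                    f"block {b.label}: derivative uses {counts.get(b.label, 0)} "
                    f"copies but copy state {b.copy_state} implies {b.copy_state - 2}"
                )
        n = len(self.derivative_order)
        if n % 2 != 1:
            raise ValueError("derivative order must have odd length")
        arm = self.derivative_order[: (n - 1) // 2]
        center = self.derivative_order[(n - 1) // 2]
        if center[0] != self.center_block:
            raise ValueError("middle element is not the center block")
        if self.derivative_order != arm + (center,) + rc.mirror(arm):
            raise ValueError("derivative order is not palindromic about the center")
        junction_edges = {j.edge for j in self.junctions}
        order = [b.label for b in self.blocks]
        ref_edges = {
            rc.adjacency_edge((order[i], 1), (order[i + 1], 1))
            for i in range(len(order) - 1)
        }
        for a, b in zip(self.derivative_order, self.derivative_order[1:]):
            e = rc.adjacency_edge(a, b)
            if e not in ref_edges and e not in junction_edges:
                raise ValueError(f"non-reference adjacency {a} > {b} has no junction")


@dataclass
class SimConfig:
    seed: int = 0
    disomic_mean_depth: float = 58.44  # binned depth of the two-copy baseline
    depth_noise_sd: float = 13.41  # SD of binned depth (all copy states)
    snv_density: float = 0.8  # heterozygous SNVs per kb
    rna_depth: float = 60.0  # mean RNA reads per informative SNV
    meth_effect: float = 0.35  # maternal-vs-paternal methylation-rate shift
    cpg_density: float = 8.0  # CpG sites per kb
    read_length_mean: float = 3000.0  # bp
    bin_size: int = 500
    base_meth_rate: float = 0.55
    control_chrom_bp: int = 30_000
    flank_bp: int = 60  # reference flank length in breakpoint consensus
    parent_mean_depth: float = 11.2
    informative_fraction: float = 0.75  # child-het SNVs in informative configs
    main_chrom: str = "chrD"
    control_chrom: str = "chrC"

    def __post_init__(self):
        for name in (
            "disomic_mean_depth", "depth_noise_sd", "snv_density", "rna_depth",
            "cpg_density", "read_length_mean", "base_meth_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.meth_effect <= 1.0:
            raise ValueError("meth_effect must be in [0, 1]")


# ---------------------------------------------------------------------------
# design construction


def _auto_junctions(
    order: Sequence[rc.Oriented],
    block_order: Sequence[str],
    provided: Sequence[JunctionSpec],
) -> list[JunctionSpec]:
    """JunctionSpecs for the non-reference adjacencies of an order, merging
    provided specs by edge and inventing blunt specs for the rest."""
    ref_edges = {
        rc.adjacency_edge((block_order[i], 1), (block_order[i + 1], 1))
        for i in range(len(block_order) - 1)
    }
    by_edge = {j.edge: j for j in provided}
    out: list[JunctionSpec] = []
    seen = set()
    k = 0
    for a, b in zip(order, order[1:]):
        e = rc.adjacency_edge(a, b)
        if e in ref_edges or e in seen:
            continue
        seen.add(e)
        if e in by_edge:
            out.append(by_edge[e])
        else:
            k += 1
            out.append(
                JunctionSpec(f"auto{k}", a[0], a[1], b[0], b[1], sv_id=f"autoSV{k}")
            )
    return out


def design_derivative(
    block_specs: Sequence[tuple[str, int, int] | BlockSpec],
    junction_specs: Sequence[JunctionSpec] = (),
    center_block: str | None = None,
) -> DerivativeDesign:
    """Build a valid palindromic derivative design from blocks and junctions.

    Exactly one block must have an odd total copy state; it is the palindrome
    pivot.  When the provided junctions (plus reference adjacencies) support
    a full arm walk, the design is found by graph enumeration and must use
    every provided junction; otherwise palindromic orders are brute-forced
    from the multiplicities (small designs only) and junctions are
    auto-created for the remaining non-reference adjacencies.  Raises when
    the multiplicities admit no palindromic linear order or a junction names
    an unknown block.
    """
    blocks = [
        b if isinstance(b, BlockSpec) else BlockSpec(*b) for b in block_specs
    ]
    labels = [b.label for b in blocks]
    odd = [b for b in blocks if b.copy_state % 2 == 1]
    if len(odd) != 1:
        raise ValueError(
            "exactly one block must have an odd total copy state "
            "(no palindrome pivot otherwise)"
        )
    center = odd[0].label
    if center_block is not None and center_block != center:
        raise ValueError(f"center_block {center_block} is not the odd-copy block")
    for j in junction_specs:
        if j.from_block not in labels or j.to_block not in labels:
            raise ValueError(f"junction {j.junction_id} references an unknown block")
    mult = {b.label: b.copy_state - 2 for b in blocks}
    graph = rc.build_graph(
        list(zip(labels, (mult[l] for l in labels))),
        [
            rc.JunctionEdge(j.from_block, j.from_sign, j.to_block, j.to_sign, j.sv_id)
            for j in junction_specs
        ],
    )
    usage = rc.arm_usage(graph, center)
    # graph-guided: enumerate arms supported edge-by-edge and keep the
    # parsimony-ranked structure, so the design's ground truth is the
    # structure its own evidence best supports
    anchor = next((b for b in labels if usage.get(b, 0) > 0), None)
    if anchor is not None:
        _, models, _ = rc.reconstruct_structure(graph, center)
        if junction_specs:
            required = {j.edge for j in junction_specs}
            models = [
                m
                for m in models
                if required
                <= {
                    rc.adjacency_edge(a, b)
                    for a, b in zip(m.sequence, m.sequence[1:])
                }
            ]
        if models:
            model = models[0]
            return DerivativeDesign(
                blocks,
                _auto_junctions(model.sequence, labels, junction_specs),
                model.sequence,
                center,
            )
    # brute force palindromic orders over the multiset
    arm_multiset: list[str] = []
    for lbl in labels:
        arm_multiset += [lbl] * usage.get(lbl, 0)
    if len(arm_multiset) > 7:
        raise ValueError("no junction-supported structure and arm too long to enumerate")
    best = None
    for perm in set(permutations(arm_multiset)):
        for signs in product((1, -1), repeat=len(perm)):
            arm = tuple(zip(perm, signs))
            for c_sign in (1, -1):
                order = arm + ((center, c_sign),) + rc.mirror(arm)
                # prefer orders with many reference adjacencies, then lexicographic
                ref_edges = {
                    rc.adjacency_edge((labels[i], 1), (labels[i + 1], 1))
                    for i in range(len(labels) - 1)
                }
                n_ref = sum(
                    rc.adjacency_edge(a, b) in ref_edges
                    for a, b in zip(order, order[1:])
                )
                key = (-n_ref, order)
                if best is None or key < best[0]:
                    best = (key, order)
    if best is None:
        raise ValueError("multiplicities admit no palindromic linear order")
    order = best[1]
    return DerivativeDesign(
        blocks, _auto_junctions(order, labels, junction_specs), order, center
    )


def paper_like_design() -> DerivativeDesign:
    """A small design mirroring the case-study geometry.

    A four-copy block V, the short five-copy center W, a six-copy X and a
    four-copy Y (plus a trailing disomic Z), with a foldback junction
    x(-) > W at the palindrome pivot and a Y > x(-) junction closing the
    six-copy loop — so the derivative order contains the characteristic
    ... X(-) W(+) X(+) ... sub-order around the center.
    """
    blocks = [
        BlockSpec("V", 12000, 4),
        BlockSpec("W", 3500, 5),
        BlockSpec("X", 9000, 6),
        BlockSpec("Y", 8000, 4),
        BlockSpec("Z", 15000, 2),
    ]
    junctions = [
        JunctionSpec("jXW", "X", -1, "W", 1, microhomology=4, sv_id="SV-XW"),
        JunctionSpec("jYX", "Y", 1, "X", -1, insertion="@" * 46, sv_id="SV-YX"),
    ]
    return design_derivative(blocks, junctions)


def random_design(
    rng: np.random.Generator,
    n_blocks: int = 6,
    n_events: int = 2,
    bin_size: int = 500,
    n_post_center: int = 1,
) -> DerivativeDesign:
    """A random derivative design built by applying ``n_events`` structural
    operations (copy-insert / invert) to a reference arm.

    Blocks before the center start at one arm copy each (four-copy);
    copy-inserts raise some to two (six-copy); blocks after the center are
    disomic (absent from the derivative).  The first arm block is pinned as
    the centromere-proximal anchor.  ``n_events`` is the *minimal* event
    count of the resulting arm, verified with the event scorer: random op
    sequences occasionally compose into a shorter description (e.g. an
    inversion followed by an adjacent flipped insert equals one flipped
    insert), and such reducible draws are re-drawn.
    """
    if n_blocks < 3:
        raise ValueError("need at least 3 blocks")
    labels = [_label(i) for i in range(n_blocks)]
    c_idx = n_blocks - 1 - n_post_center
    if c_idx < 2:
        raise ValueError("too many post-center blocks")
    center = labels[c_idx]
    # the arm carries the center once: multiplicity 3 = arm + pivot + mirror
    base = [(labels[i], 1) for i in range(c_idx + 1)]
    max_count = {lbl: (1 if lbl == center else 2) for lbl in labels}
    arm = list(base)
    for _ in range(30):  # re-draw until the op count is irreducible
        arm = list(base)
        applied = 0
        guard = 0
        while applied < n_events and guard < 200:
            guard += 1
            op = rng.choice(["insert", "invert"])
            if op == "invert" and len(arm) >= 2:
                i = int(rng.integers(1, len(arm)))
                j = int(rng.integers(i + 1, len(arm) + 1))
                arm = arm[:i] + list(rc.flip(arm[i:j])) + arm[j:]
                applied += 1
            elif op == "insert":
                i = int(rng.integers(0, len(arm)))
                j = int(rng.integers(i + 1, min(len(arm), i + 2) + 1))
                seg = arm[i:j]
                counts: dict[str, int] = {}
                for lbl, _ in arm:
                    counts[lbl] = counts.get(lbl, 0) + 1
                if any(counts[lbl] + sum(1 for l2, _ in seg if l2 == lbl)
                       > max_count[lbl] for lbl, _ in seg):
                    continue
                piece = list(seg) if rng.random() < 0.5 else list(rc.flip(seg))
                k = int(rng.integers(1, len(arm) + 1))
                arm = arm[:k] + piece + arm[k:]
                applied += 1
        score, _ = rc.score_events(
            tuple(arm), tuple(base), max_depth=max(1, n_events)
        )
        if score != n_events:
            continue
        if _truth_is_parsimony_optimal(arm, labels, center, max_count, c_idx):
            break
    usage: dict[str, int] = {}
    for lbl, _ in arm:
        usage[lbl] = usage.get(lbl, 0) + 1
    blocks = []
    for i, lbl in enumerate(labels):
        if i == c_idx:
            copy = 5
        elif i < c_idx:
            copy = 2 + 2 * usage.get(lbl, 0)
        else:
            copy = 2
        length = int(rng.integers(16, 41)) * bin_size
        if i == c_idx:
            length = max(bin_size * 7, length // 2)  # the odd block is short
        blocks.append(BlockSpec(lbl, length, copy))
    order = tuple(arm) + ((labels[c_idx], 1),) + rc.mirror(arm)
    junctions = _auto_junctions(order, labels, ())
    junctions = _assign_signatures(junctions, rng)
    return DerivativeDesign(blocks, junctions, order, labels[c_idx])


def _truth_is_parsimony_optimal(arm, labels, center, max_count, c_idx) -> bool:
    """True when the generated structure tops (or ties) the ranking of all
    structures consistent with its own junction evidence.

    A palindrome's junction set can admit a strictly more parsimonious
    alternative arm (the two arms of a palindrome read the same end joints
    in opposite order); such a truth is unrecoverable by construction, not
    by method error, so the generator rejects the draw.
    """
    order = tuple(arm) + ((center, 1),) + rc.mirror(tuple(arm))
    mult = {lbl: 0 for lbl in labels}
    for lbl, _ in order:
        mult[lbl] += 1
    junctions = _auto_junctions(order, labels, ())
    g = rc.build_graph(
        [(lbl, mult[lbl]) for lbl in labels],
        [rc.JunctionEdge(j.from_block, j.from_sign, j.to_block, j.to_sign,
                         j.sv_id) for j in junctions],
    )
    try:
        best, models, _ = rc.reconstruct_structure(g, center)
    except ValueError:
        return False
    if best is None:
        return False
    if best.sequence in (order, rc.flip(order)):
        return True
    top = rc.model_rank_key(best, g)[:2]
    return any(
        m.sequence in (order, rc.flip(order))
        for m in models
        if rc.model_rank_key(m, g)[:2] == top
    )


def _label(i: int) -> str:
    import string

    letters = string.ascii_uppercase
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


_SIGNATURE_CYCLE = ("ins_ref", "hom", "ins_novel", "blunt", "hom", "ins_ref")


def _assign_signatures(
    junctions: Sequence[JunctionSpec], rng: np.random.Generator
) -> list[JunctionSpec]:
    """Give auto-created junctions a rotating mix of signature types."""
    out = []
    for i, j in enumerate(junctions):
        kind = _SIGNATURE_CYCLE[i % len(_SIGNATURE_CYCLE)]
        if kind == "hom":
            out.append(
                JunctionSpec(
                    j.junction_id, j.from_block, j.from_sign, j.to_block,
                    j.to_sign, microhomology=int(rng.integers(2, 9)),
                    sv_id=j.sv_id,
                )
            )
        elif kind == "ins_novel":
            n = int(rng.integers(15, 50))
            ins = "".join(BASES[k] for k in rng.integers(0, 4, n))
            out.append(
                JunctionSpec(
                    j.junction_id, j.from_block, j.from_sign, j.to_block,
                    j.to_sign, insertion=ins, sv_id=j.sv_id,
                )
            )
        elif kind == "ins_ref":
            # placeholder: resolved to a templated copy once the reference exists
            n = int(rng.integers(25, 60))
            out.append(
                JunctionSpec(
                    j.junction_id, j.from_block, j.from_sign, j.to_block,
                    j.to_sign, insertion="@" * n, sv_id=j.sv_id,
                )
            )
        else:
            out.append(j)
    return out


# ---------------------------------------------------------------------------
# simulation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[k] for k in rng.integers(0, 4, n))


def _block_coords(design: DerivativeDesign) -> dict[str, tuple[int, int]]:
    coords = {}
    pos = 0
    for b in design.blocks:
        coords[b.label] = (pos, pos + b.length)
        pos += b.length
    return coords


def _breakpoint(coords, label: str, side_sign: int, is_from: bool) -> int:
    start, end = coords[label]
    if is_from:  # exit coordinate
        return end if side_sign > 0 else start
    return start if side_sign > 0 else end  # entry coordinate


def simulate_trio(design: DerivativeDesign, config: SimConfig, outdir) -> dict:
    """Write the full synthetic trio dataset to ``outdir``.

    Returns a dict of output paths plus the truth dictionary.  See the
    module docstring for the generative model; all outputs are deterministic
    functions of (design, config).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    coords = _block_coords(design)
    main_len = sum(b.length for b in design.blocks)
    main, ctrl = config.main_chrom, config.control_chrom

    ref = {
        main: list(_random_seq(rng, main_len)),
        ctrl: list(_random_seq(rng, config.control_chrom_bp)),
    }

    # --- junction signatures: engineer microhomology, resolve templated ins
    junctions = []
    edited: set[int] = set()
    for j in design.junctions:
        mh, ins, ins_from = j.microhomology, j.insertion, j.insertion_from
        if ins.startswith("@"):  # templated: copy a reference interval
            n = len(ins)
            src = int(rng.integers(0, main_len - n))
            strand = "+" if rng.random() < 0.5 else "-"
            piece = "".join(ref[main][src : src + n])
            ins = piece if strand == "+" else revcomp(piece)
            ins_from = (main, src, src + n, strand)
        if mh > 0:
            lf = _oriented_flank(ref[main], coords, j.from_block, j.from_sign,
                                 config.flank_bp, left=True)
            target = _mh_target_positions(coords, j.to_block, j.to_sign, mh)
            if any(p in edited for p in target):
                mh = 0  # collision with a previous engineered junction
            else:
                pat = lf[-mh:]
                if j.to_sign < 0:
                    pat = revcomp(pat)
                for p, base in zip(target, pat):
                    ref[main][p] = base
                edited.update(target)
        junctions.append(
            JunctionSpec(j.junction_id, j.from_block, j.from_sign, j.to_block,
                         j.to_sign, mh, ins, ins_from, j.sv_id)
        )

    ref_str = {c: "".join(s) for c, s in ref.items()}
    paths: dict[str, Path] = {}

    # --- reference FASTA
    paths["reference"] = outdir / "reference.fa"
    _write_fasta(paths["reference"], ref_str)

    # --- breakpoint consensus + manifest
    consensus: dict[str, str] = {}
    manifest_rows = []
    for j in junctions:
        lf = _oriented_flank(ref_str[main], coords, j.from_block, j.from_sign,
                             config.flank_bp, left=True)
        rf = _oriented_flank(ref_str[main], coords, j.to_block, j.to_sign,
                             config.flank_bp, left=False)
        if j.microhomology:
            cons = lf + rf[j.microhomology:]
        else:
            cons = lf + j.insertion + rf
        consensus[j.junction_id] = cons
        lc = _flank_coords(coords, j.from_block, j.from_sign, config.flank_bp, True)
        rcd = _flank_coords(coords, j.to_block, j.to_sign, config.flank_bp, False)
        manifest_rows.append(
            (j.junction_id, j.sv_id, main, *lc, main, *rcd)
        )
    paths["consensus"] = outdir / "consensus.fa"
    _write_fasta(paths["consensus"], consensus)
    paths["junction_manifest"] = outdir / "junctions.tsv"
    with open(paths["junction_manifest"], "w") as fh:
        fh.write(
            "junction_id\tsv_id\tleft_chrom\tleft_start\tleft_end\tleft_strand"
            "\tright_chrom\tright_start\tright_end\tright_strand\n"
        )
        for row in manifest_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    # --- depth bedGraphs (patient + parents)
    paths["depth"] = outdir / "depth_patient.bedgraph"
    truth_blocks = [
        {
            "label": b.label, "chrom": main, "start": coords[b.label][0],
            "end": coords[b.label][1], "copy_state": b.copy_state,
        }
        for b in design.blocks
    ]
    with open(paths["depth"], "w") as fh:
        for b in design.blocks:
            s, e = coords[b.label]
            for b0 in range(s, e, config.bin_size):
                b1 = min(b0 + config.bin_size, e)
                d = _overdispersed_depth(
                    rng, config.disomic_mean_depth * b.copy_state / 2.0,
                    config.depth_noise_sd,
                )
                fh.write(f"{main}\t{b0}\t{b1}\t{d:.2f}\n")
        for b0 in range(0, config.control_chrom_bp, config.bin_size):
            b1 = min(b0 + config.bin_size, config.control_chrom_bp)
            d = _overdispersed_depth(
                rng, config.disomic_mean_depth, config.depth_noise_sd
            )
            fh.write(f"{ctrl}\t{b0}\t{b1}\t{d:.2f}\n")
    low_depth_start = main_len - min(2000, main_len // 10)
    for parent in ("father", "mother"):
        p = outdir / f"depth_{parent}.bedgraph"
        paths[f"depth_{parent}"] = p
        with open(p, "w") as fh:
            for chrom, length in ((main, main_len), (ctrl, config.control_chrom_bp)):
                for b0 in range(0, length, config.bin_size):
                    b1 = min(b0 + config.bin_size, length)
                    mean = config.parent_mean_depth
                    if chrom == main and b0 >= low_depth_start:
                        mean = 3.0  # deliberate low-coverage pocket for filter decoys
                    d = _overdispersed_depth(rng, mean, max(1.0, mean / 4))
                    fh.write(f"{chrom}\t{b0}\t{b1}\t{d:.2f}\n")

    # --- SNVs and trio VCF
    snvs = _simulate_snvs(rng, design, config, coords, ref_str)
    paths["vcf"] = outdir / "trio.vcf"
    _write_trio_vcf(paths["vcf"], snvs, (main, main_len), (ctrl, config.control_chrom_bp))

    # --- CpG sites
    cpgs = {
        main: _poisson_positions(rng, main_len, config.cpg_density / 1000.0),
        ctrl: _poisson_positions(rng, config.control_chrom_bp, config.cpg_density / 1000.0),
    }

    # --- DNA reads with SNV alleles and CpG methylation
    reads, meth_rows, read_parent = _simulate_reads(
        rng, design, config, coords, snvs, cpgs
    )
    paths["reads"] = outdir / "reads.tsv"
    with open(paths["reads"], "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tsnv_calls\tcpg_calls\n")
        for r in reads:
            fh.write("\t".join(r) + "\n")
    paths["methylation"] = outdir / "methylation.tsv"
    with open(paths["methylation"], "w") as fh:
        fh.write("read_id\tchrom\tpos\tmethylated\n")
        for row in meth_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    # --- SV call sets (patient truth + decoys; parents with decoy triggers)
    sv_rows, parent_sv_rows = _simulate_sv_calls(
        rng, junctions, coords, main, main_len, low_depth_start
    )
    for name, rows in (
        ("svs_patient", sv_rows),
        ("svs_father", parent_sv_rows),
        ("svs_mother", []),
    ):
        p = outdir / f"{name}.tsv"
        paths[name] = p
        with open(p, "w") as fh:
            fh.write("id\tchrom\tpos\tend\tsv_type\tsize\tsupport_reads\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

    # --- allelic RNA counts at informative SNVs
    paths["rna_counts"] = outdir / "rna_counts.tsv"
    with open(paths["rna_counts"], "w") as fh:
        fh.write("chrom\tpos\ta_reads\tb_reads\n")
        for s in snvs:
            if s["configuration"] == "none":
                continue
            total = int(rng.poisson(config.rna_depth))
            if total == 0:
                continue
            b_frac = s["b_copies"] / s["copy_total"]
            b_reads = int(rng.binomial(total, b_frac))
            fh.write(f"{s['chrom']}\t{s['pos']}\t{total - b_reads}\t{b_reads}\n")

    # --- truth JSON
    truth = {
        "config": asdict(config),
        "main_chrom": main,
        "control_chrom": ctrl,
        "blocks": truth_blocks,
        "center_block": design.center_block,
        "derivative_order": [[lbl, s] for lbl, s in design.derivative_order],
        "junctions": [
            {
                "junction_id": j.junction_id,
                "sv_id": j.sv_id,
                "adjacency": [j.from_block, j.from_sign, j.to_block, j.to_sign],
                "microhomology": j.microhomology,
                "insertion_len": len(j.insertion),
                "insertion_from": list(j.insertion_from) if j.insertion_from else None,
                "breakpoints": [
                    _breakpoint(coords, j.from_block, j.from_sign, True),
                    _breakpoint(coords, j.to_block, j.to_sign, False),
                ],
            }
            for j in junctions
        ],
        "read_parent": read_parent,
        "snvs": snvs,
        "meth": {
            "base_rate": config.base_meth_rate,
            "effect": config.meth_effect,
            "elevated_chrom": main,
        },
    }
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    out = {k: str(v) for k, v in paths.items()}
    out["truth_dict"] = truth
    return out


def _overdispersed_depth(rng, mean: float, sd: float) -> float:
    """Gamma-Poisson (negative-binomial-like) bin depth; falls back to
    Poisson when the requested variance is below the Poisson floor."""
    if mean <= 0:
        return 0.0
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        lam = rng.gamma(r, mean / r)
    else:
        lam = mean
    return float(rng.poisson(lam))


def _oriented_flank(seq, coords, label, sign, flank, left: bool) -> str:
    s = seq if isinstance(seq, str) else "".join(seq)
    start, end = coords[label]
    if left:  # sequence read into the junction from the donor side
        if sign > 0:
            return s[end - flank : end]
        return revcomp(s[start : start + flank])
    if sign > 0:
        return s[start : start + flank]
    return revcomp(s[end - flank : end])


def _flank_coords(coords, label, sign, flank, left: bool):
    start, end = coords[label]
    if left:
        if sign > 0:
            return (end - flank, end, "+")
        return (start, start + flank, "-")
    if sign > 0:
        return (start, start + flank, "+")
    return (end - flank, end, "-")


def _mh_target_positions(coords, to_block, to_sign, mh) -> list[int]:
    start, end = coords[to_block]
    if to_sign > 0:
        return list(range(start, start + mh))
    return list(range(end - mh, end))


def _poisson_positions(rng, length: int, per_bp: float) -> list[int]:
    n = int(rng.poisson(length * per_bp))
    return sorted(int(p) for p in rng.choice(length, size=min(n, length), replace=False))


def _copy_at(design, coords, pos: int) -> int:
    for b in design.blocks:
        s, e = coords[b.label]
        if s <= pos < e:
            return b.copy_state
    return 2


_CONFIGS = ("AA/BB", "AB/BB", "AA/AB")


def _simulate_snvs(rng, design, config, coords, ref_str):
    """Child-het SNVs in trio configurations, with per-site truth.

    The A allele is written as REF and B as ALT.  The maternal allele is
    carried by the one normal maternal homolog plus every derivative copy,
    so at total copy c the B-copy count is c-1 (maternal B) or 1
    (paternal B).
    """
    snvs = []
    for chrom, length in (
        (config.main_chrom, len(ref_str[config.main_chrom])),
        (config.control_chrom, len(ref_str[config.control_chrom])),
    ):
        for pos0 in _poisson_positions(rng, length, config.snv_density / 1000.0):
            ref_base = ref_str[chrom][pos0]
            alt_base = BASES[(BASES.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
            informative = rng.random() < config.informative_fraction
            cfg = _CONFIGS[int(rng.integers(0, 3))] if informative else "none"
            mat_is_b = bool(rng.random() < 0.5)
            c = _copy_at(design, coords, pos0) if chrom == config.main_chrom else 2
            b_copies = (c - 1) if mat_is_b else 1
            snvs.append(
                {
                    "chrom": chrom, "pos": pos0 + 1, "ref": ref_base,
                    "alt": alt_base, "configuration": cfg,
                    "mat_allele": "B" if mat_is_b else "A",
                    "copy_total": c, "b_copies": b_copies,
                }
            )
    return snvs


def _gt(allele_pair):
    return "/".join("0" if a == "A" else "1" for a in allele_pair)


def _write_trio_vcf(path, snvs, *chroms):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chroms:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            "\tPATIENT\tFATHER\tMOTHER\n"
        )
        for s in snvs:
            mat = s["mat_allele"]
            pat = "A" if mat == "B" else "B"
            cfg = s["configuration"]
            if cfg == "AA/BB":
                f_gt, m_gt = (pat, pat), (mat, mat)
            elif cfg == "AB/BB":
                f_gt, m_gt = ("A", "B"), (mat, mat)
            elif cfg == "AA/AB":
                f_gt, m_gt = (pat, pat), ("A", "B")
            else:  # both parents het: child het but not informative
                f_gt, m_gt = ("A", "B"), ("A", "B")
            fh.write(
                f"{s['chrom']}\t{s['pos']}\t.\t{s['ref']}\t{s['alt']}\t.\tPASS\t.\t"
                f"GT\t0/1\t{_gt(f_gt)}\t{_gt(m_gt)}\n"
            )


def _simulate_reads(rng, design, config, coords, snvs, cpgs):
    """Reads per block at copy-proportional counts, maternal:(c-1) paternal:1.

    Reads stay within their block so the parental mixture is well-defined;
    each read reports the allele of every covered SNV (error-free) and a
    methylation call at every covered CpG.
    """
    snv_by_chrom: dict[str, list] = {}
    for s in snvs:
        snv_by_chrom.setdefault(s["chrom"], []).append(s)
    main, ctrl = config.main_chrom, config.control_chrom
    per_copy = config.disomic_mean_depth / 2.0
    reads, meth_rows = [], []
    read_parent: dict[str, str] = {}
    rid = 0
    regions = [(main, b.label, *coords[b.label], b.copy_state) for b in design.blocks]
    regions.append((ctrl, "control", 0, config.control_chrom_bp, 2))
    for chrom, label, start, end, c in regions:
        length = end - start
        n_reads = int(round(c * per_copy * length / config.read_length_mean))
        elevated = chrom == main and c > 2
        for _ in range(n_reads):
            rl = max(200, int(rng.normal(config.read_length_mean,
                                         config.read_length_mean * 0.15)))
            r0 = start + int(rng.integers(0, max(1, length - 1)))
            r1 = min(r0 + rl, end)
            parent = "maternal" if rng.random() < (c - 1) / c else "paternal"
            rid += 1
            read_id = f"read{rid:06d}"
            read_parent[read_id] = parent
            calls = []
            for s in snv_by_chrom.get(chrom, ()):
                p0 = s["pos"] - 1
                if r0 <= p0 < r1:
                    hap = s["mat_allele"] if parent == "maternal" else (
                        "A" if s["mat_allele"] == "B" else "B"
                    )
                    base = s["ref"] if hap == "A" else s["alt"]
                    calls.append(f"{s['pos']}:{base}")
            rate = config.base_meth_rate
            if elevated and parent == "maternal":
                rate = min(0.98, rate + config.meth_effect)
            cpg_calls = []
            for p in cpgs.get(chrom, ()):
                if r0 <= p < r1:
                    m = int(rng.random() < rate)
                    cpg_calls.append(f"{p + 1}:{m}")
                    meth_rows.append((read_id, chrom, p + 1, m))
            reads.append(
                (
                    read_id, chrom, str(r0), str(r1),
                    ";".join(calls) or ".", ";".join(cpg_calls) or ".",
                )
            )
    return reads, meth_rows, read_parent


def _simulate_sv_calls(rng, junctions, coords, main, main_len, low_depth_start):
    rows = []
    for j in junctions:
        bp1 = _breakpoint(coords, j.from_block, j.from_sign, True)
        bp2 = _breakpoint(coords, j.to_block, j.to_sign, False)
        pos, end = sorted((bp1, bp2))
        size = max(end - pos, 150)
        sv_type = "INV" if j.from_sign != j.to_sign else "BND"
        support = int(rng.integers(6, 16))
        rows.append((j.sv_id or j.junction_id, main, pos, end, sv_type, size, support))
    # decoys: each fails exactly one filter rule
    mid = main_len // 2
    rows.append(("decoy_small", main, mid, mid + 40, "DEL", 40, 12))
    rows.append(("decoy_support", main, mid + 5000, mid + 5400, "DEL", 400, 3))
    rows.append(("decoy_parental", main, 1200, 1700, "DEL", 500, 9))
    rows.append(
        ("decoy_lowdepth", main, low_depth_start + 500, low_depth_start + 900,
         "DEL", 400, 8)
    )
    parent_rows = [("father_sv1", main, 1100, 1650, "DEL", 550, 6)]
    return rows, parent_rows


def _write_fasta(path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_records_from_tsv(path) -> dict[str, list[tuple[str, int, str]]]:
    """Parse the read TSV into triophase's read-record mapping."""
    out: dict[str, list[tuple[str, int, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            read_id, chrom, start, end, snv_calls, _ = line.rstrip("\n").split("\t")
            calls = []
            if snv_calls != ".":
                for item in snv_calls.split(";"):
                    pos, base = item.split(":")
                    calls.append((chrom, int(pos), base))
            out[read_id] = calls
    return out


def meth_records_from_tsv(path):
    """Yield (read_id, chrom, pos, methylated) from the methylation TSV."""
    with open(path) as fh:
        fh.readline()
        for line in fh:
            read_id, chrom, pos, m = line.rstrip("\n").split("\t")
            yield read_id, chrom, int(pos), int(m)


# ---------------------------------------------------------------------------
# desk-scale statistical simulators


def simulate_baf_counts(
    rng: np.random.Generator,
    n_loci: int,
    total_copies: int,
    b_copies: int,
    depth_mean: float,
):
    """Per-locus (b_count, total) pairs for loci at a fixed allelic state.

    Depth is Poisson around ``depth_mean`` (floored at 1 read) and B-read
    counts are binomial with success probability ``b_copies/total_copies``.
    """
    totals = np.maximum(1, rng.poisson(depth_mean, n_loci))
    b = rng.binomial(totals, b_copies / total_copies)
    return b, totals


def modal_baf(b_counts, totals, decimals: int = 2) -> float:
    """Location of the tallest BAF peak, rounded to ``decimals``.

    A Gaussian kernel density estimate locates the tallest peak and the
    density minima flanking it; the reported position is the mean of the
    observations inside that basin — the peak's center of mass, which for
    loci at a single allelic state is an unbiased estimate of m/N.
    Rounding per locus instead (or reporting a raw histogram argmax) is a
    coin flip whenever the allelic fraction sits on a rounding-cell edge,
    as 1/6 = 0.1667 does between the 0.16 and 0.17 cells.
    """
    from scipy.stats import gaussian_kde

    baf = np.asarray(b_counts, dtype=float) / np.asarray(totals, dtype=float)
    if np.ptp(baf) < 1e-12:
        return float(np.round(baf[0], decimals))
    grid = np.linspace(0.0, 1.0, 2001)
    # a fixed 0.03 bandwidth smooths sampling wiggles without blurring
    # peaks, which sit at multiples of 1/N (spacing >= 1/6 here)
    density = gaussian_kde(baf, bw_method=0.03 / max(1e-9, float(baf.std())))(grid)
    peak = int(density.argmax())
    lo = peak
    while lo > 0 and density[lo - 1] <= density[lo]:
        lo -= 1
    hi = peak
    while hi < len(grid) - 1 and density[hi + 1] <= density[hi]:
        hi += 1
    basin = baf[(baf >= grid[lo]) & (baf <= grid[hi])]
    center = float(basin.mean()) if basin.size else float(grid[peak])
    return float(np.round(center, decimals))


def simulate_null_cpg_counts(
    rng: np.random.Generator,
    n_sites: int,
    depth_mean: float = 58.44,
    meth_rate: float = 0.55,
    effect: float = 0.0,
    mat_frac: float = 0.5,
):
    """Per-CpG 2x2 counts with a maternal methylation-rate shift.

    ``mat_frac`` is the maternal share of reads (0.5 for a disomic locus;
    (c-1)/c in a c-copy region of a maternal derivative); ``effect`` = 0
    gives the null.
    """
    from .allelemeth import CpgSiteCounts

    totals = rng.poisson(depth_mean, n_sites)
    n_mat = rng.binomial(totals, mat_frac)
    n_pat = totals - n_mat
    mat_rate = min(0.99, meth_rate + effect)
    mat_meth = rng.binomial(n_mat, mat_rate)
    pat_meth = rng.binomial(n_pat, meth_rate)
    return [
        CpgSiteCounts("chrN", i + 1, int(mm), int(nm - mm), int(pm), int(np_ - pm))
        for i, (mm, nm, pm, np_) in enumerate(zip(mat_meth, n_mat, pat_meth, n_pat))
    ]
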