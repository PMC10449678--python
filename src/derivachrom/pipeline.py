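"""End-to-end pipeline: configuration, stage orchestration and validation.

Stages run in dependency order — copy-number segmentation and trio phasing
first, then SV filtering, junction resolution, structure reconstruction,
and the allele-specific methylation and expression analyses — and the run
emits a single structured report.  All numeric thresholds default to the
published analysis values (500 bp bins, SV size >= 100 bp and support >= 5,
parental proximity 300 bp, parental depth >= 10, Fisher alpha 0.001,
chi-square alpha 0.05, CpG coverage >= 10, 1 kb promoters, +/- 2 Mb
centromeric windows).  A stage failure marks its dependents skipped rather
than aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import (
    allelemeth,
    alleleexpr,
    cnseg,
    junctionseq,
    reconstruct as rc,
    svselect,
    triophase,
)

log = logging.getLogger("derivachrom")

PAPER_DEFAULTS = {
    "bin_size": 500,
    "sv_min_size": 100,
    "sv_min_support": 5,
    "sv_proximity": 300,
    "sv_min_parent_depth": 10,
    "fisher_alpha": 0.001,
    "chi2_alpha": 0.05,
    "cpg_min_reads": 10,
    "promoter_bp": 1000,
    "centromere_radius": 2_000_000,
}


@dataclass
class PipelineConfig:
    """Input paths, stage toggles and the analysis thresholds."""

    inputs: dict = field(default_factory=dict)  # name -> path
    outdir: str = "pipeline_out"
    stages: dict = field(
        default_factory=lambda: {
            s: True
            for s in (
                "cnseg", "phase", "svselect", "junctions",
                "reconstruct", "methylation", "expression",
            )
        }
    )
    thresholds: dict = field(default_factory=lambda: dict(PAPER_DEFAULTS))
    baseline_region: tuple | None = None  # (chrom, start, end) disomic control
    copy_states: tuple = (2, 4, 6)  # per-bin calling (disjoint intervals)
    refine_states: tuple = (2, 4, 5, 6)  # segment-level refinement incl. odd
    seed: int = 0

    def __post_init__(self):
        merged = dict(PAPER_DEFAULTS)
        merged.update(self.thresholds)
        self.thresholds = merged
        bad = [k for k, v in self.thresholds.items() if not v > 0]
        if bad:
            raise ValueError(f"thresholds must be positive: {bad}")

    REQUIRED_INPUTS = {
        "cnseg": ("depth",),
        "phase": ("vcf", "reads"),
        "svselect": ("svs_patient", "svs_father", "svs_mother",
                     "depth_father", "depth_mother"),
        "junctions": ("consensus", "junction_manifest", "reference"),
        "reconstruct": (),
        "methylation": ("methylation",),
        "expression": ("rna_counts",),
    }

    def validate(self) -> None:
        for stage, enabled in self.stages.items():
            if not enabled:
                continue
            for name in self.REQUIRED_INPUTS.get(stage, ()):
                p = self.inputs.get(name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"stage '{stage}' enabled but input '{name}' is missing"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if data.pop("paper_defaults", True) is False:
            pass  # thresholds below still merge over the defaults
        if "baseline_region" in data and data["baseline_region"] is not None:
            data["baseline_region"] = tuple(data["baseline_region"])
        for key in ("copy_states", "refine_states"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["baseline_region"] = (
            list(self.baseline_region) if self.baseline_region else None
        )
        data["copy_states"] = list(self.copy_states)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages and return (and write) the aggregate report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {"seed": config.seed, "thresholds": dict(th), "stages": {}}
    state: dict = {}

    def run_stage(name, fn, deps=()):
        if not config.stages.get(name, False):
            report["stages"][name] = {"status": "disabled"}
            return
        for dep in deps:
            if report["stages"].get(dep, {}).get("status") not in (None, "ok"):
                report["stages"][name] = {"status": "skipped",
                                          "reason": f"dependency {dep} unavailable"}
                return
        try:
            report["stages"][name] = fn() | {"status": "ok"}
        except Exception as exc:  # halt dependents, keep the run alive
            log.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}

    # ---- copy-number segmentation
    def stage_cnseg():
        bins = cnseg.read_depth_bedgraph(config.inputs["depth"])
        if config.baseline_region:
            chrom, s, e = config.baseline_region
            base_bins = [b for b in bins if b.chrom == chrom]
            mu, sigma = cnseg.estimate_baseline(base_bins, (s, e))
        else:
            mu, sigma = cnseg.estimate_baseline(bins)
        intervals = cnseg.copy_intervals(mu, sigma, config.copy_states)
        blocks_by_chrom = {}
        for chrom in sorted({b.chrom for b in bins}):
            cb = [b for b in bins if b.chrom == chrom]
            states = [cnseg.call_copy_state(b.mean_depth, intervals) for b in cb]
            segs = cnseg.segment_blocks(cb, states)
            segs = cnseg.refine_block_states(
                segs, cb, mu, sigma, config.refine_states
            )
            blocks_by_chrom[chrom] = cnseg.polish_boundaries(segs, cb, mu)
        # label across chromosomes in genomic order
        labels = cnseg.block_labels()
        blocks = []
        for chrom in blocks_by_chrom:
            for blk in blocks_by_chrom[chrom]:
                blk.label = next(labels)
                blocks.append(blk)
        state["blocks"] = blocks
        state["intervals"] = intervals
        state["bins"] = bins
        state["baseline"] = (mu, sigma)
        cnseg.write_blocks_bed(blocks, outdir / "blocks.bed")
        return {
            "baseline": {"mu": round(mu, 2), "sigma": round(sigma, 2)},
            "intervals": [
                {"k": iv.copy_state, "lo": round(iv.lo, 2), "hi": round(iv.hi, 2)}
                for iv in intervals
            ],
            "blocks": [
                {
                    "label": b.label, "chrom": b.chrom, "start": b.start,
                    "end": b.end, "copy_state": b.copy_state,
                }
                for b in blocks
            ],
        }

    run_stage("cnseg", stage_cnseg)

    # ---- trio phasing + BAF
    def stage_phase():
        from .simtrio import read_records_from_tsv

        trio = triophase.read_trio_vcf(
            config.inputs["vcf"], "PATIENT", "FATHER", "MOTHER"
        )
        snvs, skipped = triophase.select_informative_snvs(trio)
        records = read_records_from_tsv(config.inputs["reads"])
        assignments = triophase.classify_reads(records, snvs)
        state["informative_snvs"] = snvs
        state["assignments"] = {a.read_id: a.call for a in assignments}
        assignments_file = outdir / "read_assignments.tsv"
        with open(assignments_file, "w") as fh:
            fh.write("read_id\tcall\n")
            for a in assignments:
                fh.write(f"{a.read_id}\t{a.call}\n")
        # DNA BAF per informative SNV (B = ALT allele)
        counts: dict[tuple[str, int], list[int]] = {}
        snv_index = {(s.chrom, s.pos): s for s in snvs}
        for read_id, calls in records.items():
            for chrom, pos, base in calls:
                if (chrom, pos) in snv_index:
                    counts.setdefault((chrom, pos), [0, 0])
                    counts[(chrom, pos)][1] += 1
        # second pass: B counts need the ALT base per site
        import pysam

        with pysam.VariantFile(str(config.inputs["vcf"])) as vcf:
            alts = {(r.chrom, r.pos): r.alts[0] for r in vcf if r.alts}
        for read_id, calls in records.items():
            for chrom, pos, base in calls:
                key = (chrom, pos)
                if key in counts and base == alts.get(key):
                    counts[key][0] += 1
        bafs = {
            key: triophase.compute_baf(bc, tot, key[0], key[1])
            for key, (bc, tot) in sorted(counts.items())
            if tot > 0
        }
        state["baf"] = bafs
        calls_summary = {
            call: sum(1 for a in assignments if a.call == call)
            for call in ("maternal", "paternal", "unclassified", "conflicting")
        }
        return {
            "informative_snvs": len(snvs),
            "skipped_snvs": skipped,
            "reads": calls_summary,
            "baf_sites": len(bafs),
            "assignments_file": str(assignments_file),
        }

    run_stage("phase", stage_phase)

    # ---- SV filtering
    def stage_svselect():
        patient = svselect.read_sv_tsv(config.inputs["svs_patient"])
        ctx = svselect.ParentContext(
            parent_svs={
                "father": svselect.read_sv_tsv(config.inputs["svs_father"]),
                "mother": svselect.read_sv_tsv(config.inputs["svs_mother"]),
            },
            depths={
                "father": svselect.depth_track_from_bedgraph(
                    config.inputs["depth_father"]
                ),
                "mother": svselect.depth_track_from_bedgraph(
                    config.inputs["depth_mother"]
                ),
            },
        )
        kept, rejected = svselect.filter_patient_specific(
            patient, ctx,
            min_size=th["sv_min_size"], min_support=th["sv_min_support"],
            proximity=th["sv_proximity"],
            min_parent_depth=th["sv_min_parent_depth"],
        )
        state["kept_svs"] = kept
        return {
            "kept": [s.id for s in kept],
            "rejected": {s.id: reason for s, reason in rejected},
        }

    run_stage("svselect", stage_svselect)

    # ---- junction resolution + mechanisms
    def stage_junctions():
        import pandas as pd
        from pyfaidx import Fasta

        ref = Fasta(str(config.inputs["reference"]))
        cons = Fasta(str(config.inputs["consensus"]))
        manifest = pd.read_csv(config.inputs["junction_manifest"], sep="\t")
        resolutions = {}
        adjacencies = []
        blocks = state.get("blocks", [])
        # depth cannot separate adjacent same-copy blocks; SV breakpoints can
        bps = []
        for row in manifest.itertuples():
            bps.append(row.left_end if row.left_strand == "+" else row.left_start)
            bps.append(row.right_start if row.right_strand == "+" else row.right_end)
        if blocks:
            blocks = cnseg.harmonize_blocks_with_breakpoints(
                blocks, state["bins"], bps, _main_chrom(blocks),
                state["baseline"][0], state["baseline"][1],
                config.refine_states, bin_size=th["bin_size"],
            )
        state["blocks_split"] = blocks
        for row in manifest.itertuples():
            lf = str(ref[row.left_chrom][row.left_start : row.left_end])
            if row.left_strand == "-":
                lf = junctionseq.revcomp(lf)
            rf = str(ref[row.right_chrom][row.right_start : row.right_end])
            if row.right_strand == "-":
                rf = junctionseq.revcomp(rf)
            res = junctionseq.resolve_junction(
                str(cons[row.junction_id][:]), lf, rf, row.junction_id
            )
            resolutions[row.junction_id] = (res, row.sv_id)
            adj = _manifest_adjacency(row, blocks)
            if adj is not None:
                adjacencies.append(
                    rc.JunctionEdge(*adj, sv_id=str(row.sv_id))
                )
        state["junction_edges"] = adjacencies
        # group junctions into events by sv_id, classify mechanisms
        by_event: dict[str, list] = {}
        for jid, (res, sv_id) in resolutions.items():
            by_event.setdefault(str(sv_id), []).append(res)
        mechanisms = {
            ev: junctionseq.classify_mechanism(rs, ev).mechanism
            for ev, rs in sorted(by_event.items())
        }
        mech_counts: dict[str, int] = {}
        for m in mechanisms.values():
            mech_counts[m] = mech_counts.get(m, 0) + 1
        state["resolutions"] = resolutions
        return {
            "junctions": {
                jid: {
                    "microhomology": res.microhomology_bp,
                    "insertion": res.insertion_bp,
                    "resolved": res.resolved,
                }
                for jid, (res, _) in sorted(resolutions.items())
            },
            "mechanisms": mechanisms,
            "mechanism_counts": mech_counts,
        }

    run_stage("junctions", stage_junctions, deps=("cnseg",))

    # ---- structure reconstruction
    def stage_reconstruct():
        source = state.get("blocks_split") or state["blocks"]
        main_chrom = _main_chrom(source)
        blocks = [b for b in source
                  if b.chrom == main_chrom and isinstance(b.copy_state, int)]
        odd = [b for b in blocks if b.copy_state % 2 == 1]
        if len(odd) != 1:
            raise ValueError(f"expected one odd-copy center block, found {len(odd)}")
        graph = rc.build_graph(blocks, state.get("junction_edges", []))
        best, models, truncated = rc.reconstruct_structure(graph, odd[0].label)
        state["structure"] = best
        state["block_objects"] = blocks
        # SV breakpoints against the final (junction-harmonized) boundaries
        sv_boundary_max = None
        if state.get("kept_svs"):
            table = svselect.annotate_boundary_distance(state["kept_svs"], blocks)
            table.to_csv(outdir / "sv_boundaries.tsv", sep="\t", index=False)
            sv_boundary_max = int(table["distance"].max()) if len(table) else None
        return {
            "sv_boundary_max_distance": sv_boundary_max,
            "center_block": odd[0].label,
            "n_models": len(models),
            "truncated": truncated,
            "structure": rc.structure_text(best) if best else None,
            "event_score": best.event_score if best else None,
            "blocks": [
                {
                    "label": b.label, "chrom": b.chrom, "start": b.start,
                    "end": b.end, "copy_state": b.copy_state,
                }
                for b in blocks
            ],
        }

    run_stage("reconstruct", stage_reconstruct, deps=("cnseg", "junctions"))

    # ---- allele-specific methylation
    def stage_methylation():
        from .simtrio import meth_records_from_tsv

        read_parent = state.get("assignments", {})
        sites = allelemeth.site_counts_from_reads(
            meth_records_from_tsv(config.inputs["methylation"]), read_parent
        )
        calls, excluded = allelemeth.test_sites(
            sites, alpha=th["fisher_alpha"], min_reads=th["cpg_min_reads"]
        )
        per_chrom = allelemeth.compare_chromosomes(calls, alpha=th["chi2_alpha"])
        per_chrom.to_csv(outdir / "methylation_by_chrom.tsv", sep="\t", index=False)
        return {
            "sites_tested": len(calls),
            "excluded": excluded,
            "hypermethylated": {
                "maternal": sum(1 for c in calls if c.direction == "maternal"),
                "paternal": sum(1 for c in calls if c.direction == "paternal"),
            },
            "by_chromosome": per_chrom.to_dict(orient="records"),
        }

    run_stage("methylation", stage_methylation, deps=("phase",))

    # ---- allele-specific expression
    def stage_expression():
        import pandas as pd

        df = pd.read_csv(config.inputs["rna_counts"], sep="\t")
        blocks = state.get("blocks", [])
        tests = []
        for r in df.itertuples():
            cls = _region_class(str(r.chrom), int(r.pos), blocks)
            t = alleleexpr.test_allelic_balance(
                int(r.b_reads), int(r.a_reads), str(r.chrom), int(r.pos), cls,
                alpha=th["chi2_alpha"],
            )
            if t is not None:
                tests.append(t)
        summary = alleleexpr.summarize_balance(
            tests, class_pairs=(("aneusomic", "disomic"),)
        )
        state["balance_tests"] = tests
        return summary

    run_stage("expression", stage_expression, deps=("phase",))

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _main_chrom(blocks) -> str:
    """The chromosome carrying aneusomic blocks (max copy state)."""
    best, best_c = None, -1
    for b in blocks:
        if isinstance(b.copy_state, int) and b.copy_state > best_c:
            best, best_c = b.chrom, b.copy_state
    return best


def _region_class(chrom, pos, blocks) -> str:
    for b in blocks:
        if b.chrom == chrom and b.start <= pos - 1 < b.end:
            if isinstance(b.copy_state, int) and b.copy_state > 2:
                return "aneusomic"
            return "disomic"
    return "disomic"


def _manifest_adjacency(row, blocks):
    """Map a junction's flank coordinates to an oriented block adjacency.

    The left flank ends at the exit breakpoint of the donor block, the
    right flank starts at the entry breakpoint of the acceptor block;
    strands give the traversal signs.
    """
    if not blocks:
        return None

    def find_block(chrom, coord, prefer_end):
        best, best_d = None, None
        for b in blocks:
            if b.chrom != chrom:
                continue
            d = abs((b.end if prefer_end else b.start) - coord)
            if best_d is None or d < best_d:
                best, best_d = b, d
        return best, best_d

    tol = 2 * 500
    if row.left_strand == "+":
        lb, ld = find_block(row.left_chrom, row.left_end, True)
        ls = 1
    else:
        lb, ld = find_block(row.left_chrom, row.left_start, False)
        ls = -1
    if row.right_strand == "+":
        rb, rd = find_block(row.right_chrom, row.right_start, False)
        rs = 1
    else:
        rb, rd = find_block(row.right_chrom, row.right_end, True)
        rs = -1
    if lb is None or rb is None or ld > tol or rd > tol:
        return None
    return (lb.label, ls, rb.label, rs)


def validate_report(report: dict, truth: Mapping) -> dict:
    """Score a pipeline report against a simulation truth record."""
    card: dict = {}
    bin_size = report.get("thresholds", {}).get("bin_size", 500)
    # block boundaries and states (post-split blocks when available: depth
    # alone cannot see a boundary between same-copy neighbours)
    cn = report["stages"].get("reconstruct", {})
    if "blocks" not in cn:
        cn = report["stages"].get("cnseg", {})
    if "blocks" in cn:
        main = truth["main_chrom"]
        # only boundaries a method can see: a copy-state change or an SV
        # junction breakpoint (same-copy reference-adjacent blocks are
        # indistinguishable by construction)
        jct_bps = {bp for j in truth["junctions"] for bp in j["breakpoints"]}
        tb = truth["blocks"]
        true_bounds = {tb[0]["start"], tb[-1]["end"]} | (
            jct_bps & {b["start"] for b in tb} | jct_bps & {b["end"] for b in tb}
        )
        for b1, b2 in zip(tb, tb[1:]):
            if b1["copy_state"] != b2["copy_state"]:
                true_bounds.add(b1["end"])
        true_bounds = sorted(true_bounds)
        called = [b for b in cn["blocks"] if b["chrom"] == main]
        called_bounds = sorted({b["start"] for b in called} | {b["end"] for b in called})
        errs = [
            min(abs(tb - cb) for cb in called_bounds) for tb in true_bounds
        ]
        card["boundary_max_error_bins"] = max(errs) / bin_size
        # per-true-block modal called state
        correct = 0
        for tb in truth["blocks"]:
            mid = (tb["start"] + tb["end"]) // 2
            hit = [
                b for b in called if b["start"] <= mid < b["end"]
            ]
            if hit and hit[0]["copy_state"] == tb["copy_state"]:
                correct += 1
        card["block_state_accuracy"] = correct / len(truth["blocks"])
    ph = report["stages"].get("phase", {})
    if ph.get("status") == "ok":
        card["phasing_summary"] = ph["reads"]
        f = ph.get("assignments_file")
        if f and Path(f).exists():
            correct = classified = conflicting = 0
            with open(f) as fh:
                fh.readline()
                for line in fh:
                    read_id, call = line.split()
                    if call in ("maternal", "paternal"):
                        classified += 1
                        correct += call == truth["read_parent"].get(read_id)
                    elif call == "conflicting":
                        conflicting += 1
            card["phasing_accuracy"] = correct / classified if classified else None
            card["conflicting_reads"] = conflicting
    jc = report["stages"].get("junctions", {})
    if jc.get("status") == "ok":
        true_sig = {
            j["junction_id"]: (j["microhomology"], j["insertion_len"])
            for j in truth["junctions"]
        }
        exact = sum(
            1
            for jid, res in jc["junctions"].items()
            if jid in true_sig
            and (res["microhomology"], res["insertion"]) == true_sig[jid]
        )
        card["junction_exact"] = exact / max(1, len(true_sig))
    rcs = report["stages"].get("reconstruct", {})
    if rcs.get("status") == "ok" and rcs.get("structure"):
        card["structure_match"] = _structure_matches(
            rcs["structure"], truth["derivative_order"], truth, report
        )
    return card


def _merge_interval_chain(chain):
    """Canonicalize an oriented-interval sequence: fuse genomically
    contiguous same-orientation neighbours (a block split that no junction
    or copy change separates is not a real structural boundary)."""
    out = []
    for s, e, sign in chain:
        if out:
            ps, pe, psign = out[-1]
            if sign == psign == 1 and pe == s:
                out[-1] = (ps, e, 1)
                continue
            if sign == psign == -1 and ps == e:
                out[-1] = (s, pe, -1)
                continue
        out.append((s, e, sign))
    return out


def _structure_matches(structure_text, true_order, truth, report) -> bool:
    """Compare reconstructed structure to truth up to orientation flip.

    Both structures are rendered as chains of oriented genomic intervals
    and canonically merged first, because adjacent same-copy blocks with no
    junction between them are indistinguishable (and interchangeable)
    descriptions of the same DNA.
    """
    source = report["stages"].get("reconstruct", {})
    if "blocks" not in source:
        source = report["stages"].get("cnseg", {})
    main = truth["main_chrom"]
    called = {
        b["label"]: (b["start"], b["end"])
        for b in source.get("blocks", [])
        if b["chrom"] == main
    }
    chain = []
    for token in structure_text.split():
        lbl, sig = token[:-3], token[-3:]
        if lbl not in called:
            return False
        s, e = called[lbl]
        chain.append((s, e, 1 if sig == "(+)" else -1))
    tspan = {b["label"]: (b["start"], b["end"]) for b in truth["blocks"]}
    tchain = [(*tspan[lbl], sign) for lbl, sign in true_order]
    got = _merge_interval_chain(chain)
    want = _merge_interval_chain(tchain)
    flipped = [(s, e, -sign) for s, e, sign in reversed(want)]
    tol = 2 * report.get("thresholds", {}).get("bin_size", 500)

    def close(c1, c2):
        return len(c1) == len(c2) and all(
            s1 == s2 and abs(a1 - a2) <= tol and abs(b1 - b2) <= tol
            for (a1, b1, s1), (a2, b2, s2) in zip(c1, c2)
        )

    return close(got, want) or close(got, flipped)
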