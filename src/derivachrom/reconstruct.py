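"""Parsimony reconstruction of the derivative chromosome's block structure.

Copy-number blocks and resolved SV junctions define a graph on oriented
block ends: reference edges join genomically consecutive blocks, junction
edges join the block ends fused by each SV.  The derivative chromosome is a
walk in this graph that uses each block according to its derivative
multiplicity (total copies - 2).  Because the chromosome is a dicentric
palindrome, the full structure is ``arm + center + mirror(arm)`` where the
center is the unique odd-copy block and ``mirror`` reverses order and flips
orientations.  Candidate arms are enumerated by depth-first walk, and each
candidate is scored by the minimal number of structural events — insertion
of a copied contiguous segment (either orientation) or inversion of a
contiguous segment — needed to derive it from the reference block order
(breadth-first search over operation applications).  Deletions are excluded:
derivative formation by breakage-fusion-bridge cycles duplicates content.

Oriented blocks are ``(label, sign)`` pairs with sign +1/-1.  A block
traversed with sign +1 is entered at its genomic left end and exited at its
right end; sign -1 reverses this.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

Oriented = tuple[str, int]  # (block label, +1/-1)
End = tuple[str, str]  # (block label, "L"/"R")


def flip(seq: Sequence[Oriented]) -> tuple[Oriented, ...]:
    """Whole-sequence orientation flip: reverse order, negate signs."""
    return tuple((lbl, -s) for lbl, s in reversed(seq))


mirror = flip  # the mirrored arm of a palindrome is the flipped arm


def exit_end(block: str, sign: int) -> End:
    return (block, "R" if sign > 0 else "L")


def entry_end(block: str, sign: int) -> End:
    return (block, "L" if sign > 0 else "R")


def adjacency_edge(a: Oriented, b: Oriented) -> tuple[End, End]:
    """Canonical edge for the oriented adjacency a > b."""
    e1, e2 = exit_end(*a), entry_end(*b)
    return tuple(sorted((e1, e2)))  # type: ignore[return-value]


@dataclass(frozen=True)
class JunctionEdge:
    """An SV-supported connection between two oriented block ends.

    Declared as the adjacency ``(from_block, from_sign) > (to_block,
    to_sign)``; the orientation-reversed twin adjacency maps to the same
    undirected end pair, so each physical junction is a single edge.
    """

    from_block: str
    from_sign: int
    to_block: str
    to_sign: int
    sv_id: str = ""

    @property
    def edge(self) -> tuple[End, End]:
        return adjacency_edge(
            (self.from_block, self.from_sign), (self.to_block, self.to_sign)
        )


@dataclass
class BlockGraph:
    order: list[str]  # block labels in genomic order
    multiplicities: dict[str, int]  # derivative multiplicity per block
    reference_edges: set[tuple[End, End]]
    junction_edges: dict[tuple[End, End], list[str]]  # edge -> sv ids
    rejected_junctions: list[JunctionEdge] = field(default_factory=list)

    def has_edge(self, edge: tuple[End, End]) -> bool:
        return edge in self.reference_edges or edge in self.junction_edges

    def edges_from(self, end: End) -> list[tuple[End, bool]]:
        """(other end, is_reference) for every edge incident to ``end``,
        reference edges first, then by block label."""
        out = []
        for edge in self.reference_edges | set(self.junction_edges):
            a, b = edge
            if a == end:
                out.append((b, edge in self.reference_edges))
            if b == end and a != b:
                out.append((a, edge in self.reference_edges))
            if a == end and b == end:  # foldback
                out.append((a, edge in self.reference_edges))
        out.sort(key=lambda t: (not t[1], t[0]))
        return out


@dataclass
class CandidatePath:
    sequence: tuple[Oriented, ...]
    event_score: int | None = None
    decomposition: tuple[str, ...] = ()


@dataclass
class StructureModel:
    sequence: tuple[Oriented, ...]
    center_block: str
    arm: tuple[Oriented, ...]
    event_score: int | None = None
    palindromic: bool = True


def build_graph(
    blocks: Sequence,
    junctions: Iterable[JunctionEdge],
    boundary_tolerance: int | None = None,
) -> BlockGraph:
    """Assemble the oriented block graph.

    ``blocks`` are cnseg ``CopyBlock`` objects (or ``(label, multiplicity)``
    pairs) in genomic order.  Junctions whose endpoints name unknown blocks
    are rejected with a record rather than raising.
    """
    order: list[str] = []
    mult: dict[str, int] = {}
    for b in blocks:
        if hasattr(b, "label"):
            order.append(b.label)
            m = b.derivative_multiplicity
            mult[b.label] = m if m is not None else 0
        else:
            lbl, m = b
            order.append(lbl)
            mult[lbl] = m
    ref_edges = {
        adjacency_edge((order[i], 1), (order[i + 1], 1)) for i in range(len(order) - 1)
    }
    jct: dict[tuple[End, End], list[str]] = {}
    rejected = []
    for j in junctions:
        if j.from_block not in mult or j.to_block not in mult:
            rejected.append(j)
            continue
        edge = j.edge
        if edge in ref_edges:
            continue  # reference adjacency restated by an SV call
        jct.setdefault(edge, []).append(j.sv_id)
    return BlockGraph(order, mult, ref_edges, jct, rejected)


def _walk_successors(graph: BlockGraph, node: Oriented) -> list[Oriented]:
    succ = []
    for (blk, end), _ in graph.edges_from(exit_end(*node)):
        succ.append((blk, 1 if end == "L" else -1))
    return succ


def enumerate_paths(
    graph: BlockGraph,
    anchor_block: str,
    max_paths: int = 10_000,
    usage: Mapping[str, int] | None = None,
    require_full: bool = False,
    end_adjacent_to: str | None = None,
) -> tuple[list[CandidatePath], bool]:
    """Depth-first enumeration of walks from the anchor respecting per-block
    usage limits.

    ``usage`` caps how many times each block may appear (defaults to the
    graph multiplicities, with at least one use for the anchor).  Maximal
    walks (no extensible edge left) are emitted; with ``require_full`` only
    walks consuming the full usage budget qualify, and with
    ``end_adjacent_to`` only walks whose final oriented block connects to
    that block by a graph edge.  Walks are deduplicated up to whole-path
    orientation flip.  Returns (paths, truncated_flag).
    """
    limits = dict(usage) if usage is not None else dict(graph.multiplicities)
    limits.setdefault(anchor_block, max(1, limits.get(anchor_block, 1)))
    if limits.get(anchor_block, 0) < 1:
        limits[anchor_block] = 1
    seen: set[tuple[Oriented, ...]] = set()
    paths: list[CandidatePath] = []
    truncated = False

    def ends_ok(seq: tuple[Oriented, ...]) -> bool:
        if end_adjacent_to is None:
            return True
        last = seq[-1]
        for sign in (1, -1):
            if graph.has_edge(adjacency_edge(last, (end_adjacent_to, sign))):
                return True
        return False

    def emit(seq: tuple[Oriented, ...]) -> None:
        nonlocal truncated
        if require_full and any(
            sum(1 for lbl, _ in seq if lbl == b) != limits.get(b, 0)
            for b in limits
        ):
            return
        if not ends_ok(seq):
            return
        # arms for symmetric assembly are anchored, so their direction is
        # meaningful; only free walks are deduplicated up to a whole flip
        canon = seq if require_full else min(seq, flip(seq))
        if canon in seen:
            return
        seen.add(canon)
        if len(paths) >= max_paths:
            truncated = True
            return
        paths.append(CandidatePath(seq))

    counts = {anchor_block: 1}

    def dfs(seq: list[Oriented]) -> None:
        if truncated:
            return
        extended = False
        for nxt in _walk_successors(graph, seq[-1]):
            lbl = nxt[0]
            if counts.get(lbl, 0) >= limits.get(lbl, 0):
                continue
            counts[lbl] = counts.get(lbl, 0) + 1
            seq.append(nxt)
            extended = True
            dfs(seq)
            seq.pop()
            counts[lbl] -= 1
        if require_full or not extended:
            emit(tuple(seq))
        elif not require_full:
            pass

    if anchor_block not in graph.multiplicities:
        return [], False
    dfs([(anchor_block, 1)])
    return paths, truncated


def _insertions(state: tuple[Oriented, ...], slack: int, budget: Mapping[str, int]):
    n = len(state)
    for i in range(n):
        for j in range(i + 1, min(n, i + slack) + 1):
            seg = state[i:j]
            over = False
            cnt: dict[str, int] = {}
            for lbl, _ in seg:
                cnt[lbl] = cnt.get(lbl, 0) + 1
                if cnt[lbl] > budget.get(lbl, 0):
                    over = True
                    break
            if over:
                continue
            for piece in (seg, flip(seg)):
                for k in range(n + 1):
                    yield state[:k] + piece + state[k:], f"insert{list(piece)}@{k}"


def _inversions(state: tuple[Oriented, ...]):
    n = len(state)
    for i in range(n):
        for j in range(i + 1, n + 1):
            yield state[:i] + flip(state[i:j]) + state[j:], f"invert[{i}:{j}]"


def score_events(
    candidate: Sequence[Oriented],
    reference_order: Sequence[Oriented],
    max_depth: int = 4,
    max_nodes: int = 2_000_000,
) -> tuple[int, tuple[str, ...]]:
    """Minimal event count transforming the reference order into the
    candidate, by BFS over {copy-insert segment, invert segment}.

    Search states are pruned to sequences no longer than the candidate whose
    per-block usage never exceeds the candidate's.  If no transformation is
    found within ``max_depth`` events (or the node budget), returns
    ``max_depth + 1`` with an empty decomposition (flagged-unreachable
    convention).
    """
    target = tuple(candidate)
    start = tuple(reference_order)
    if start == target:
        return 0, ()
    tcount: dict[str, int] = {}
    for lbl, _ in target:
        tcount[lbl] = tcount.get(lbl, 0) + 1
    scount: dict[str, int] = {}
    for lbl, _ in start:
        scount[lbl] = scount.get(lbl, 0) + 1
    if any(scount.get(b, 0) > tcount.get(b, 0) for b in scount):
        return max_depth + 1, ()  # would need a deletion
    frontier = {start: ()}
    visited = {start}
    nodes = 0
    for depth in range(1, max_depth + 1):
        nxt: dict[tuple[Oriented, ...], tuple[str, ...]] = {}
        for state, ops in frontier.items():
            slack = len(target) - len(state)
            moves = list(_inversions(state))
            if slack > 0:
                moves += list(_insertions(state, slack, _remaining(state, tcount)))
            for new, op in moves:
                if len(new) > len(target) or new in visited:
                    continue
                nodes += 1
                if nodes > max_nodes:
                    return max_depth + 1, ()
                if new == target:
                    return depth, ops + (op,)
                visited.add(new)
                nxt[new] = ops + (op,)
        frontier = nxt
        if not frontier:
            break
    return max_depth + 1, ()


def _remaining(state: Sequence[Oriented], target_counts: Mapping[str, int]):
    used: dict[str, int] = {}
    for lbl, _ in state:
        used[lbl] = used.get(lbl, 0) + 1
    return {b: target_counts.get(b, 0) - used.get(b, 0) for b in target_counts}


def arm_usage(graph: BlockGraph, center_block: str) -> dict[str, int]:
    """Per-arm block usage implied by derivative multiplicities.

    Even-multiplicity blocks split equally between the two mirrored arms;
    the center block consumes one copy at the pivot and splits the rest.
    """
    usage = {}
    for blk, m in graph.multiplicities.items():
        if blk == center_block:
            if m % 2 != 1:
                raise ValueError(f"center block {blk} has even multiplicity {m}")
            usage[blk] = (m - 1) // 2
        else:
            if m % 2 != 0:
                raise ValueError(f"non-center block {blk} has odd multiplicity {m}")
            usage[blk] = m // 2
    return usage


def reference_arm(graph: BlockGraph, usage: Mapping[str, int]) -> tuple[Oriented, ...]:
    """Genomic-order baseline for event scoring: each block used in the arm,
    once, forward, in reference order."""
    return tuple((b, 1) for b in graph.order if usage.get(b, 0) > 0)


def assemble_symmetric(
    best_arm_candidates: Sequence[CandidatePath],
    center_block: str,
    graph: BlockGraph,
) -> list[StructureModel]:
    """Fold arm candidates into full palindromic structures.

    A valid model is ``arm + center + mirror(arm)`` where both adjacencies at
    the pivot (arm-end > center and center > flipped arm-end) are graph
    edges and per-block usage equals the derivative multiplicity.  Returns
    the valid models (validated; possibly empty).
    """
    models = []
    for cand in best_arm_candidates:
        arm = cand.sequence
        if not arm:
            continue
        last = arm[-1]
        for c_sign in (1, -1):
            center = (center_block, c_sign)
            e1 = adjacency_edge(last, center)
            e2 = adjacency_edge(center, (last[0], -last[1]))
            if not (graph.has_edge(e1) and graph.has_edge(e2)):
                continue
            seq = arm + (center,) + mirror(arm)
            model = StructureModel(seq, center_block, arm, cand.event_score)
            ok, _ = validate_model(model, graph)
            if ok:
                models.append(model)
                break
    return models


def validate_model(model: StructureModel, graph: BlockGraph) -> tuple[bool, list[str]]:
    """Check multiplicity accounting, palindromy and edge support."""
    problems = []
    used: dict[str, int] = {}
    for lbl, _ in model.sequence:
        used[lbl] = used.get(lbl, 0) + 1
    for blk, m in graph.multiplicities.items():
        if used.get(blk, 0) != m:
            problems.append(f"block {blk}: used {used.get(blk, 0)}, multiplicity {m}")
    for lbl in used:
        if lbl not in graph.multiplicities:
            problems.append(f"unknown block {lbl}")
    n = len(model.arm)
    expect = model.arm + ((model.center_block, model.sequence[n][1]),) + mirror(model.arm)
    if model.sequence != expect:
        problems.append("sequence is not arm + center + mirror(arm)")
    for a, b in zip(model.sequence, model.sequence[1:]):
        if not graph.has_edge(adjacency_edge(a, b)):
            problems.append(f"adjacency {a} > {b} unsupported by any edge")
    return (not problems), problems


def reconstruct_structure(
    graph: BlockGraph,
    center_block: str,
    anchor_block: str | None = None,
    max_paths: int = 10_000,
    max_depth: int = 4,
) -> tuple[StructureModel | None, list[StructureModel], bool]:
    """End-to-end reconstruction: enumerate arms, score, assemble, rank.

    Every SV junction is physical evidence from the derivative chromosome,
    so models are ranked first by how many junction edges they leave unused
    (a full structure should use all of them), then by event-parsimony
    score.  Returns (best model or None, all valid models ranked,
    truncation flag); ties on the ranking key keep a deterministic
    sequence-lexicographic order, the first reported as best.
    """
    usage = arm_usage(graph, center_block)
    anchor = anchor_block or next(
        (b for b in graph.order if usage.get(b, 0) > 0), None
    )
    if anchor is None:
        return None, [], False
    arms, truncated = enumerate_paths(
        graph,
        anchor,
        max_paths=max_paths,
        usage=usage,
        require_full=True,
        end_adjacent_to=center_block,
    )
    ref = reference_arm(graph, usage)
    for cand in arms:
        cand.event_score, cand.decomposition = score_events(
            cand.sequence, ref, max_depth=max_depth
        )
    models = assemble_symmetric(arms, center_block, graph)
    models.sort(key=lambda m: model_rank_key(m, graph))
    return (models[0] if models else None), models, truncated


def unused_junctions(model: StructureModel, graph: BlockGraph) -> int:
    """Junction edges of the graph not traversed by the model."""
    used = {
        adjacency_edge(a, b)
        for a, b in zip(model.sequence, model.sequence[1:])
    }
    return sum(1 for e in graph.junction_edges if e not in used)


def model_rank_key(model: StructureModel, graph: BlockGraph):
    return (
        unused_junctions(model, graph),
        model.event_score if model.event_score is not None else 99,
        model.sequence,
    )


def structure_text(model: StructureModel) -> str:
    return " ".join(
        f"{lbl}(+)" if s > 0 else f"{lbl}(-)" for lbl, s in model.sequence
    )
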