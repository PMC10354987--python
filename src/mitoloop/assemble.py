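"""Desk-scale overlap-layout-consensus assembly of recruited reads.

Long accurate reads at high coverage over a ~16-150 kb circular genome do
not need a string-graph assembler: all suffix-prefix overlaps are found by
seed-and-extend, a greedy best-overlap-first layout is built (closing into
a cycle when the extension returns to its starting read), and a per-column
majority vote over the laid-out reads polishes the spliced backbone.

Reads that disagree with the consensus they were laid into — identity below
``min_read_identity`` or a single indel of ``min_structural_indel`` bp or
more — are deferred to a second assembly round. This is what turns a
heteroplasmic read pool into two candidate contigs, one per haplotype.

Cyclic layouts keep their terminal redundancy (the closing overlap is left
duplicated at the ends) so the circularization stage can detect and trim it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .align import align_infix, align_prefix, diagonal_clusters, parse_cigar
from .config import PipelineConfig
from .records import SequenceRecord, revcomp


@dataclass
class Overlap:
    """A pairwise overlap between read ``a_id`` (plus strand) and ``b_id``.

    ``orientation`` is "forward" when b overlaps as stored and "reverse" when
    its reverse complement does. ``a_hang`` is the offset of oriented b
    relative to a's start: positive means a's suffix meets b's prefix;
    negative means oriented b's suffix meets a's prefix (|a_hang| bp of b
    precede the overlap). ``contained_id`` names the read fully covered by
    the other, if any.
    """

    a_id: str
    b_id: str
    a_hang: int
    overlap_len: int
    orientation: str
    identity: float
    contained_id: str | None = None

    @property
    def is_containment(self) -> bool:
        return self.contained_id is not None


@dataclass
class Layout:
    """An ordered, oriented read path; cyclic when extension closed a loop."""

    nodes: list[tuple[str, str]]            # (read_id, orientation)
    junction_overlaps: list[int]            # oriented-prefix bp spliced out
    is_cyclic: bool = False
    closing_overlap: int = 0


@dataclass
class DraftContig:
    id: str
    bases: str
    supporting_read_ids: list[str] = field(default_factory=list)
    layout_is_cyclic: bool = False


def _oriented(read: SequenceRecord, orient: str) -> str:
    return read.bases if orient == "+" else revcomp(read.bases)


def compute_overlaps(reads: list[SequenceRecord], min_overlap: int,
                     min_identity: float) -> list[Overlap]:
    """All dovetail and containment overlaps >= min_overlap at >= min_identity.

    Seeds shared k-mers between each read and every other read (both
    orientations), clusters them by diagonal, then verifies the implied
    suffix-prefix alignment with edlib. Containments (one read inside the
    other) are flagged rather than used for layout extension.
    """
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids")
    by_id = {r.id: r for r in reads}
    n = len(reads)
    if n < 2:
        return []
    min_len = min(len(r) for r in reads)
    k = min(15, max(4, min_overlap // 3, min(12, min_len // 3)))
    dense = min_len < 2000 or min_overlap < 200
    s_index = s_query = 1 if dense else 4

    # global forward k-mer index over all reads
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ri, r in enumerate(reads):
        seq = r.bases
        for p in range(0, len(seq) - k + 1, s_index):
            index[seq[p:p + k]].append((ri, p))

    # pair+orientation -> seed hits as (oriented_b_pos, a_pos), so the
    # cluster diagonal equals the hang of oriented b relative to a
    pair_hits: dict[tuple[int, int, str], list[tuple[int, int]]] = defaultdict(list)
    for ai, a in enumerate(reads):
        fwd, rev = a.bases, revcomp(a.bases)
        la = len(fwd)
        for p in range(0, la - k + 1, s_query):
            for bi, q in index.get(fwd[p:p + k], ()):
                if bi > ai:
                    pair_hits[(ai, bi, "forward")].append((q, p))
            for bi, q in index.get(rev[p:p + k], ()):
                # rc(a)[p:p+k] == b[q:q+k]  <=>  a vs rc(b) match at
                # a_pos = la - p - k, rc_b_pos = len(b) - q - k
                if bi > ai:
                    lb = len(reads[bi])
                    pair_hits[(ai, bi, "reverse")].append(
                        (lb - q - k, la - p - k))

    overlaps: list[Overlap] = []
    for (ai, bi, orient) in sorted(pair_hits):
        hits = pair_hits[(ai, bi, orient)]
        a, b = reads[ai], reads[bi]
        bseq = b.bases if orient == "forward" else revcomp(b.bases)
        la, lb = len(a), len(bseq)
        for diag, cl_hits in diagonal_clusters(hits)[:2]:
            if len(cl_hits) < 2:
                continue
            ov = _verify_overlap(a, b, bseq, diag, orient, min_overlap,
                                 min_identity)
            if ov is not None:
                overlaps.append(ov)
                break
    return overlaps


def _verify_overlap(a: SequenceRecord, b: SequenceRecord, bseq: str,
                    hang: int, orient: str, min_overlap: int,
                    min_identity: float) -> Overlap | None:
    """Interpret a seed diagonal as containment or dovetail and verify it.

    Near-flush placements (within a small, length-scaled slop) are tried as
    containment first, then as dovetail.
    """
    la, lb = len(a), len(bseq)
    pad = 60
    slop = max(2, min(30, min(la, lb) // 100))

    def _containment_b():
        w0 = max(0, hang - pad)
        aln = align_infix(bseq, a.bases[w0: hang + lb + pad])
        if aln and aln.identity >= min_identity and lb >= min_overlap:
            contained = b.id if lb < la or b.id > a.id else a.id
            return Overlap(a.id, b.id, hang, lb, orient,
                           round(aln.identity, 6), contained_id=contained)
        return None

    def _containment_a():
        pos = -hang
        w0 = max(0, pos - pad)
        aln = align_infix(a.bases, bseq[w0: pos + la + pad])
        if aln and aln.identity >= min_identity and la >= min_overlap:
            return Overlap(a.id, b.id, hang, la, orient,
                           round(aln.identity, 6), contained_id=a.id)
        return None

    def _dovetail(query: str, target: str):
        if len(query) < min_overlap:
            return None
        aln = align_prefix(query, target)
        if (aln and aln.identity >= min_identity
                and aln.stats.target_consumed >= min_overlap):
            return Overlap(a.id, b.id, hang, aln.stats.target_consumed,
                           orient, round(aln.identity, 6))
        return None

    if hang >= 0:
        if hang + lb <= la + slop and lb <= la:
            ov = _containment_b()
            if ov is not None:
                return ov
        if hang + lb >= la - slop and hang > 0:
            return _dovetail(a.bases[hang:], bseq)
        return None
    # hang < 0: oriented b starts first
    if -hang + la <= lb + slop and la <= lb:
        ov = _containment_a()
        if ov is not None:
            return ov
    if -hang + la >= lb - slop:
        return _dovetail(bseq[-hang:], a.bases)
    return None


def _directed_edges(overlaps: list[Overlap]):
    """Expand each dovetail into its two mirror-image oriented edges.

    An edge (u, uo) -> (v, vo, splice) means: read v in orientation vo
    extends the path after read u in orientation uo, with ``splice`` bp of
    oriented v's prefix already covered by the overlap.
    """
    edges = []
    for ov in overlaps:
        if ov.is_containment:
            continue
        l, ident = ov.overlap_len, ov.identity
        if ov.orientation == "forward":
            if ov.a_hang > 0:
                pair = ((ov.a_id, "+"), (ov.b_id, "+"))
            else:
                pair = ((ov.b_id, "+"), (ov.a_id, "+"))
            mirror = ((pair[1][0], "-"), (pair[0][0], "-"))
        else:
            if ov.a_hang > 0:
                pair = ((ov.a_id, "+"), (ov.b_id, "-"))
                mirror = ((ov.b_id, "+"), (ov.a_id, "-"))
            else:
                pair = ((ov.b_id, "-"), (ov.a_id, "+"))
                mirror = ((ov.a_id, "-"), (ov.b_id, "+"))
        for (u, v) in (pair, mirror):
            edges.append((l, ident, u, v))
    # longer overlap first, then higher identity, then lexicographic ids
    edges.sort(key=lambda e: (-e[0], -e[1], e[2][0], e[3][0], e[2][1], e[3][1]))
    return edges


def greedy_layout(overlaps: list[Overlap], reads: list[SequenceRecord]
                  ) -> list[Layout]:
    """Best-overlap-first path extension over the dovetail graph.

    Contained reads never extend a path (they are folded back in at
    consensus time). When the highest-scoring usable edge connects the tail
    of a path to its own head, the path closes into a cycle.
    """
    contained = {ov.contained_id for ov in overlaps if ov.is_containment}
    edges = _directed_edges(overlaps)

    orient: dict[str, str] = {}
    succ: dict[str, tuple[str, int]] = {}
    pred: dict[str, str] = {}
    path_of: dict[str, int] = {}
    paths: dict[int, dict] = {}
    next_pid = 0

    def new_path(rid, o):
        nonlocal next_pid
        orient[rid] = o
        path_of[rid] = next_pid
        paths[next_pid] = {"head": rid, "tail": rid, "cyclic": False,
                           "closing": 0}
        next_pid += 1

    for l, ident, (u, uo), (v, vo) in edges:
        if u in contained or v in contained:
            continue
        if u in orient and (orient[u] != uo or u in succ):
            continue
        if v in orient and (orient[v] != vo or v in pred):
            continue
        if u not in orient:
            new_path(u, uo)
        if v not in orient:
            new_path(v, vo)
        pu, pv = path_of[u], path_of[v]
        if paths[pu]["cyclic"] or paths[pv]["cyclic"]:
            continue
        if pu == pv:
            if paths[pu]["head"] == v and paths[pu]["tail"] == u and u != v:
                succ[u] = (v, l)
                pred[v] = u
                paths[pu]["cyclic"] = True
                paths[pu]["closing"] = l
            continue
        if paths[pu]["tail"] != u or paths[pv]["head"] != v:
            continue
        succ[u] = (v, l)
        pred[v] = u
        paths[pu]["tail"] = paths[pv]["tail"]
        node = v
        while True:
            path_of[node] = pu
            if node not in succ:
                break
            node = succ[node][0]
        del paths[pv]

    used = set()
    layouts = []
    for pid in sorted(paths):
        info = paths[pid]
        nodes, junctions = [], []
        rid = info["head"]
        while True:
            nodes.append((rid, orient[rid]))
            used.add(rid)
            if rid in succ:
                nxt, l = succ[rid]
                if nxt == info["head"]:  # closing edge of a cycle
                    break
                junctions.append(l)
                rid = nxt
            else:
                break
        layouts.append(Layout(nodes, junctions, info["cyclic"],
                              info["closing"]))
    # untouched, non-contained reads become singleton layouts
    for r in reads:
        if r.id not in used and r.id not in contained:
            layouts.append(Layout([(r.id, "+")], []))
    return layouts


def _containment_placements(overlaps, by_id):
    """contained_id -> (container_id, relative orientation, hang on container +)."""
    placements = {}
    for ov in overlaps:
        if not ov.is_containment or ov.contained_id in placements:
            continue
        rel = "+" if ov.orientation == "forward" else "-"
        if ov.contained_id == ov.b_id:
            placements[ov.b_id] = (ov.a_id, rel, max(0, ov.a_hang))
        else:
            # a inside oriented b: express hang in b's + frame
            pos_in_oriented_b = -min(0, ov.a_hang)
            if ov.orientation == "forward":
                placements[ov.a_id] = (ov.b_id, "+", pos_in_oriented_b)
            else:
                lb, la = len(by_id[ov.b_id]), len(by_id[ov.a_id])
                placements[ov.a_id] = (ov.b_id, "-",
                                       lb - pos_in_oriented_b - la)
    return placements


def call_consensus(layout: Layout, reads: list[SequenceRecord],
                   config: PipelineConfig | None = None,
                   contained: dict | None = None,
                   ) -> tuple[DraftContig, list[str]]:
    """Splice the layout into a backbone and polish it by per-column vote.

    Returns the contig plus the ids of reads deferred for structural
    disagreement (second-round haplotype assembly). Cyclic layouts keep the
    closing overlap duplicated at the ends.
    """
    config = config or PipelineConfig()
    by_id = {r.id: r for r in reads}
    placements = []  # (rank, read_id, orient, offset)
    backbone = ""
    for i, (rid, o) in enumerate(layout.nodes):
        seq = _oriented(by_id[rid], o)
        if i == 0:
            offset = 0
            backbone = seq
        else:
            splice = layout.junction_overlaps[i - 1]
            offset = len(backbone) - splice
            backbone += seq[splice:]
        placements.append((i, rid, o, offset))

    if contained:
        base_rank = len(layout.nodes)
        node_pos = {rid: (o, off) for _, rid, o, off in placements}
        extra = []
        for cid in sorted(contained):
            container, rel, hang = contained[cid]
            if container not in node_pos:
                continue
            co, coff = node_pos[container]
            clen = len(by_id[container])
            if co == "+":
                extra.append((cid, _flip(rel, "+"), coff + hang))
            else:
                off = coff + clen - hang - len(by_id[cid])
                extra.append((cid, _flip(rel, "-"), off))
        for j, (cid, o, off) in enumerate(extra):
            placements.append((base_rank + j, cid, o, off))

    if len(placements) == 1:
        rid = placements[0][1]
        contig = DraftContig("", backbone, [rid], layout.is_cyclic)
        return contig, []

    L = len(backbone)
    votes: list[dict] = [dict() for _ in range(L)]
    ins_votes: dict[int, dict] = defaultdict(dict)
    cov = [0] * L
    deferred: list[str] = []
    aligned = []
    pad = 150
    for rank, rid, o, off in placements:
        seq = _oriented(by_id[rid], o)
        w0 = max(0, off - pad)
        w1 = min(L, off + len(seq) + pad)
        aln = align_infix(seq, backbone[w0:w1])
        if aln is None:
            deferred.append(rid)
            continue
        if (aln.identity < config.min_read_identity
                or aln.stats.max_indel >= config.min_structural_indel):
            deferred.append(rid)
            continue
        aligned.append((rank, rid, seq, w0 + aln.t_start, aln.cigar))

    for rank, rid, seq, t0, cigar in aligned:
        q = 0
        t = t0
        for nops, op in parse_cigar(cigar):
            if op in ("=", "X", "M"):
                for _ in range(nops):
                    _vote(votes[t], seq[q], rank)
                    cov[t] += 1
                    q += 1
                    t += 1
            elif op == "D":
                for _ in range(nops):
                    _vote(votes[t], "-", rank)
                    cov[t] += 1
                    t += 1
            elif op == "I":
                _vote(ins_votes[t], seq[q:q + nops], rank)
                q += nops

    out = []
    for t in range(L):
        if t in ins_votes and cov[t]:
            opt, (count, rank) = _best_option(ins_votes[t])
            if count * 2 > cov[t]:
                out.append(opt)
        if not votes[t]:
            out.append(backbone[t])
            continue
        opt, _ = _best_option(votes[t])
        if opt != "-":
            out.append(opt)
    consensus = "".join(out)
    support = [rid for _, rid, _, _ in placements if rid not in set(deferred)]
    contig = DraftContig("", consensus, support, layout.is_cyclic)
    return contig, deferred


def _flip(a: str, b: str) -> str:
    return "+" if a == b else "-"


def _vote(d: dict, option: str, rank: int) -> None:
    if option in d:
        d[option][0] += 1
    else:
        d[option] = [1, rank]


def _best_option(d: dict):
    # most votes; ties to the vote first cast by the earliest layout read
    return min(d.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))


def assemble(reads: list[SequenceRecord], config: PipelineConfig | None = None
             ) -> list[DraftContig]:
    """Two-round OLC assembly: main round, then deferred-read haplotype round."""
    config = config or PipelineConfig()
    if not reads:
        raise ValueError("no reads to assemble")
    contigs: list[DraftContig] = []
    counter = 1
    pool = list(reads)
    for round_no in (1, 2):
        overlaps = compute_overlaps(pool, config.min_overlap,
                                    config.min_overlap_identity)
        layouts = greedy_layout(overlaps, pool)
        by_id = {r.id: r for r in pool}
        placements = _containment_placements(overlaps, by_id)
        deferred_ids: list[str] = []
        for layout in layouts:
            node_ids = {rid for rid, _ in layout.nodes}
            local_contained = {
                cid: info for cid, info in placements.items()
                if info[0] in node_ids
            }
            contig, deferred = call_consensus(layout, pool, config,
                                              local_contained)
            contig.id = f"contig_{counter}"
            counter += 1
            contigs.append(contig)
            deferred_ids.extend(deferred)
        if round_no == 2 or len(deferred_ids) < config.min_deferred_reads:
            break
        seen = set()
        pool = [by_id[rid] for rid in deferred_ids
                if not (rid in seen or seen.add(rid))]
        if not pool:
            break
    return contigs


def accept_contigs(contigs: list[SequenceRecord]) -> list[DraftContig]:
    """Wrap externally assembled contigs unchanged (the -c entry point)."""
    if not contigs:
        raise ValueError("no contigs supplied")
    return [DraftContig(c.id, c.bases, [], False) for c in contigs]
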