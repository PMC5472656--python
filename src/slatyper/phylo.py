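"""Novel-allele characterisation: assembly, Jukes-Cantor distances,
neighbor-joining trees with bootstrap support, and locus placement.

Novel alleles are first seen as a single amplified insert; the complete exon
2-3 coding stretch is recovered by assembling two flanking amplicons onto the
core sequence by exact suffix-prefix overlap.  The assembled sequence is then
placed at a locus (SLA-1/-2/-3) by building a neighbor-joining tree over
Jukes-Cantor distances against the full reference library and reading off the
smallest locus-pure clade containing the novel leaf, with Felsenstein
bootstrap support from column resampling.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .genotyping import _aligner
from .library import (AlleleLibrary, PrimerPair, SHORT_PRIMERS, UNASSIGNED,
                      extract_amplicon)


class AssemblyError(ValueError):
    """Raised when fragment overlaps disagree or are too short."""


@dataclass
class AssembledSequence:
    """Exon 2-3 assembly of a novel allele from three overlapping fragments.

    Exon spans are 1-based inclusive coordinates on the assembled sequence
    (the conventional full-length exon 2 span is nt 33-302 and exon 3 runs
    303-578)."""

    ns_id: str
    sequence: str
    exon2_span: tuple[int, int] = (33, 302)
    exon3_span: tuple[int, int] = (303, 578)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def exon2_complete(self) -> bool:
        return self.length >= self.exon2_span[1]

    @property
    def exon3_complete(self) -> bool:
        return self.length >= self.exon3_span[1]

    def fasta_header(self) -> str:
        e2 = "complete" if self.exon2_complete else "partial"
        e3 = "complete" if self.exon3_complete else "partial"
        return (f"{self.ns_id} exon2={self.exon2_span[0]}-{self.exon2_span[1]}"
                f"({e2});exon3={self.exon3_span[0]}-{self.exon3_span[1]}({e3})")


def _suffix_prefix_overlap(left: str, right: str, min_overlap: int,
                           junction: str) -> int:
    """Longest k >= min_overlap with left[-k:] == right[:k]; raises with the
    first disagreeing position of the longest candidate otherwise."""
    for k in range(min(len(left), len(right)), min_overlap - 1, -1):
        if left[-k:] == right[:k]:
            return k
    k = min(len(left), len(right))
    tail, head = left[-k:], right[:k]
    first_bad = next((i + 1 for i in range(k) if tail[i] != head[i]), k)
    raise AssemblyError(
        f"no exact overlap >= {min_overlap} nt at the {junction} junction; "
        f"first disagreement at overlap position {first_bad}")


def assemble_exon2_3(core: str, exon2_frag: str, exon3_frag: str,
                     min_overlap: int = 30, ns_id: str = "NS",
                     exon2_span: tuple[int, int] = (33, 302),
                     exon3_span: tuple[int, int] = (303, 578)
                     ) -> AssembledSequence:
    """Assemble exon2-fragment + core + exon3-fragment by maximal exact
    suffix-prefix overlaps (containment collapses onto the container)."""
    if not (core and exon2_frag and exon3_frag):
        raise AssemblyError("all three fragments must be non-empty")
    if exon2_frag in core:
        left = core
    else:
        k = _suffix_prefix_overlap(exon2_frag, core, min_overlap, "exon2/core")
        left = exon2_frag[:len(exon2_frag) - k] + core
    if exon3_frag in left:
        assembled = left
    else:
        k = _suffix_prefix_overlap(left, exon3_frag, min_overlap, "core/exon3")
        assembled = left + exon3_frag[k:]
    return AssembledSequence(ns_id=ns_id, sequence=assembled,
                             exon2_span=exon2_span, exon3_span=exon3_span)


class JCDistance(NamedTuple):
    distance: float
    p: float
    compared: int
    saturated: bool


JC_SATURATION_CAP = 5.0


def jc_distance_info(seq_a: str, seq_b: str,
                     cap: float = JC_SATURATION_CAP) -> JCDistance:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) between equal-length
    aligned sequences; non-ACGT positions in either sequence are excluded;
    p >= 3/4 saturates to ``cap``."""
    if len(seq_a) != len(seq_b) or not seq_a:
        raise ValueError("sequences must be aligned to equal non-zero length")
    acgt = set("ACGT")
    diffs = compared = 0
    for x, y in zip(seq_a, seq_b):
        if x in acgt and y in acgt:
            compared += 1
            diffs += x != y
    if compared == 0:
        raise ValueError("no comparable (ACGT) positions")
    p = diffs / compared
    if p >= 0.75:
        return JCDistance(cap, p, compared, True)
    return JCDistance(-0.75 * math.log1p(-4.0 * p / 3.0), p, compared, False)


def jc_distance(seq_a: str, seq_b: str, cap: float = JC_SATURATION_CAP) -> float:
    return jc_distance_info(seq_a, seq_b, cap).distance


def jc_matrix(seqs: Mapping[str, str], cap: float = JC_SATURATION_CAP
              ) -> DistanceMatrix:
    """Pairwise JC distance matrix.  Equal-length inputs are compared
    directly; otherwise each pair is globally aligned first (unit costs, free
    end gaps) and gap columns are excluded."""
    names = list(seqs)
    n = len(names)
    lengths = {len(s) for s in seqs.values()}
    aligner = _aligner() if len(lengths) > 1 else None
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[names[i]], seqs[names[j]]
            if len(a) != len(b):
                aln = aligner.align(a, b)[0]
                ra, rb = aln[0], aln[1]
                pairs = [(x, y) for x, y in zip(ra, rb)
                         if x != "-" and y != "-"]
                a = "".join(x for x, _ in pairs)
                b = "".join(y for _, y in pairs)
            d = jc_distance(a, b, cap)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=names)


def _nj_rep(node_reps: list[str], i: int) -> str:
    return node_reps[i]


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (representative leaf) pair.  Negative branch lengths are clamped to zero
    with the deficit moved to the sibling branch so pairwise path lengths are
    preserved.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    reps: list[str] = list(ids)  # smallest leaf name under each active node
    active = list(range(n))

    def join(i: int, j: int, vi: float, vj: float) -> int:
        # clamp negatives, moving the deficit to the sibling
        if vi < 0:
            vj, vi = vi + vj, 0.0
        if vj < 0:
            vi, vj = vi + vj, 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(vi), float(vj)
        parent.extend([ci, cj])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            ((ai, aj) for ai, aj in cands if ai < aj),
            key=lambda t: tuple(sorted((reps[active[t[0]]],
                                        reps[active[t[1]]]))))
        ai, aj = best
        i, j = active[ai], active[aj]
        d_ij = D[i, j]
        vi = 0.5 * d_ij + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = d_ij - vi
        k = join(i, j, vi, vj)
        # distances from the new node to the remaining active nodes
        newrow = np.zeros(len(nodes))
        for a_ in active:
            if a_ in (i, j):
                continue
            newrow[a_] = 0.5 * (D[i, a_] + D[j, a_] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[k, :len(newrow)] = newrow
        D[:len(newrow), k] = newrow
        active = [a_ for a_ in active if a_ not in (i, j)] + [k]

    # final three nodes joined at an (unrooted) trifurcating root
    i, j, k = active
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        nodes[idx].length = float(max(v, 0.0))
        root.append(nodes[idx])
    return root


def two_taxon_tree(dm: DistanceMatrix) -> TreeNode:
    """Trivial single-edge tree for exactly two taxa."""
    a, b = dm.ids
    root = TreeNode()
    na, nb = TreeNode(name=a), TreeNode(name=b)
    na.length = float(dm[a, b]) / 2
    nb.length = float(dm[a, b]) / 2
    root.extend([na, nb])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (implicitly unrooted) tree, each
    canonicalised as the side not containing the smallest leaf name."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(seqs: Mapping[str, str], n_reps: int = 1000,
                      seed: int = 42, cap: float = JC_SATURATION_CAP
                      ) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Point-estimate JC+NJ tree with Felsenstein bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal bipartition of the point tree is the percentage
    of replicate trees containing it.  Supports are attached to the internal
    nodes (``node.support``) and used as internal node labels in newick.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires an aligned (equal-length) matrix")
    names = list(seqs)
    mat = np.array([np.frombuffer(seqs[n].encode(), dtype=np.uint8)
                    for n in names])
    L = mat.shape[1]

    point = nj_tree(jc_matrix(seqs, cap))
    splits = bipartitions(point)
    counts: Counter = Counter()
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = {n: mat[i, cols].tobytes().decode() for i, n in enumerate(names)}
        rep_splits = bipartitions(nj_tree(jc_matrix(rep, cap)))
        for s in splits & rep_splits:
            counts[s] += 1
    supports = {s: 100.0 * counts[s] / n_reps for s in splits}

    leaves = {t.name for t in point.tips()}
    ref = min(leaves)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves - side)
        if side in supports:
            node.support = supports[side]
            node.name = f"{supports[side]:.0f}"
    return point, supports


@dataclass
class LocusAssignment:
    ns_id: str
    locus: str
    support: float                # bootstrap % of the assigning clade, or -1
    low_confidence: bool
    nearest: str
    evidence: str


def assign_locus(novel: AssembledSequence, library: AlleleLibrary,
                 primers: PrimerPair = SHORT_PRIMERS, n_reps: int = 200,
                 purity: float = 0.90, seed: int = 42,
                 min_span: int = 100) -> LocusAssignment:
    """Place a novel sequence at a locus via the JC/NJ tree of the novel plus
    all library alleles over the common (amplified) span.

    The assigned locus is that of the smallest enclosing clade whose leaves
    are >= ``purity`` one locus, reported with that clade's bootstrap
    support; when no such clade exists the nearest neighbor's locus is used,
    flagged low-confidence.  Spans under ``min_span`` nt are refused: locus
    placement from short partial sequences is unreliable.
    """
    if novel.length < min_span:
        raise ValueError(
            f"novel sequence span {novel.length} nt < {min_span} nt; "
            "locus placement on short partial sequences is unreliable")
    seqs: dict[str, str] = {}
    locus_of: dict[str, str] = {}
    for rec in library:
        amp = extract_amplicon(rec, primers)
        if amp is None:
            continue
        seqs[rec.name] = amp.insert
        locus_of[rec.name] = rec.locus
    if len(seqs) < 2:
        raise ValueError("need at least two amplified library alleles")

    # trim everything to the common span: novel vs library inserts
    span = min(novel.length, *(len(s) for s in seqs.values()))
    matrix = {name: s[:span] for name, s in seqs.items()}
    matrix[novel.ns_id] = novel.sequence[:span]

    tree, supports = bootstrap_support(matrix, n_reps=n_reps, seed=seed)
    dm = jc_matrix(matrix)
    nearest = min((n for n in matrix if n != novel.ns_id),
                  key=lambda n: (dm[novel.ns_id, n], n))

    tip = next(t for t in tree.tips() if t.name == novel.ns_id)
    node = tip.parent
    while node is not None and node.parent is not None:
        members = [t.name for t in node.tips() if t.name != novel.ns_id]
        if members:
            tally = Counter(locus_of[m] for m in members)
            locus, cnt = tally.most_common(1)[0]
            if cnt / len(members) >= purity:
                support = getattr(node, "support", -1.0)
                return LocusAssignment(
                    novel.ns_id, locus, support, False, nearest,
                    f"smallest locus-pure clade of {len(members)} "
                    f"{locus} alleles")
        node = node.parent
    return LocusAssignment(
        novel.ns_id, locus_of[nearest], -1.0, True, nearest,
        "no locus-pure enclosing clade; nearest-neighbor fallback")
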