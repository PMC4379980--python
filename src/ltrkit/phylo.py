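"""Neighbour-joining phylogeny of reverse-transcriptase domains.

RT protein sequences of at least 80 aa are extracted from classified
elements, pairwise p-distances are computed from global alignments, and
the Saitou-Nei neighbour-joining algorithm builds an unrooted tree.
Bootstrap supports come from column resampling of an anchor-projected
pseudo-alignment.  Families are delimited by single-linkage clustering
of the distance matrix at a configurable cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import SequenceRecord
from ._align import align_stats, protein_global_aligner
from .classify import SuperfamilyCall, six_frame_translate
from .detect import FullLengthRE

log = logging.getLogger("ltrkit")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix entries must be finite")
        self.values = v


def extract_rt(elements: list[FullLengthRE], calls: dict[str, SuperfamilyCall],
               min_aa: int = 80) -> list[SequenceRecord]:
    """Translated RT regions of classified elements, at least ``min_aa`` long."""
    out: list[SequenceRecord] = []
    for el in elements:
        call = calls.get(el.element_id)
        if call is None or call.superfamily == "Unknown":
            continue
        rt_hits = [h for h in call.evidence if h.label == "RT"]
        if not rt_hits:
            continue
        hit = max(rt_hits, key=lambda h: h.score)
        nt = el.element_sequence[hit.interval.start : hit.interval.end]
        if hit.frame < 0:
            from .io import revcomp

            nt = revcomp(nt)
        prot = six_frame_translate(nt)[1] if len(nt) >= 3 else ""
        prot = prot.rstrip("*")
        if len(prot) < min_aa:
            log.info("element %s RT span %d aa < %d; excluded", el.element_id, len(prot), min_aa)
            continue
        out.append(SequenceRecord(el.element_id, prot))
    return out


def protein_distances(seqs: list[SequenceRecord]) -> DistanceMatrix:
    """Pairwise p-distances (1 - identity over gap-free aligned columns)."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n = len(seqs)
    aligner = protein_global_aligner()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            st = align_stats(aligner, seqs[i].sequence, seqs[j].sequence)
            cols = st.identities + st.mismatches
            dist = 1.0 - st.identities / cols if cols else 1.0
            d[i, j] = d[j, i] = dist
    return DistanceMatrix([s.id for s in seqs], d)


# --------------------------------------------------------------------------
# neighbour joining
# --------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list | None = None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.label])
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)


def nj_tree(matrix: DistanceMatrix) -> str:
    """Saitou-Nei neighbour joining; returns a newick string.

    Ties in the Q-criterion break deterministically towards the
    lexicographically smallest label pair; negative branch-length
    estimates are clamped to zero.
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("need at least three taxa")
    d = matrix.values.copy()
    nodes: list[_Node] = [_Node(label=l) for l in labels]
    order: list[str] = list(labels)  # smallest leaf label per node, for tie-breaks

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m - 1):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(order[i], order[j]), max(order[i], order[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        nodes = [nodes[x] for x in keep] + [new]
        order = [order[x] for x in keep] + [min(order[i], order[j])]
        d = d2

    # join the last three nodes at an unrooted trifurcation
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    root = _Node(children=[(a, la), (b, lb), (c, lc)])
    return root.newick() + ";"


def _bipartitions(node: _Node, all_leaves: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions (as the smaller/canonical side) of a tree."""
    parts: set[frozenset] = set()

    def walk(n: _Node) -> frozenset:
        if not n.children:
            return frozenset([n.label])
        acc: set[str] = set()
        for c, _ in n.children:
            leaves = walk(c)
            if 1 < len(leaves) < len(all_leaves) - 1:
                side = leaves
                other = all_leaves - leaves
                parts.add(min((frozenset(side), frozenset(other)), key=lambda s: (len(s), sorted(s))))
            acc |= leaves
        return frozenset(acc)

    walk(node)
    return parts


def newick_bipartitions(newick: str) -> set[frozenset]:
    """Bipartition set of a newick tree (via dendropy, label-order free)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    parts: set[frozenset] = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.tail_node is None:
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            parts.add(min((side, other), key=lambda s: (len(s), sorted(s))))
    return parts


def _anchor_pseudo_alignment(seqs: list[SequenceRecord]) -> np.ndarray:
    """Project all sequences onto the longest one to get resampleable columns.

    Returns a (n_seqs, n_anchor_columns) array of bytes; 45 (``-``) marks
    positions deleted relative to the anchor.  Insertions relative to the
    anchor are ignored — a deliberately simple stand-in for a multiple
    alignment, adequate for bootstrap column resampling.
    """
    anchor_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i].sequence), -i))
    anchor = seqs[anchor_idx].sequence
    aligner = protein_global_aligner()
    cols = np.full((len(seqs), len(anchor)), ord("-"), dtype=np.uint8)
    for i, s in enumerate(seqs):
        if i == anchor_idx:
            cols[i] = np.frombuffer(anchor.encode(), dtype=np.uint8)
            continue
        aln = aligner.align(anchor, s.sequence)[0]
        tblocks, qblocks = aln.aligned
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            seg = np.frombuffer(s.sequence[qs:qe].encode(), dtype=np.uint8)
            cols[i, ts:te] = seg
    return cols


def _pdist_from_columns(cols: np.ndarray) -> np.ndarray:
    n = cols.shape[0]
    d = np.zeros((n, n))
    gap = ord("-")
    for i in range(n):
        for j in range(i + 1, n):
            ok = (cols[i] != gap) & (cols[j] != gap)
            tot = int(ok.sum())
            dist = float((cols[i][ok] != cols[j][ok]).mean()) if tot else 1.0
            d[i, j] = d[j, i] = dist
    return d


def bootstrap_support(seqs: list[SequenceRecord], replicates: int = 100,
                      seed: int = 0) -> dict[frozenset, float]:
    """Bootstrap proportions for each internal bipartition of the NJ tree.

    Columns of the anchor-projected pseudo-alignment are resampled with
    replacement; the support of a bipartition is the fraction of
    replicate NJ trees that contain it.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    labels = [s.id for s in seqs]
    cols = _anchor_pseudo_alignment(seqs)
    base = DistanceMatrix(labels, _pdist_from_columns(cols))
    original = newick_bipartitions(nj_tree(base))
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    n_cols = cols.shape[1]
    for _ in range(replicates):
        sel = rng.integers(0, n_cols, size=n_cols)
        rep = DistanceMatrix(labels, _pdist_from_columns(cols[:, sel]))
        rep_parts = newick_bipartitions(nj_tree(rep))
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1
    return {bp: c / replicates for bp, c in counts.items()}


def family_clusters(matrix: DistanceMatrix, cutoff: float = 0.25) -> dict[str, int]:
    """Single-linkage families at a distance cutoff (1-based family ids)."""
    if len(matrix.labels) == 1:
        return {matrix.labels[0]: 1}
    condensed = squareform(matrix.values, checks=False)
    z = linkage(condensed, method="single")
    assignment = fcluster(z, t=cutoff, criterion="distance")
    return {lbl: int(fam) for lbl, fam in zip(matrix.labels, assignment)}
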