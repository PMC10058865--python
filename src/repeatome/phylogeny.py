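"""RT-domain phylogeny: extraction, progressive alignment, NJ, bootstrap.

The reverse-transcriptase (RT) domain is present in both Copia and Gypsy
elements and conserved enough to carry phylogenetic signal across lineages,
so retained full-length elements are compared through their RT nucleotide
sequences.  The pipeline is: extract RT subsequences (reverse-complemented
to the element strand), build a guide-tree-driven progressive multiple
alignment, compute pairwise K2P distances over ungapped columns, build a
Saitou-Nei neighbor-joining tree, and attach bootstrap supports from
column-resampled replicates.  Leaf ids follow ``species|lineage|element`` so
monophyly of lineages (and of species within a lineage) can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import GenomeSequence, RepeatomeError, reverse_complement, logger
from .dating import k2p_from_counts

_NEG = -1e30


# ---------------------------------------------------------------------------
# RT extraction
# ---------------------------------------------------------------------------

def extract_rt(elements: Sequence, genome) -> list[GenomeSequence]:
    """RT nucleotide subsequences of retained elements, on the element strand.

    Elements without an RT domain hit are skipped with a log entry.  Ids are
    ``species|lineage|index``.
    """
    seq = genome.seq if hasattr(genome, "seq") else str(genome)
    out = []
    skipped = 0
    for i, el in enumerate(elements):
        rt_hits = [h for h in getattr(el, "domains", []) if h.domain == "RT"]
        if not rt_hits:
            skipped += 1
            continue
        hit = max(rt_hits, key=lambda h: h.score)
        sub = seq[hit.start:hit.end]
        if getattr(el, "strand", "+") == "-":
            sub = reverse_complement(sub)
        species = getattr(el, "species", "") or "sp"
        lineage = getattr(el, "lineage", "") or "unclassified"
        out.append(GenomeSequence(f"{species}|{lineage}|{i}", sub))
    if skipped:
        logger.warning("extract_rt: %d element(s) lack an RT domain", skipped)
    return out


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RtAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise RepeatomeError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


_SYM = "ACGT-"
_SYM_INDEX = {s: i for i, s in enumerate(_SYM)}
# column score: match +2, mismatch -1, gap symbol neutral
_S5 = np.full((5, 5), -1.0)
np.fill_diagonal(_S5, 2.0)
_S5[4, :] = 0.0
_S5[:, 4] = 0.0

_GAP_OPEN = -5.0
_GAP_EXT = -1.0


def _profile(rows: Sequence[str]) -> np.ndarray:
    arr = np.zeros((len(rows[0]), 5))
    for row in rows:
        for j, ch in enumerate(row):
            arr[j, _SYM_INDEX.get(ch, 4)] += 1
    return arr / len(rows)


def _profile_align(rows_a: Sequence[str], rows_b: Sequence[str]
                   ) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) global profile-profile alignment.

    Deterministic tie-breaking: diagonal > gap-in-B > gap-in-A.  Returns the
    two row groups padded to the merged column space.
    """
    fa, fb = _profile(rows_a), _profile(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    score = fa @ _S5 @ fb.T

    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)   # consumes A (gap in B)
    Y = np.full((la + 1, lb + 1), _NEG)   # consumes B (gap in A)
    M[0, 0] = 0.0
    X[1:, 0] = _GAP_OPEN + _GAP_EXT * np.arange(la)
    Y[0, 1:] = _GAP_OPEN + _GAP_EXT * np.arange(lb)
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + score[i - 1]
        X[i] = np.maximum(np.maximum(M[i - 1], Y[i - 1]) + _GAP_OPEN,
                          X[i - 1] + _GAP_EXT)
        # Y within-row scan: Y[i,j] = max(Z[j-1], Y[i,j-1] + ext)
        Z = np.maximum(M[i], X[i]) + _GAP_OPEN
        u = Z - _GAP_EXT * np.arange(lb + 1)
        run = np.maximum.accumulate(u[:-1])
        Y[i, 1:] = run + _GAP_EXT * np.arange(1, lb + 1)
        Y[i, 0] = _NEG

    # traceback
    ops: list[str] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            ops.append("A")
            came_ext = X[i, j] == X[i - 1, j] + _GAP_EXT
            opens = np.array([M[i - 1, j], Y[i - 1, j]]) + _GAP_OPEN
            i -= 1
            if came_ext and X[i, j] + _GAP_EXT >= max(opens):
                state = 1
            else:
                state = 0 if opens[0] >= opens[1] else 2
        else:
            ops.append("B")
            came_ext = Y[i, j] == Y[i, j - 1] + _GAP_EXT
            opens = np.array([M[i, j - 1], X[i, j - 1]]) + _GAP_OPEN
            j -= 1
            if came_ext and Y[i, j] + _GAP_EXT >= max(opens):
                state = 2
            else:
                state = 0 if opens[0] >= opens[1] else 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ia += 1
            ib += 1
        elif op == "A":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
    return out_a, out_b


def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def align_rt(sequences: Sequence[GenomeSequence]) -> RtAlignment:
    """Guide-tree-driven progressive multiple alignment.

    Sequences are sorted by id first, so the result is invariant to input
    order; the guide tree is UPGMA on pairwise k-mer distances and groups
    are merged by affine-gap profile-profile alignment.
    """
    if len(sequences) < 2:
        raise RepeatomeError("need at least 2 sequences to align")
    seqs = sorted(sequences, key=lambda s: s.id)
    n = len(seqs)
    if n == 2:
        a, b = _profile_align([seqs[0].seq], [seqs[1].seq])
        return RtAlignment((seqs[0].id, seqs[1].id), (a[0], b[0]))
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i].seq, seqs[j].seq)
    Z = linkage(squareform(d, checks=False), method="average")
    groups: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i].id], [seqs[i].seq]) for i in range(n)}
    for m, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = groups.pop(int(a))
        ids_b, rows_b = groups.pop(int(b))
        new_a, new_b = _profile_align(rows_a, rows_b)
        groups[n + m] = (ids_a + ids_b, new_a + new_b)
    ids, rows = groups.popitem()[1]
    order = np.argsort(ids)
    return RtAlignment(tuple(ids[i] for i in order),
                       tuple(rows[i] for i in order))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i


def _encode_rows(rows: Sequence[str]) -> np.ndarray:
    return np.vstack([_ENC[np.frombuffer(r.encode(), dtype=np.uint8)]
                      for r in rows])


def k2p_matrix(alignment: RtAlignment, clamp: float = 1e-6) -> np.ndarray:
    """Pairwise K2P distances over ungapped, unambiguous columns.

    Near-saturated pairs are clamped to a large finite distance so NJ stays
    defined; fully informative data never hits the clamp.
    """
    enc = _encode_rows(alignment.rows)
    n = enc.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            valid = (a < 4) & (b < 4)
            nv = int(valid.sum())
            if nv == 0:
                D[i, j] = D[j, i] = 0.0
                continue
            diff = valid & (a != b)
            x = a ^ b
            ts = int((diff & (x == 2)).sum())
            tv = int(diff.sum()) - ts
            D[i, j] = D[j, i] = k2p_from_counts(nv, ts, tv, clamp=clamp).K
    return D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree represented with a trifurcating root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def total_branch_length(self) -> float:
        total = 0.0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, length in node.children:
                total += length
                stack.append(child)
        return total

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions, keyed by the canonical leaf-set side.

        The canonical side is the one not containing the alphabetically
        first leaf.
        """
        all_leaves = frozenset(self.root.leaves())
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, _ in node.children:
                stack.append(child)
                side = frozenset(child.leaves())
                if len(side) < 2 or len(side) > len(all_leaves) - 2:
                    continue
                if ref in side:
                    side = all_leaves - side
                out[side] = child
        return out

    def is_monophyletic(self, leaf_set: Iterable[str]) -> bool:
        target = frozenset(leaf_set)
        all_leaves = frozenset(self.root.leaves())
        if not target or not target <= all_leaves:
            return False
        if len(target) in (1, len(all_leaves), len(all_leaves) - 1):
            return True
        ref = min(all_leaves)
        if ref in target:
            target = all_leaves - target
        return target in self.bipartitions()

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.name
            inner = ",".join(f"{fmt(c)}:{l:.6f}" for c, l in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}"
        return fmt(self.root) + ";"


def nj_tree(matrix: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing Q = (n-2) d(i,j) - R_i - R_j with
    the standard two-point branch lengths; negative branch lengths are
    clamped to zero with the excess transferred to the sister branch.  On an
    additive matrix the generating topology and branch lengths are recovered
    exactly.  Returns an unrooted tree (trifurcating root).
    """
    D = np.asarray(matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise RepeatomeError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise RepeatomeError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise RepeatomeError("need at least 3 taxa for NJ")
    if len(ids) != n:
        raise RepeatomeError("ids do not match matrix size")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, d_new])
        d_new = np.append(d_new, 0.0)
        D = np.column_stack([D, d_new])
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(alignment: RtAlignment,
                      rng: np.random.Generator,
                      n_reps: int = 100,
                      distance_fn: Callable[[RtAlignment], np.ndarray] = k2p_matrix,
                      ) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    ``n_reps`` replicates resample alignment columns with replacement; the
    support of each internal branch of the reference tree is the percentage
    of replicates whose NJ tree contains the same bipartition.
    """
    ref = nj_tree(distance_fn(alignment), alignment.ids)
    ref_biparts = ref.bipartitions()
    counts = {side: 0 for side in ref_biparts}
    L = alignment.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = tuple("".join(row[c] for c in cols) for row in alignment.rows)
        rep = RtAlignment(alignment.ids, rows)
        rep_tree = nj_tree(distance_fn(rep), rep.ids)
        rep_sides = set(rep_tree.bipartitions())
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for side, node in ref_biparts.items():
        node.support = 100.0 * counts[side] / n_reps
    return ref


# ---------------------------------------------------------------------------
# monophyly reporting
# ---------------------------------------------------------------------------

def _leaf_labels(tree: PhyloTree) -> dict[str, tuple[str, str]]:
    """leaf id -> (species, lineage) parsed from ``species|lineage|...`` ids."""
    out = {}
    for leaf in tree.leaf_names():
        parts = leaf.split("|")
        species = parts[0] if parts else leaf
        lineage = parts[1] if len(parts) > 1 else "unclassified"
        out[leaf] = (species, lineage)
    return out


def lineage_separation_report(tree: PhyloTree) -> pd.DataFrame:
    """Monophyly summary per lineage and per species.

    For each label class, reports whether the label's leaves form a clade in
    the unrooted tree, the size of the largest label-pure subtree, and the
    bootstrap support of the separating branch where one exists.
    """
    labels = _leaf_labels(tree)
    all_leaves = frozenset(labels)
    biparts = tree.bipartitions()
    rows = []
    for kind, idx in (("lineage", 1), ("species", 0)):
        values = sorted({v[idx] for v in labels.values()})
        for value in values:
            members = frozenset(l for l, v in labels.items() if v[idx] == value)
            mono = tree.is_monophyletic(members)
            largest_pure = 1
            support = None
            for side, node in biparts.items():
                for candidate in (side, all_leaves - side):
                    if candidate <= members and len(candidate) > largest_pure:
                        largest_pure = len(candidate)
                if side == members or (all_leaves - side) == members:
                    support = node.support
            if len(members) in (len(all_leaves), len(all_leaves) - 1):
                largest_pure = len(members)
            elif members in (frozenset(s) for s in biparts):
                largest_pure = len(members)
            rows.append({"kind": kind, "label": value,
                         "n_leaves": len(members), "monophyletic": mono,
                         "largest_pure_clade": max(largest_pure,
                                                   1 if members else 0),
                         "support": support})
    return pd.DataFrame(rows)
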