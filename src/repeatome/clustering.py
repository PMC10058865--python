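"""Graph-based repeat quantification from unassembled reads.

Repetitive DNA is quantified without assembly by an all-to-all similarity
comparison of sequence reads: reads sampled from the same repeat family
overlap and align to each other, so connected components of the similarity
graph correspond to repeat subfamilies ("clusters"), and the fraction of
reads falling into clusters estimates the repetitive fraction of the genome.
Clusters linked by shared mate pairs are grouped into superclusters
(approximating repeat families), and clusters are annotated by similarity
search (nucleotide and six-frame translated) against a labeled repeat
library.

Default edge thresholds: >= 90 % identity over >= 55 % of the read length.
A shared-9-mer prefilter bounds the number of alignments; 9 is chosen so
that any pair passing the default thresholds necessarily shares an exact
9-mer (>= 50 matching columns broken by <= 5 non-matches leave a run of
length >= ceil(50/6) = 9), so prefiltering never removes a passing pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_core import (GenomeSequence, ParseError, RepeatomeError,
                      reverse_complement, logger)


# ---------------------------------------------------------------------------
# pairwise read similarity
# ---------------------------------------------------------------------------

def _nt_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_NT_ALIGNER = _nt_local_aligner()


def _pep_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_PEP_ALIGNER = _pep_local_aligner()


def _alignment_identity(aln) -> tuple[float, int]:
    """(percent identity, overlap columns) of a local alignment.

    Columns are the locally aligned region including internal gap columns;
    identity counts identical base columns.
    """
    qblocks, tblocks = aln.aligned
    q, t = aln.sequences
    matches = 0
    block_cols = 0
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        block_cols += q1 - q0
        matches += sum(a == b for a, b in zip(q[q0:q1], t[t0:t1]))
    gap_cols = 0
    for i in range(1, len(qblocks)):
        gap_cols += (qblocks[i][0] - qblocks[i - 1][1]) \
            + (tblocks[i][0] - tblocks[i - 1][1])
    cols = block_cols + gap_cols
    return (100.0 * matches / cols if cols else 0.0), cols


def read_similarity(a: str, b: str) -> tuple[float, int]:
    """Best local-alignment identity/overlap over both strands of ``b``."""
    best = (0.0, 0)
    for bb in (b, reverse_complement(b)):
        if _NT_ALIGNER.score(a, bb) <= 0:
            continue
        identity, cols = _alignment_identity(_NT_ALIGNER.align(a, bb)[0])
        if identity * cols > best[0] * best[1]:
            best = (identity, cols)
    return best


def _passes(a: str, b: str, min_identity: float, min_cols: int
            ) -> tuple[float, int] | None:
    """Edge test with a score-bound shortcut before any traceback.

    A passing alignment (identity >= f over >= C columns) has local score at
    least C*(3f - 2) under the +1/-1/-2 scoring, so a best score below that
    bound proves no passing alignment exists.
    """
    f = min_identity / 100.0
    bound = min_cols * (3.0 * f - 2.0) if f > 2.0 / 3.0 else 0.0
    best: tuple[float, int] | None = None
    for bb in (b, reverse_complement(b)):
        if _NT_ALIGNER.score(a, bb) < bound:
            continue
        identity, cols = _alignment_identity(_NT_ALIGNER.align(a, bb)[0])
        if identity >= min_identity and cols >= min_cols:
            if best is None or identity * cols > best[0] * best[1]:
                best = (identity, cols)
    return best


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)
            if "N" not in seq[i:i + k]}


def build_similarity_graph(reads: Sequence[GenomeSequence],
                           min_identity: float = 90.0,
                           min_overlap_fraction: float = 0.55,
                           k: int = 9,
                           prefilter: bool = True,
                           max_reads: int = 50_000,
                           subsample_seed: int = 0) -> nx.Graph:
    """All-to-all similarity graph over reads.

    An edge joins two reads iff a local alignment on either strand reaches
    ``min_identity`` percent over at least ``min_overlap_fraction`` of the
    (shorter) read length.  With ``prefilter`` a shared-k-mer screen limits
    which pairs are aligned; with the default thresholds the screen is
    lossless (see module docstring).  Inputs beyond ``max_reads`` are
    deterministically subsampled.
    """
    if not reads:
        raise RepeatomeError("no reads to cluster")
    if not (0 < min_identity <= 100) or not (0 < min_overlap_fraction <= 1):
        raise ValueError("thresholds out of range")
    if len(reads) > max_reads:
        import numpy as np
        rng = np.random.default_rng(subsample_seed)
        idx = sorted(rng.choice(len(reads), size=max_reads, replace=False))
        logger.info("subsampling %d of %d reads (seed %d)",
                    max_reads, len(reads), subsample_seed)
        reads = [reads[i] for i in idx]
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in reads)
    graph.graph["total_reads"] = len(reads)

    if prefilter:
        index: dict[str, list[int]] = {}
        for i, r in enumerate(reads):
            for km in _kmers(r.seq, k):
                index.setdefault(km, []).append(i)
        pairs: set[tuple[int, int]] = set()
        for i, r in enumerate(reads):
            partners: set[int] = set()
            for km in _kmers(r.seq, k) | _kmers(reverse_complement(r.seq), k):
                partners.update(index.get(km, ()))
            for j in partners:
                if j > i:
                    pairs.add((i, j))
        candidate_pairs: Iterable[tuple[int, int]] = sorted(pairs)
    else:
        candidate_pairs = ((i, j) for i in range(len(reads))
                           for j in range(i + 1, len(reads)))

    for i, j in candidate_pairs:
        a, b = reads[i], reads[j]
        min_cols = int(min_overlap_fraction * min(len(a.seq), len(b.seq)) + 0.9999)
        hit = _passes(a.seq, b.seq, min_identity, min_cols)
        if hit is not None:
            graph.add_edge(a.id, b.id, identity=round(hit[0], 2), overlap=hit[1])
    return graph


# ---------------------------------------------------------------------------
# clusters and superclusters
# ---------------------------------------------------------------------------

@dataclass
class ReadCluster:
    id: int
    read_ids: tuple[str, ...]
    genome_proportion: float    # percent of the analyzed reads
    is_top: bool = False
    annotation: str = "unknown"
    supercluster: int | None = None

    @property
    def size(self) -> int:
        return len(self.read_ids)


@dataclass
class Supercluster:
    id: int
    cluster_ids: tuple[int, ...]
    read_count: int


def cluster_graph(graph: nx.Graph,
                  top_threshold_pct: float = 0.01
                  ) -> tuple[list[ReadCluster], list[str]]:
    """Connected components (>= 2 reads) as clusters; the rest are singlets.

    Clusters are sorted by size descending (ties by smallest read id) and
    numbered from 1; ``is_top`` marks clusters holding more than
    ``top_threshold_pct`` percent of the analyzed reads.
    """
    total = graph.graph.get("total_reads", graph.number_of_nodes())
    components = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), c[0]))
    clusters = []
    for i, comp in enumerate(components, start=1):
        proportion = 100.0 * len(comp) / total
        clusters.append(ReadCluster(
            id=i, read_ids=tuple(comp), genome_proportion=proportion,
            is_top=proportion > top_threshold_pct))
    singlets = sorted(n for n in graph.nodes if graph.degree(n) == 0)
    return clusters, singlets


def _pair_base(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[:-2]
    return read_id


def build_superclusters(clusters: Sequence[ReadCluster],
                        min_shared_pairs: int = 1) -> list[Supercluster]:
    """Group clusters connected by shared mate pairs.

    Two clusters are linked when at least ``min_shared_pairs`` read pairs
    have one mate in each (mates recognized by the /1 and /2 id suffixes);
    superclusters are connected components of that cluster-level graph and
    partition the clusters.
    """
    cluster_of: dict[str, int] = {}
    for c in clusters:
        for rid in c.read_ids:
            cluster_of[rid] = c.id
    link_counts: dict[tuple[int, int], int] = {}
    by_base: dict[str, list[int]] = {}
    for rid, cid in cluster_of.items():
        by_base.setdefault(_pair_base(rid), []).append(cid)
    for cids in by_base.values():
        if len(cids) == 2 and cids[0] != cids[1]:
            key = tuple(sorted(cids))
            link_counts[key] = link_counts.get(key, 0) + 1
    g = nx.Graph()
    g.add_nodes_from(c.id for c in clusters)
    for (a, b), n in link_counts.items():
        if n >= min_shared_pairs:
            g.add_edge(a, b)
    size_of = {c.id: c.size for c in clusters}
    comps = [sorted(comp) for comp in nx.connected_components(g)]
    comps.sort(key=lambda comp: (-sum(size_of[c] for c in comp), comp[0]))
    supers = []
    for i, comp in enumerate(comps, start=1):
        supers.append(Supercluster(i, tuple(comp),
                                   sum(size_of[c] for c in comp)))
        for c in clusters:
            if c.id in comp:
                c.supercluster = i
    return supers


# ---------------------------------------------------------------------------
# cluster annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryEntry:
    name: str
    label: str                  # "class/superfamily/lineage" (levels optional)
    seq: str


def load_repeat_library(path: str | Path) -> list[LibraryEntry]:
    """Read a repeat library FASTA with ``name#class/superfamily/lineage``
    headers; an entry without a ``#label`` tag is an error."""
    entries = []
    with Path(path).open() as fh:
        header, chunks = None, []
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    entries.append(_library_entry(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
        if header is not None:
            entries.append(_library_entry(header, "".join(chunks)))
    return entries


def _library_entry(header: str, seq: str) -> LibraryEntry:
    name = header.split()[0]
    if "#" not in name:
        raise ParseError(f"library entry {name!r} lacks a #class label")
    base, label = name.split("#", 1)
    return LibraryEntry(base, label, seq.upper())


def _six_frame_peptides(seq: str) -> list[str]:
    rc = reverse_complement(seq)
    peps = []
    for src in (seq, rc):
        for f in range(3):
            sub = src[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                peps.append(str(Seq(sub).translate()))
    return peps


def annotate_clusters(clusters: Sequence[ReadCluster],
                      reads_by_id: Mapping[str, str],
                      library: Sequence[LibraryEntry],
                      nt_score_threshold: float = 30.0,
                      aa_score_threshold: float = 50.0,
                      max_reads_per_cluster: int = 30) -> list[ReadCluster]:
    """Label clusters against a repeat library.

    Each sampled member read is searched against every library family in
    nucleotide mode (local alignment, both strands) and, where that fails,
    in translated mode (all six frames of both read and family, BLOSUM62).
    The cluster label is the label of the family collecting the most read
    hits; ties break toward the higher summed score; no hits leaves the
    cluster "unknown".
    """
    if not library:
        raise RepeatomeError("empty repeat library")
    lib_peps = {e.name: _six_frame_peptides(e.seq) for e in library}
    for cluster in clusters:
        votes: dict[str, int] = {}
        scores: dict[str, float] = {}
        sample = cluster.read_ids[:max_reads_per_cluster]
        for rid in sample:
            seq = reads_by_id[rid]
            rc = reverse_complement(seq)
            read_peps = None
            for entry in library:
                nt = max(_NT_ALIGNER.score(seq, entry.seq),
                         _NT_ALIGNER.score(rc, entry.seq))
                hit_score = nt if nt >= nt_score_threshold else None
                if hit_score is None:
                    if read_peps is None:
                        read_peps = _six_frame_peptides(seq)
                    aa = max((_PEP_ALIGNER.score(rp, lp)
                              for rp in read_peps
                              for lp in lib_peps[entry.name]), default=0.0)
                    if aa >= aa_score_threshold:
                        hit_score = aa
                if hit_score is not None:
                    votes[entry.name] = votes.get(entry.name, 0) + 1
                    scores[entry.name] = scores.get(entry.name, 0.0) + hit_score
        if votes:
            best = max(votes, key=lambda n: (votes[n], scores[n], n))
            label = next(e.label for e in library if e.name == best)
            cluster.annotation = label
        else:
            cluster.annotation = "unknown"
    return list(clusters)


def clustered_fraction(clusters: Sequence[ReadCluster], total_reads: int
                       ) -> float:
    """Percent of analyzed reads that fell into clusters (2 decimals)."""
    if total_reads <= 0:
        raise RepeatomeError("total read count must be positive")
    return round(100.0 * sum(c.size for c in clusters) / total_reads, 2)
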