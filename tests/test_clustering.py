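import networkx as nx
import numpy as np
import pytest

from repeatome import clustering as clu
from repeatome import synthetic as syn
from repeatome.io_core import GenomeSequence, ParseError, reverse_complement
from repeatome.survey_tables import load_read_clustering


def _reads_from_template(template, n, read_len, rng, prefix):
    """Reads tiled over a template so neighbours overlap well."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, len(template) - read_len + 1))
        out.append(GenomeSequence(f"{prefix}{i}", template[start:start + read_len]))
    return out


def test_identical_reads_make_one_full_identity_edge(rng):
    seq = syn.random_dna(100, rng)
    g = clu.build_similarity_graph([GenomeSequence("a", seq),
                                    GenomeSequence("b", seq)])
    assert g.number_of_edges() == 1
    assert g["a"]["b"]["identity"] == 100.0
    assert g["a"]["b"]["overlap"] == 100


def test_reverse_complement_still_matches(rng):
    seq = syn.random_dna(100, rng)
    g = clu.build_similarity_graph(
        [GenomeSequence("a", seq),
         GenomeSequence("b", reverse_complement(seq))])
    assert g.number_of_edges() == 1


def test_random_reads_share_no_edge(rng):
    g = clu.build_similarity_graph(
        [GenomeSequence("a", syn.random_dna(100, rng)),
         GenomeSequence("b", syn.random_dna(100, rng))])
    assert g.number_of_edges() == 0


def test_family_reads_cluster_unique_reads_do_not(rng):
    """Edges appear only within the repeat-family group; the k-mer prefilter
    agrees exactly with brute-force all-pairs alignment."""
    family_template = syn.random_dna(160, rng)
    family = _reads_from_template(family_template, 20, 100, rng, "fam")
    unique = [GenomeSequence(f"uni{i}", syn.random_dna(100, rng))
              for i in range(20)]
    reads = family + unique
    fast = clu.build_similarity_graph(reads)
    brute = clu.build_similarity_graph(reads, prefilter=False)
    assert set(map(frozenset, fast.edges())) == set(map(frozenset, brute.edges()))
    for u, v in fast.edges():
        assert u.startswith("fam") and v.startswith("fam")
    comps = [c for c in nx.connected_components(fast) if len(c) >= 2]
    assert len(comps) == 1 and comps[0] == {r.id for r in family}


def test_edgeless_graph_gives_only_singlets():
    g = nx.Graph()
    g.add_nodes_from(f"r{i}" for i in range(5))
    g.graph["total_reads"] = 5
    clusters, singlets = clu.cluster_graph(g)
    assert clusters == [] and len(singlets) == 5


def test_cluster_proportions_and_top_rule():
    g = nx.Graph()
    g.graph["total_reads"] = 1000
    for i in range(30):
        g.add_edge(f"a{i}", f"a{(i + 1) % 30}")
    for i in range(10):
        g.add_edge(f"b{i}", f"b{(i + 1) % 10}")
    clusters, _ = clu.cluster_graph(g)
    assert [c.size for c in clusters] == [30, 10]
    assert [c.genome_proportion for c in clusters] == [3.0, 1.0]
    assert all(c.is_top for c in clusters)
    assert clusters[0].id == 1


def test_partition_invariant(planted):
    genome, truth, recipe = planted
    rng = np.random.default_rng(3)
    import dataclasses
    small = dataclasses.replace(recipe, coverage=0.6)
    pairs = syn.simulate_reads(genome, small, rng)
    reads = []
    for p in pairs:
        reads.append(GenomeSequence(f"{p.id}/1", p.mate1))
        reads.append(GenomeSequence(f"{p.id}/2", p.mate2))
    g = clu.build_similarity_graph(reads)
    clusters, singlets = clu.cluster_graph(g)
    assert sum(c.size for c in clusters) + len(singlets) == len(reads)
    total_prop = sum(c.genome_proportion for c in clusters)
    assert total_prop == pytest.approx(
        clu.clustered_fraction(clusters, len(reads)), abs=0.01)


def test_raising_identity_threshold_refines_partition(rng):
    template = syn.random_dna(140, rng)
    reads = _reads_from_template(template, 15, 100, rng, "r")
    # degrade some reads so identities spread below/above the bar
    degraded = [GenomeSequence(r.id, syn.mutate_k2p(r.seq, 0.08, 2.0, rng))
                for r in reads]
    loose = clu.build_similarity_graph(degraded, min_identity=85)
    strict = clu.build_similarity_graph(degraded, min_identity=97)
    strict_comps = list(nx.connected_components(strict))
    for comp in strict_comps:
        # every strict component sits inside one loose component
        containers = [c for c in nx.connected_components(loose) if comp <= c]
        assert len(containers) == 1


def _mkclusters(spec):
    return [clu.ReadCluster(id=i + 1, read_ids=tuple(rids),
                            genome_proportion=0.0)
            for i, rids in enumerate(spec)]


def test_superclusters_without_links_match_clusters():
    clusters = _mkclusters([("a0/1", "a1/1"), ("b0/1", "b1/1")])
    supers = clu.build_superclusters(clusters)
    assert sorted(s.cluster_ids for s in supers) == [(1,), (2,)]


def test_supercluster_threshold_and_transitivity():
    a = tuple(f"p{i}/1" for i in range(5)) + ("x0/1",)
    b = tuple(f"p{i}/2" for i in range(5)) + ("q0/1",)
    c = ("q0/2", "y0/1")
    clusters = _mkclusters([a, b, c])
    merged = clu.build_superclusters(clusters, min_shared_pairs=3)
    by_size = {s.cluster_ids for s in merged}
    assert (1, 2) in by_size and (3,) in by_size  # 5 pairs >= 3; 1 pair < 3
    chained = clu.build_superclusters(_mkclusters([a, b, c]),
                                      min_shared_pairs=1)
    assert {s.cluster_ids for s in chained} == {(1, 2, 3)}


def test_genome_proportion_formula_reproduces_survey_values():
    table = load_read_clustering()
    for species, row in table.iterrows():
        cluster = clu.ReadCluster(1, ("r",) * int(row["clustered_reads"]), 0.0)
        recomputed = clu.clustered_fraction([cluster], int(row["total_reads"]))
        assert recomputed == pytest.approx(row["genome_proportion_pct"])


def test_annotation_by_library(rng, tmp_path):
    fam_seq = syn.random_dna(3000, rng)
    lib_path = tmp_path / "lib.fa"
    lib_path.write_text(f">fam1#LTR/Copia/SIRE\n{fam_seq}\n"
                        f">fam2#LTR/Gypsy/Tat\n{syn.random_dna(3000, rng)}\n")
    entries = clu.load_repeat_library(lib_path)
    fam_reads = _reads_from_template(fam_seq, 8, 100, rng, "fam")
    rand_reads = [GenomeSequence(f"bg{i}", syn.random_dna(100, rng))
                  for i in range(4)]
    clusters = [
        clu.ReadCluster(1, tuple(r.id for r in fam_reads), 0.0),
        clu.ReadCluster(2, tuple(r.id for r in rand_reads), 0.0),
    ]
    reads_by_id = {r.id: r.seq for r in fam_reads + rand_reads}
    clu.annotate_clusters(clusters, reads_by_id, entries)
    assert clusters[0].annotation == "LTR/Copia/SIRE"
    assert clusters[1].annotation == "unknown"


def test_translated_only_homology_detected(rng, tmp_path):
    """A synonymous recode destroys nucleotide identity but keeps the
    peptide, so only the translated search can label the cluster."""
    from Bio.Seq import Seq
    from repeatome.synthetic import reverse_translate, _CODONS
    peptide = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
    dna = reverse_translate(peptide, rng)
    # recode every codon to the synonymous codon sharing fewest bases
    recoded = []
    for i in range(0, len(dna), 3):
        codon = dna[i:i + 3]
        options = _CODONS[str(Seq(codon).translate())]
        recoded.append(max(options,
                           key=lambda c: sum(a != b for a, b in zip(c, codon))))
    recoded = "".join(recoded)
    assert str(Seq(recoded).translate()) == peptide
    nt_identity = sum(a == b for a, b in zip(dna, recoded)) / len(dna)
    assert nt_identity < 0.75
    lib_path = tmp_path / "lib.fa"
    lib_path.write_text(f">fam#LTR/Copia/SIRE\n{dna}\n")
    entries = clu.load_repeat_library(lib_path)
    cluster = clu.ReadCluster(1, ("r0",), 0.0)
    clu.annotate_clusters([cluster], {"r0": recoded}, entries,
                          nt_score_threshold=80.0)
    assert cluster.annotation == "LTR/Copia/SIRE"


def test_unlabeled_library_entry_rejected(tmp_path):
    p = tmp_path / "lib.fa"
    p.write_text(">fam1\nACGTACGT\n")
    with pytest.raises(ParseError, match="lacks a #class label"):
        clu.load_repeat_library(p)
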