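import numpy as np
import pytest

from repeatome import annotate as ann
from repeatome import phylogeny as phy
from repeatome import synthetic as syn
from repeatome.evaluation import random_additive_tree, tree_distance_matrix
from repeatome.io_core import GenomeSequence, RepeatomeError, reverse_complement


def _element_with_rt(seq_id, rt_start, rt_end, strand="+", species="spA",
                     lineage="SIRE"):
    el = ann.FullLengthElement(seq_id, (0, 300), (rt_end + 1000,
                                                  rt_end + 1300), 99.0,
                               species=species, lineage=lineage)
    el.strand = strand
    el.domains = [ann.DomainHit("RT", rt_start, rt_end,
                                0 if strand == "+" else 3, 100.0,
                                "ref", lineage, "Copia")]
    return el


def test_extract_rt_interval_and_strand(rng):
    genome = GenomeSequence("g", syn.random_dna(5000, rng))
    plus = _element_with_rt("g", 400, 1000)
    minus = _element_with_rt("g", 400, 1000, strand="-")
    seqs = phy.extract_rt([plus, minus], genome)
    assert len(seqs[0].seq) == 600
    assert seqs[0].seq == genome.seq[400:1000]
    assert seqs[1].seq == reverse_complement(genome.seq[400:1000])
    assert seqs[0].id.startswith("spA|SIRE|")


def test_extract_rt_skips_elements_without_rt(rng):
    genome = GenomeSequence("g", syn.random_dna(5000, rng))
    el = ann.FullLengthElement("g", (0, 300), (3000, 3300), 99.0)
    assert phy.extract_rt([el], genome) == []


def test_identical_sequences_align_gap_free(rng):
    seq = syn.random_dna(200, rng)
    aln = phy.align_rt([GenomeSequence("a", seq), GenomeSequence("b", seq)])
    assert aln.rows[0] == aln.rows[1] == seq


def test_single_deletion_gives_one_gap_run(rng):
    seq = syn.random_dna(300, rng)
    deleted = seq[:150] + seq[153:]
    aln = phy.align_rt([GenomeSequence("a", seq),
                        GenomeSequence("b", deleted)])
    gappy = aln.rows[list(aln.ids).index("b")]
    runs = [r for r in gappy.replace("-", " ").split() if r]
    assert gappy.count("-") == 3
    assert "---" in gappy                      # one contiguous run
    assert gappy.replace("-", "") == deleted


def test_alignment_invariant_to_input_order(rng):
    seqs = syn.simulate_rt_sequences(
        [("Copia", "SIRE"), ("Gypsy", "Tat")], 3, rng, length=200)
    aln1 = phy.align_rt(seqs)
    aln2 = phy.align_rt(list(reversed(seqs)))
    assert aln1.ids == aln2.ids
    assert aln1.rows == aln2.rows


def test_three_taxon_closed_form():
    D = np.array([[0.0, 2.0, 4.0],
                  [2.0, 0.0, 4.0],
                  [4.0, 4.0, 0.0]])
    tree = phy.nj_tree(D, ["A", "B", "C"])
    lengths = {child.name: length for child, length in tree.root.children}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def test_nj_exact_on_additive_matrices(rng):
    for _ in range(25):
        n = int(rng.integers(4, 13))
        D, labels = random_additive_tree(n, rng)
        tree = phy.nj_tree(D, labels)
        assert np.allclose(tree_distance_matrix(tree, labels), D, atol=1e-6)
        assert sorted(tree.leaf_names()) == sorted(labels)


def test_nj_agrees_with_reference_implementation(rng):
    """Independent cross-check: scikit-bio's NJ on the same matrix yields the
    same unrooted topology (bipartition set)."""
    import skbio
    D, labels = random_additive_tree(8, rng)
    D = (D + D.T) / 2.0  # remove float asymmetry from path summation
    ours = phy.nj_tree(D, labels)
    ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
    ref_biparts = set()
    n_leaves = len(labels)
    first = min(labels)
    for node in ref.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n_leaves - 2:
            if first in side:
                side = frozenset(labels) - side
            ref_biparts.add(side)
    assert set(ours.bipartitions()) == ref_biparts


def test_equal_distances_give_equal_pendant_branches():
    D = np.ones((4, 4)) - np.eye(4)
    tree = phy.nj_tree(D, list("ABCD"))
    total = tree.total_branch_length()
    assert total == pytest.approx(sum(
        l for _, l in tree.root.children) + sum(
        l for child, _ in tree.root.children
        for _, l in child.children), abs=1e-9)


def test_asymmetric_matrix_rejected():
    D = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.raises(RepeatomeError, match="symmetric"):
        phy.nj_tree(D, list("ABC"))


def test_bootstrap_supports_separation(rng):
    seqs = syn.simulate_rt_sequences(
        [("Copia", "SIRE"), ("Gypsy", "Tat")], 4, rng, length=400,
        ancestor_sub=0.3, within_sub=0.01)
    aln = phy.align_rt(seqs)
    tree = phy.bootstrap_support(aln, np.random.default_rng(1), n_reps=50)
    supports = [node.support for node in tree.bipartitions().values()
                if node.support is not None]
    assert supports and all(0 <= s <= 100 for s in supports)
    sire = frozenset(l for l in tree.leaf_names() if "|SIRE|" in l)
    assert tree.is_monophyletic(sire)
    report = phy.lineage_separation_report(tree)
    lin = report[report["kind"] == "lineage"].set_index("label")
    assert lin.loc["SIRE", "support"] == 100.0


def test_bootstrap_deterministic_under_seed(rng):
    seqs = syn.simulate_rt_sequences(
        [("Copia", "SIRE"), ("Gypsy", "Tat")], 3, rng, length=200)
    aln = phy.align_rt(seqs)
    t1 = phy.bootstrap_support(aln, np.random.default_rng(9), n_reps=20)
    t2 = phy.bootstrap_support(aln, np.random.default_rng(9), n_reps=20)
    assert t1.newick() == t2.newick()


def test_k2p_matrix_counts(rng):
    aln = phy.RtAlignment(("a", "b"), ("ACGTAC-T", "GCGTACAT"))
    D = phy.k2p_matrix(aln)
    # 7 comparable columns, one A<->G transition
    from repeatome.dating import k2p_from_counts
    assert D[0, 1] == pytest.approx(k2p_from_counts(7, 1, 0).K)


def test_single_label_trivially_monophyletic(rng):
    seqs = syn.simulate_rt_sequences([("Copia", "SIRE")], 4, rng, length=200,
                                     within_sub=0.05)
    aln = phy.align_rt(seqs)
    tree = phy.nj_tree(phy.k2p_matrix(aln), aln.ids)
    report = phy.lineage_separation_report(tree)
    lin = report[report["kind"] == "lineage"]
    assert lin["monophyletic"].all()
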