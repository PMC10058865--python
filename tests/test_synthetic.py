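import numpy as np
import pytest

from repeatome import io_core as io
from repeatome import synthetic as syn
from repeatome.dating import count_substitutions


def test_age_zero_gives_identical_ltrs(rng, library):
    spec = syn.ElementSpec("Copia", "SIRE", ltr_len=300, internal_len=2200,
                           age_T=0.0)
    seq, realized = syn.make_element(spec, rng, library)
    assert seq[:300] == seq[-300:]
    assert realized["divergence"] == 0.0
    assert seq[:2] == "TG" and seq[-2:] == "CA"


def test_ltr_length_bounds_enforced():
    with pytest.raises(io.RepeatomeError):
        syn.ElementSpec("Copia", "SIRE", ltr_len=80, internal_len=2000)
    with pytest.raises(io.RepeatomeError):
        syn.ElementSpec("Copia", "SIRE", ltr_len=100, internal_len=100)


def test_mean_divergence_matches_2rT(rng, library):
    """Across replicates the realized inter-LTR K2P distance averages 2rT."""
    spec = syn.ElementSpec("Copia", "SIRE", ltr_len=10_000, internal_len=2200)
    consensus = syn.build_consensus(spec, rng, library)
    rate, age = 2e-8, 1e6          # expected divergence 2rT = 0.04
    k2ps = []
    for _ in range(200):
        _, realized = syn.mutate_copy(consensus, spec, age, rate, 2.0, rng)
        k2ps.append(realized["k2p"])
    k2ps = np.array(k2ps)
    se = k2ps.std(ddof=1) / np.sqrt(len(k2ps))
    assert abs(k2ps.mean() - 0.04) < 3 * se


def test_mutation_respects_protected_positions(rng):
    seq = "TG" + "A" * 96 + "CA"
    out = syn.mutate_k2p(seq, 5.0, 2.0, rng, protect=(0, 1, 98, 99))
    assert out[:2] == "TG" and out[-2:] == "CA"
    assert out != seq  # lambda=5 per site certainly mutates the middle


def test_empty_recipe_gives_pure_background(rng):
    recipe = syn.SimRecipe(genome_length=5_000)
    genome, truth = syn.plant_elements(recipe, rng)
    assert len(genome.seq) == 5_000
    assert truth.elements == [] and truth.tandems == []
    assert truth.repeat_fraction == 0.0


def test_planted_fraction_hits_target(rng):
    """Scaling copy numbers to a 0.60 target lands within +-0.05 (2 Mb)."""
    spec = syn.ElementSpec("Copia", "SIRE", ltr_len=1000, internal_len=8000)
    fam = syn.RepeatFamily("f", spec, 10, syn.AgeDistribution.point(0.1))
    recipe = syn.SimRecipe(genome_length=2_000_000, families=[fam])
    recipe = syn.scale_to_fraction(recipe, 0.60)
    genome, truth = syn.plant_elements(recipe, rng)
    assert abs(truth.repeat_fraction - 0.60) <= 0.05


def test_forced_nesting_records_parent_child(rng):
    spec = syn.ElementSpec("Gypsy", "Tekay", ltr_len=300, internal_len=3000)
    fam = syn.RepeatFamily("f", spec, 2, syn.AgeDistribution.point(0.1))
    recipe = syn.SimRecipe(genome_length=50_000, families=[fam],
                           nesting_probability=1.0)
    genome, truth = syn.plant_elements(recipe, rng)
    parents = [e for e in truth.elements if e.parent is not None]
    assert len(parents) == 1
    child = parents[0]
    host = next(e for e in truth.elements if e.id == child.parent)
    assert host.ltr5[1] <= child.start and child.end <= host.ltr3[0]
    assert host.interrupted


def test_truth_intervals_valid_and_tsd_duplicated(planted):
    genome, truth, recipe = planted
    for e in truth.elements:
        assert 0 <= e.start < e.end <= len(genome.seq)
        element = genome.seq[e.start:e.end]
        assert element.startswith("TG") and element.endswith("CA")
        # TSD: 5 bp left of the element equal the 5 bp right of it
        assert genome.seq[e.start - 5:e.start] == genome.seq[e.end:e.end + 5]
        # extracting the truth LTRs reproduces the recorded divergence
        l5 = genome.seq[e.ltr5[0]:e.ltr5[1]]
        l3 = genome.seq[e.ltr3[0]:e.ltr3[1]]
        n, ts, tv = count_substitutions(l5, l3)
        assert (ts, tv) == (e.transitions, e.transversions)


def test_read_count_matches_coverage_formula(rng):
    recipe = syn.SimRecipe(genome_length=100_000, coverage=10.0)
    genome, _ = syn.plant_elements(recipe, rng)
    pairs = syn.simulate_reads(genome, recipe, rng)
    assert len(pairs) == 10 * 100_000 // (2 * 100)


def test_error_free_reads_are_genome_substrings(rng):
    recipe = syn.SimRecipe(genome_length=20_000, coverage=1.0)
    genome, _ = syn.plant_elements(recipe, rng)
    pairs = syn.simulate_reads(genome, recipe, rng)
    both = genome.seq + "#" + io.reverse_complement(genome.seq)
    for p in pairs[:50]:
        assert p.mate1 in both and p.mate2 in both


def test_read_simulation_deterministic(rng, tmp_path):
    recipe = syn.SimRecipe(genome_length=10_000, coverage=1.0)
    genome, _ = syn.plant_elements(recipe, rng)
    p1 = syn.simulate_reads(genome, recipe, np.random.default_rng(5))
    p2 = syn.simulate_reads(genome, recipe, np.random.default_rng(5))
    f1a, f1b = tmp_path / "a1.fq", tmp_path / "a2.fq"
    f2a, f2b = tmp_path / "b1.fq", tmp_path / "b2.fq"
    io.write_fastq_pair(p1, f1a, f1b)
    io.write_fastq_pair(p2, f2a, f2b)
    assert f1a.read_bytes() == f2a.read_bytes()
    assert f1b.read_bytes() == f2b.read_bytes()


def test_invalid_recipe_parameters_rejected():
    with pytest.raises(io.RepeatomeError):
        syn.SimRecipe(genome_length=1000, coverage=0.0)
    with pytest.raises(io.RepeatomeError):
        syn.SimRecipe(genome_length=1000, kappa=0.0)
    with pytest.raises(io.RepeatomeError):
        syn.RepeatFamily("f", syn.ElementSpec("Copia", "SIRE", 300, 2000),
                         -1, syn.AgeDistribution.point(1.0))
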