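"""Ground-truth evaluation of every pipeline stage on synthetic data.

Each function sets up a synthetic study condition (planted genomes, RT
cohorts, random additive trees), runs the corresponding method, and measures
its accuracy against the known truth: dating bias, detector recall and
boundary error, filter agreement, clustering equivalence with brute-force
alignment, NJ recovery, lineage monophyly.  The same functions back both the
test suite and the reproduction script, so reported numbers are always
recomputed from scratch.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np

from . import annotate as ann
from . import clustering as clu
from . import dating as dat
from . import detect as det
from . import phylogeny as phy
from . import synthetic as syn
from .io_core import GenomeSequence


# ---------------------------------------------------------------------------
# dating round trip
# ---------------------------------------------------------------------------

def dating_recovery(seed: int,
                    ages_mya: Sequence[float] = (0.5, 1.0, 2.0, 5.0, 10.0),
                    n_per_cohort: int = 300,
                    ltr_len: int = 2000,
                    kappa: float = 2.0,
                    rate: float = dat.DEFAULT_RATE,
                    bin_width: float = 0.5) -> dict:
    """Plant cohorts of known age; estimate ages back through the full
    align -> K2P -> T = K/(2r) chain.

    Reports, per cohort, the mean estimated age, its standard error, the
    absolute deviation from truth in SE units, and whether the histogram
    mode falls in a bin whose closure contains the true age (the planted
    ages sit exactly on bin edges, so both adjacent bins contain the truth
    in closure).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    ltr = syn.random_dna(ltr_len, rng)
    out = {}
    for age in ages_mya:
        lam = rate * age * 1e6
        estimates = []
        for _ in range(n_per_cohort):
            l5 = syn.mutate_k2p(ltr, lam, kappa, rng)
            l3 = syn.mutate_k2p(ltr, lam, kappa, rng)
            aln = dat.align_ltr_pair(l5, l3)
            dist = dat.k2p_distance(aln)
            if dist.saturated:
                continue
            estimates.append(dat.insertion_age(dist.K, rate).mya)
        estimates = np.array(estimates)
        mean = float(estimates.mean())
        se = float(estimates.std(ddof=1) / np.sqrt(len(estimates)))
        edges = np.arange(0.0, max(ages_mya) + 5 * bin_width, bin_width)
        counts, _ = np.histogram(estimates, bins=edges)
        mode_lo = float(edges[int(np.argmax(counts))])
        mode_hi = mode_lo + bin_width
        out[age] = {
            "mean_mya": mean,
            "se": se,
            "z": abs(mean - age) / se if se > 0 else 0.0,
            "mode_bin": (mode_lo, mode_hi),
            "mode_contains_truth": mode_lo <= age <= mode_hi,
            "n": int(len(estimates)),
        }
    return out


# ---------------------------------------------------------------------------
# detector recall / precision
# ---------------------------------------------------------------------------

def _detector_recipe(genome_length: int, n_elements: int) -> syn.SimRecipe:
    """Study condition: elements with divergence <= 10 % (ages <= ~2 MY) and
    intact TSD / terminal motif."""
    layouts = [(500, 3000), (800, 4400), (1200, 6000),
               (400, 2600), (700, 5000), (1000, 3500)]
    lineages = [("Copia", "SIRE"), ("Copia", "Angela"), ("Copia", "Ale"),
                ("Gypsy", "Tekay"), ("Gypsy", "Athila"), ("Gypsy", "Tat")]
    peaks = [0.5, 0.8, 1.1, 1.4, 1.7, 2.0]
    per_family = n_elements // len(layouts)
    families = []
    for (ltr, internal), (sf, lin), peak in zip(layouts, lineages, peaks):
        spec = syn.ElementSpec(sf, lin, ltr_len=ltr, internal_len=internal)
        families.append(syn.RepeatFamily(
            f"{sf}_{lin}", spec, per_family,
            syn.AgeDistribution.gaussian(peak, 0.1)))
    return syn.SimRecipe(genome_length=genome_length, families=families,
                         mutate_tsd=False, preserve_motif=True)


def detector_benchmark(seed: int, genome_length: int = 2_000_000,
                       n_elements: int = 60,
                       params: det.DetectionParams = det.DetectionParams()
                       ) -> dict:
    """Recall, boundary accuracy and constraint compliance on one genome."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 102]))
    recipe = _detector_recipe(genome_length, n_elements)
    genome, truth = syn.plant_elements(recipe, rng)
    calls = det.detect_elements(genome, params)

    qualifying = [e for e in truth.elements
                  if e.divergence <= 0.10 and e.tsd_intact and e.motif_intact]
    matched = 0
    boundary_errors = []
    for e in qualifying:
        best = None
        for c in calls:
            ov = min(e.end, c.element[1]) - max(e.start, c.element[0])
            if ov > 0.5 * (e.end - e.start):
                err = max(abs(c.element[0] - e.start), abs(c.element[1] - e.end))
                if best is None or err < best:
                    best = err
        if best is not None:
            matched += 1
            boundary_errors.append(best)

    violations = 0
    for c in calls:
        l5 = c.ltr5[1] - c.ltr5[0]
        l3 = c.ltr3[1] - c.ltr3[0]
        ok = (params.min_ltr_len <= l5 <= params.max_ltr_len
              and params.min_ltr_len <= l3 <= params.max_ltr_len
              and params.min_element_len <= c.element_len <= params.max_element_len
              and c.ltr_identity >= params.min_ltr_identity
              and c.motif_ok and c.tsd is not None and len(c.tsd) == params.tsd_len)
        if not ok:
            violations += 1

    return {
        "n_planted": len(truth.elements),
        "n_qualifying": len(qualifying),
        "n_calls": len(calls),
        "recall_pct": 100.0 * matched / len(qualifying) if qualifying else 0.0,
        "max_boundary_error": max(boundary_errors) if boundary_errors else 0,
        "mean_boundary_error": float(np.mean(boundary_errors))
        if boundary_errors else 0.0,
        "n_violations": violations,
    }


# ---------------------------------------------------------------------------
# filter correctness
# ---------------------------------------------------------------------------

def filter_benchmark(seed: int, n_clean: int = 8, n_nested_pairs: int = 4,
                     n_violations: int = 6) -> dict:
    """Plant clean, nested, and domain-order-violating elements; check that
    the filter's verdicts agree with the truth registry 100 %."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 103]))
    library = ann.default_domain_library()
    clean_specs = [
        syn.ElementSpec("Copia", "SIRE", ltr_len=400, internal_len=2600),
        syn.ElementSpec("Gypsy", "Athila", ltr_len=500, internal_len=2800),
    ]
    bad_specs = [
        # duplicated RT
        syn.ElementSpec("Copia", "Angela", ltr_len=400, internal_len=3200,
                        domain_order=("GAG", "PR", "INT", "RT", "RT", "RH")),
        # INT/RT order swapped relative to the Copia layout
        syn.ElementSpec("Copia", "Ale", ltr_len=400, internal_len=2600,
                        domain_order=("GAG", "PR", "RT", "INT", "RH")),
    ]
    families = []
    for i, spec in enumerate(clean_specs):
        families.append(syn.RepeatFamily(
            f"clean{i}", spec, n_clean // len(clean_specs),
            syn.AgeDistribution.point(0.3)))
    for i, spec in enumerate(bad_specs):
        families.append(syn.RepeatFamily(
            f"bad{i}", spec, n_violations // len(bad_specs),
            syn.AgeDistribution.point(0.3)))
    # host/guest pairs for nesting
    host_spec = syn.ElementSpec("Gypsy", "Tekay", ltr_len=400,
                                internal_len=3200)
    families.append(syn.RepeatFamily("host", host_spec, n_nested_pairs,
                                     syn.AgeDistribution.point(0.5)))
    recipe = syn.SimRecipe(genome_length=500_000, families=families,
                           mutate_tsd=False, preserve_motif=True,
                           nesting_probability=0.0)
    genome, truth = syn.plant_elements(recipe, rng)

    # force one nested guest inside each host element
    guest_spec = syn.ElementSpec("Copia", "SIRE", ltr_len=400,
                                 internal_len=2000)
    guest_consensus = syn.build_consensus(guest_spec, rng, library)
    seq = genome.seq
    hosts = [e for e in truth.elements if e.family == "host"]
    for k, host in enumerate(hosts):
        gseq, realized = syn.mutate_copy(guest_consensus, guest_spec, 0.2e6,
                                         recipe.rate, recipe.kappa, rng,
                                         preserve_motif=True)
        pos = (host.ltr5[1] + host.ltr3[0]) // 2
        tsd = seq[pos:pos + 5]
        seq = seq[:pos] + tsd + gseq + seq[pos:]
        added = len(gseq) + 5
        for e in truth.elements:
            if e.start > pos:
                e.start += added
                e.end += added
                e.ltr5 = (e.ltr5[0] + added, e.ltr5[1] + added)
                e.ltr3 = (e.ltr3[0] + added, e.ltr3[1] + added)
            elif e.end > pos:
                e.end += added
                e.ltr3 = (e.ltr3[0] + added, e.ltr3[1] + added)
                e.interrupted = True
        start = pos + 5
        truth.elements.append(syn.PlantedElement(
            id=f"guest_{k}", seq_id=genome.id, start=start,
            end=start + len(gseq),
            ltr5=(start, start + guest_spec.ltr_len),
            ltr3=(start + len(gseq) - guest_spec.ltr_len, start + len(gseq)),
            family="guest", superfamily="Copia", lineage="SIRE",
            domain_order=guest_spec.resolved_order(), age_years=0.2e6,
            divergence=realized["divergence"], k2p=realized["k2p"],
            transitions=realized["transitions"],
            transversions=realized["transversions"],
            tsd=tsd, tsd_intact=True, motif_intact=realized["motif_intact"],
            parent=host.id))
    genome = GenomeSequence(genome.id, seq)

    # build candidates straight from the truth registry (the filter is what
    # is under test here, not the detector)
    candidates = [det.LtrCandidate(genome.id, e.ltr5, e.ltr3,
                                   ltr_identity=100.0 - 100 * e.divergence,
                                   tsd=e.tsd, motif_ok=True)
                  for e in truth.elements]
    elements = ann.annotate_elements(candidates, genome, library)
    retained, removal_log = ann.filter_elements(elements)

    status_of = {e.element: e.status for e in elements}
    agree = total = 0
    for e in truth.elements:
        expected = "retained"
        if e.interrupted:
            expected = "removed_nested"
        elif e.family.startswith("bad"):
            expected = "removed_domain_order"
        got = status_of.get((e.start, e.end))
        total += 1
        agree += int(got == expected)
    return {
        "n_elements": total,
        "n_retained": len(retained),
        "n_removed": len(removal_log),
        "agreement_pct": 100.0 * agree / total if total else 0.0,
    }


# ---------------------------------------------------------------------------
# clustering equivalence
# ---------------------------------------------------------------------------

def _partition(graph: nx.Graph) -> set[frozenset]:
    return {frozenset(c) for c in nx.connected_components(graph) if len(c) >= 2}


def clustering_equivalence(seed: int, max_reads: int = 500) -> dict:
    """Exact partition agreement between k-mer-prefiltered clustering and
    brute-force all-pairs alignment clustering on a small read set."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104]))
    families = [
        syn.RepeatFamily("f1", syn.ElementSpec("Copia", "SIRE", 400, 2400),
                         4, syn.AgeDistribution.point(0.2)),
        syn.RepeatFamily("f2", syn.ElementSpec("Gypsy", "Tat", 400, 2400),
                         3, syn.AgeDistribution.point(0.5)),
    ]
    recipe = syn.SimRecipe(genome_length=45_000, families=families,
                           coverage=1.0)
    genome, _ = syn.plant_elements(recipe, rng)
    pairs = syn.simulate_reads(genome, recipe, rng)
    reads = []
    for p in pairs:
        reads.append(GenomeSequence(f"{p.id}/1", p.mate1))
        reads.append(GenomeSequence(f"{p.id}/2", p.mate2))
    reads = reads[:max_reads]
    fast = clu.build_similarity_graph(reads, prefilter=True)
    brute = clu.build_similarity_graph(reads, prefilter=False)
    same = _partition(fast) == _partition(brute)
    clusters, singlets = clu.cluster_graph(fast)
    return {
        "n_reads": len(reads),
        "n_edges": fast.number_of_edges(),
        "n_clusters": len(clusters),
        "identical_partition": same,
        "partition_agreement_pct": 100.0 if same else 0.0,
    }


# ---------------------------------------------------------------------------
# NJ recovery on additive matrices
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator
                         ) -> tuple[np.ndarray, list[str]]:
    """Random unrooted binary tree -> its additive leaf distance matrix."""
    g = nx.Graph()
    labels = [f"t{i}" for i in range(n_taxa)]
    g.add_edge(labels[0], "x0", weight=rng.uniform(0.05, 1.0))
    g.add_edge(labels[1], "x0", weight=rng.uniform(0.05, 1.0))
    g.add_edge(labels[2], "x0", weight=rng.uniform(0.05, 1.0))
    internal = 1
    for leaf in labels[3:]:
        u, v = list(g.edges)[rng.integers(g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"x{internal}"
        internal += 1
        split = rng.uniform(0.2, 0.8)
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, leaf, weight=rng.uniform(0.05, 1.0))
    D = np.zeros((n_taxa, n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n_taxa):
        for j in range(n_taxa):
            D[i, j] = lengths[labels[i]][labels[j]]
    return D, labels


def tree_distance_matrix(tree: phy.PhyloTree, labels: Sequence[str]
                         ) -> np.ndarray:
    g = nx.Graph()
    counter = [0]

    def walk(node):
        if not node.children:
            return node.name
        me = f"__internal{counter[0]}"
        counter[0] += 1
        for child, length in node.children:
            g.add_edge(me, walk(child), weight=length)
        return me

    walk(tree.root)
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = lengths[labels[i]][labels[j]] if i != j else 0.0
    return D


def nj_recovery(seed: int, n_trees: int = 100, max_taxa: int = 12) -> dict:
    """Fraction of random additive matrices whose generating tree NJ
    reconstructs exactly (branch lengths to 1e-6)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 105]))
    exact = 0
    for _ in range(n_trees):
        n = int(rng.integers(4, max_taxa + 1))
        D, labels = random_additive_tree(n, rng)
        tree = phy.nj_tree(D, labels)
        D2 = tree_distance_matrix(tree, labels)
        if np.allclose(D, D2, atol=1e-6):
            exact += 1
    return {"n_trees": n_trees, "exact_pct": 100.0 * exact / n_trees}


# ---------------------------------------------------------------------------
# phylogenetic structure recovery
# ---------------------------------------------------------------------------

def phylo_structure(seed: int, n_per_lineage: int = 6,
                    n_bootstrap: int = 100) -> dict:
    """Monophyly + bootstrap support for well-separated synthetic lineages,
    and species non-monophyly within a single shuffled lineage."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 106]))
    lineages = [("Copia", "SIRE"), ("Copia", "Angela"),
                ("Gypsy", "Tekay"), ("Gypsy", "Athila")]
    seqs = syn.simulate_rt_sequences(lineages, n_per_lineage, rng,
                                     species=("HEL", "LAC", "CYN"))
    alignment = phy.align_rt(seqs)
    tree = phy.bootstrap_support(alignment, rng, n_reps=n_bootstrap)
    report = phy.lineage_separation_report(tree)
    lin = report[report["kind"] == "lineage"]
    supports = [s for s in lin["support"] if s is not None and not np.isnan(s)]
    all_mono = bool(lin["monophyletic"].all())
    min_support = min(supports) if supports else float("nan")

    # single lineage, species labels round-robin (i.e. shuffled w.r.t. the
    # within-lineage structure)
    seqs1 = syn.simulate_rt_sequences([("Copia", "SIRE")], 12, rng,
                                      species=("HEL", "LAC", "CYN"),
                                      within_sub=0.05)
    aln1 = phy.align_rt(seqs1)
    tree1 = phy.nj_tree(phy.k2p_matrix(aln1), aln1.ids)
    rep1 = phy.lineage_separation_report(tree1)
    sp1 = rep1[rep1["kind"] == "species"]
    return {
        "n_lineages": len(lin),
        "all_lineages_monophyletic": all_mono,
        "lineages_monophyletic_pct": 100.0 * lin["monophyletic"].mean(),
        "min_lineage_support": float(min_support),
        "shuffled_species_monophyletic": int(sp1["monophyletic"].sum()),
        "n_shuffled_species": len(sp1),
    }


# ---------------------------------------------------------------------------
# table arithmetic (published survey values)
# ---------------------------------------------------------------------------

def table_arithmetic() -> dict:
    """Recompute the survey tables' derived quantities from primary cells."""
    from . import summary as summ
    from . import survey_tables as st

    reads = st.load_read_clustering()
    proportions = {
        sp: round(100.0 * row["clustered_reads"] / row["total_reads"], 2)
        for sp, row in reads.iterrows()}

    props = st.load_ltr_proportions()
    lineage_rows = props[props["lineage"] != "Total"]
    totals = props[props["lineage"] == "Total"].set_index("superfamily")
    species = list(st.SPECIES)
    matrix = totals[species]
    ratios = summ.gypsy_copia_ratio(matrix)
    maxdiff_super = summ.max_difference(matrix)
    sire = lineage_rows[(lineage_rows["lineage"] == "SIRE")][species]
    sire_maxdiff = float(summ.max_difference(sire).iloc[0])

    counts = st.load_element_counts()
    copia_total = {sp: int(counts.loc[counts["superfamily"] == "Copia",
                                      sp].sum()) for sp in species}
    gypsy_total = {sp: int(counts.loc[counts["superfamily"] == "Gypsy",
                                      sp].sum()) for sp in species}
    species_total = {sp: int(counts[sp].sum()) for sp in species}
    grand_total = sum(species_total.values())
    hel = "Helianthus annuus"
    return {
        "proportions_pct": proportions,
        "gypsy_copia_ratio": {sp: float(ratios[sp]) for sp in species},
        "copia_max_difference": float(maxdiff_super["Copia"]),
        "gypsy_max_difference": float(maxdiff_super["Gypsy"]),
        "sire_max_difference": sire_maxdiff,
        "helianthus_copia_total": copia_total[hel],
        "helianthus_gypsy_total": gypsy_total[hel],
        "helianthus_total": species_total[hel],
        "helianthus_gypsy_share_pct": round(
            100.0 * gypsy_total[hel] / species_total[hel], 1),
        "grand_total_elements": grand_total,
    }
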