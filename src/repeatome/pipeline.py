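"""End-to-end pipeline: simulate -> cluster -> detect -> annotate -> date ->
phylogeny -> summarize.

The pipeline is driven by a declarative config (a plain mapping, typically
loaded from YAML).  With a ``simulate`` section it generates the per-species
synthetic genomes and reads itself; otherwise the config must name input
files per stage (``genomes``, ``reads``, ``library``).  One global seed is
set per run; each stochastic stage draws from a stage-named substream, so
adding or removing a stage never perturbs the randomness of the others.
Outputs are plain TSV/FASTA/GFF3/newick files plus a JSON echo of the
effective parameters; a rerun with the same seed and config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import annotate as ann
from . import clustering as clu
from . import dating as dat
from . import detect as det
from . import phylogeny as phy
from . import summary as summ
from . import synthetic as syn
from .io_core import (GenomeSequence, StageError, logger, parse_sequences,
                      write_annotations, write_fasta, write_fastq_pair)

_STAGE_IDS = {"simulate": 1, "cluster": 2, "detect": 3, "annotate": 4,
              "date": 5, "phylo": 6, "summarize": 7}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for one stage of one run."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_IDS[stage]]))


def _species_recipes(cfg: Mapping[str, Any], rng: np.random.Generator
                     ) -> dict[str, syn.SimRecipe]:
    """Per-species recipes sharing family consensus sequences and the rDNA
    monomer, with per-species copy-number variation (so abundance profiles
    differ across species while repeats are homologous)."""
    species = list(cfg.get("species", ["spA", "spB"]))
    base = syn.default_recipe(
        genome_length=int(cfg.get("genome_length", 150_000)),
        coverage=float(cfg.get("coverage", 3.0)),
        nesting_probability=float(cfg.get("nesting_probability", 0.0)),
        copies_per_family=int(cfg.get("copies_per_family", 3)),
        ltr_len=int(cfg.get("ltr_len", 400)),
        internal_len=int(cfg.get("internal_len", 2400)),
    )
    library = ann.default_domain_library()
    for fam in base.families:
        fam.consensus = syn.build_consensus(fam.spec, rng, library, base.gc)
    for tan in base.tandems:
        tan.monomer = syn.random_dna(tan.monomer_len, rng, base.gc)
    recipes = {}
    for sp in species:
        families = []
        for fam in base.families:
            jitter = int(rng.integers(0, max(fam.copy_number, 1) + 1))
            families.append(dataclasses.replace(
                fam, copy_number=max(1, fam.copy_number + jitter - 1)))
        recipes[sp] = dataclasses.replace(base, families=families,
                                          tandems=list(base.tandems))
    return recipes


def run_pipeline(config: Mapping[str, Any], outdir: str | Path,
                 seed: int | None = None) -> dict[str, Any]:
    """Execute the stages in order and write per-stage outputs.

    Returns a results dictionary (per-species cluster tables, detected
    candidates, annotated elements, dating tables, trees, summary tables).
    Raises :class:`StageError` naming the stage when an input is missing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    results: dict[str, Any] = {"seed": seed}
    echo = {"seed": seed, "config": {k: v for k, v in config.items()}}
    (outdir / "run_config.json").write_text(
        json.dumps(echo, indent=2, default=str, sort_keys=True))

    sim_cfg = config.get("simulate")
    genomes: dict[str, GenomeSequence] = {}
    reads: dict[str, list] = {}
    truths: dict[str, syn.GroundTruth] = {}
    domain_library = ann.default_domain_library()
    repeat_library_path = outdir / "repeat_library.fa"

    # ---- simulate ---------------------------------------------------------
    if sim_cfg is not None:
        rng = stage_rng(seed, "simulate")
        recipes = _species_recipes(sim_cfg, rng)
        all_families: dict[str, syn.RepeatFamily] = {}
        for sp, recipe in recipes.items():
            genome, truth = syn.plant_elements(recipe, rng, domain_library,
                                               seq_id=sp)
            genomes[sp] = genome
            truths[sp] = truth
            reads[sp] = syn.simulate_reads(genome, recipe, rng,
                                           id_prefix=f"{sp}_read")
            write_fasta([genome], outdir / f"{sp}.genome.fa")
            write_fastq_pair(reads[sp], outdir / f"{sp}.reads_1.fq",
                             outdir / f"{sp}.reads_2.fq")
            for fam in recipe.families:
                all_families.setdefault(fam.name, fam)
            _truth_table(truth).to_csv(outdir / f"{sp}.truth.tsv",
                                       sep="\t", index=False)
        lib_recipe = dataclasses.replace(
            next(iter(recipes.values())),
            families=list(all_families.values()))
        syn.write_repeat_library(lib_recipe, repeat_library_path)
        results["truth"] = truths
    else:
        for sp, path in (config.get("genomes") or {}).items():
            genomes[sp] = parse_sequences(path)[0]
        for sp, (p1, p2) in (config.get("reads") or {}).items():
            from .io_core import parse_read_pairs
            reads[sp] = parse_read_pairs(p1, p2)
        if config.get("library"):
            repeat_library_path = Path(config["library"])

    # ---- cluster ----------------------------------------------------------
    cl_cfg = config.get("cluster", {})
    if not reads:
        raise StageError("cluster: no reads available "
                         "(no simulate section and no reads files)")
    if not repeat_library_path.exists():
        raise StageError("cluster: repeat library not found")
    lib_entries = clu.load_repeat_library(repeat_library_path)
    cluster_tables: dict[str, pd.DataFrame] = {}
    read_counts: dict[str, tuple[int, int]] = {}
    for sp in sorted(reads):
        flat = []
        for p in reads[sp]:
            flat.append(GenomeSequence(f"{p.id}/1", p.mate1))
            flat.append(GenomeSequence(f"{p.id}/2", p.mate2))
        graph = clu.build_similarity_graph(
            flat,
            min_identity=float(cl_cfg.get("min_identity", 90.0)),
            min_overlap_fraction=float(cl_cfg.get("min_overlap_fraction", 0.55)),
            max_reads=int(cl_cfg.get("max_reads", 50_000)),
            subsample_seed=seed)
        clusters, singlets = clu.cluster_graph(graph)
        clu.build_superclusters(clusters,
                                int(cl_cfg.get("min_shared_pairs", 1)))
        reads_by_id = {r.id: r.seq for r in flat}
        clu.annotate_clusters(clusters, reads_by_id, lib_entries)
        table = pd.DataFrame([
            {"cluster": c.id, "size": c.size,
             "genome_proportion": round(c.genome_proportion, 4),
             "is_top": c.is_top, "annotation": c.annotation,
             "supercluster": c.supercluster}
            for c in clusters])
        table.to_csv(outdir / f"{sp}.clusters.tsv", sep="\t", index=False)
        cluster_tables[sp] = table
        read_counts[sp] = (len(flat), sum(c.size for c in clusters))
    results["clusters"] = cluster_tables
    results["read_counts"] = read_counts

    # ---- detect -----------------------------------------------------------
    det_cfg = config.get("detect", {})
    if not genomes:
        raise StageError("detect: no genome available "
                         "(no simulate section and no genomes files)")
    params = det.DetectionParams(
        min_ltr_identity=float(det_cfg.get("min_ltr_identity", 85.0)))
    candidates: dict[str, list] = {}
    for sp in sorted(genomes):
        cands = det.detect_elements(genomes[sp], params)
        candidates[sp] = cands
        write_annotations(cands, outdir / f"{sp}.candidates.gff3",
                          {sp: len(genomes[sp].seq)})
    results["candidates"] = candidates

    # ---- annotate ---------------------------------------------------------
    an_cfg = config.get("annotate", {})
    elements_by_species: dict[str, list] = {}
    for sp in sorted(candidates):
        elements = ann.annotate_elements(
            candidates[sp], genomes[sp], domain_library, species=sp,
            score_threshold=float(an_cfg.get("score_threshold", 80.0)))
        retained, removal_log = ann.filter_elements(
            elements, nested_policy=an_cfg.get("nested_policy", "keep_inner"))
        elements_by_species[sp] = retained
        write_annotations(retained, outdir / f"{sp}.elements.gff3")
        pd.DataFrame([{"seq_id": el.seq_id, "start": el.element[0],
                       "end": el.element[1], "reason": reason}
                      for el, reason in removal_log]).to_csv(
            outdir / f"{sp}.removed.tsv", sep="\t", index=False)
    counts = ann.count_table(elements_by_species)
    count_summary = ann.summarize_counts(counts)
    count_summary.to_csv(outdir / "element_counts.tsv", sep="\t", index=False)
    results["elements"] = elements_by_species
    results["element_counts"] = count_summary

    # ---- date -------------------------------------------------------------
    dt_cfg = config.get("date", {})
    dated_frames = []
    for sp in sorted(elements_by_species):
        dated = dat.date_elements(elements_by_species[sp], genomes[sp],
                                  rate=float(dt_cfg.get("rate", dat.DEFAULT_RATE)))
        dated_frames.append(dated)
    dated_all = pd.concat(dated_frames, ignore_index=True) if dated_frames \
        else pd.DataFrame()
    dated_all.to_csv(outdir / "element_ages.tsv", sep="\t", index=False)
    profiles = dat.age_profile(
        dated_all, bin_width_mya=float(dt_cfg.get("bin_width", 0.5)),
        max_mya=float(dt_cfg.get("max_mya", 15.0))) if len(dated_all) else []
    dat.profile_table(profiles).to_csv(outdir / "age_profiles.tsv",
                                       sep="\t", index=False)
    results["dated"] = dated_all
    results["profiles"] = profiles

    # ---- phylo ------------------------------------------------------------
    ph_cfg = config.get("phylo", {})
    rng_phy = stage_rng(seed, "phylo")
    rt_seqs = []
    for sp in sorted(elements_by_species):
        rt_seqs.extend(phy.extract_rt(elements_by_species[sp], genomes[sp]))
    results["rt_sequences"] = rt_seqs
    if len(rt_seqs) >= 3:
        alignment = phy.align_rt(rt_seqs)
        tree = phy.bootstrap_support(
            alignment, rng_phy, n_reps=int(ph_cfg.get("bootstrap", 25)))
        (outdir / "rt_tree.nwk").write_text(tree.newick() + "\n")
        phy.lineage_separation_report(tree).to_csv(
            outdir / "monophyly.tsv", sep="\t", index=False)
        results["tree"] = tree
    else:
        logger.warning("phylo: fewer than 3 RT sequences; stage skipped")
        results["tree"] = None

    # ---- summarize --------------------------------------------------------
    su_cfg = config.get("summarize", {})
    proportions = summ.genome_proportion_table(read_counts)
    proportions.to_csv(outdir / "genome_proportions.tsv", sep="\t")
    abundance = summ.lineage_abundance_matrix(cluster_tables)
    abundance.to_csv(outdir / "abundance_matrix.tsv", sep="\t")
    results["proportions"] = proportions
    results["abundance"] = abundance
    if abundance.shape[0] >= 2 and abundance.shape[1] >= 2:
        dendro = summ.hierarchical_cluster(
            abundance, axis=su_cfg.get("axis", "columns"),
            linkage=su_cfg.get("linkage", "average"),
            distance=su_cfg.get("distance", "euclidean"))
        (outdir / "abundance_dendrogram.nwk").write_text(dendro.newick() + "\n")
        results["dendrogram"] = dendro
        summ.sharing_report(
            abundance,
            presence_threshold=float(su_cfg.get("presence_threshold", 0.01))
        ).to_csv(outdir / "sharing.tsv", sep="\t")
    return results


def _truth_table(truth: syn.GroundTruth) -> pd.DataFrame:
    rows = []
    for e in truth.elements:
        rows.append({
            "id": e.id, "seq_id": e.seq_id, "start": e.start, "end": e.end,
            "family": e.family, "superfamily": e.superfamily,
            "lineage": e.lineage, "age_mya": round(e.age_mya, 4),
            "divergence": round(e.divergence, 5),
            "tsd_intact": e.tsd_intact, "motif_intact": e.motif_intact,
            "parent": e.parent or "", "strand": e.strand,
        })
    for t in truth.tandems:
        rows.append({"id": t.id, "seq_id": t.seq_id, "start": t.start,
                     "end": t.end, "family": t.name, "superfamily": t.kind,
                     "lineage": "", "age_mya": "", "divergence": "",
                     "tsd_intact": "", "motif_intact": "", "parent": "",
                     "strand": ""})
    return pd.DataFrame(rows)
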