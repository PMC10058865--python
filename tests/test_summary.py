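import numpy as np
import pandas as pd
import pytest

from repeatome import summary as summ
from repeatome.io_core import RepeatomeError
from repeatome.survey_tables import (SPECIES, load_ltr_proportions,
                                     load_read_clustering)


def test_genome_proportion_table_reproduces_survey():
    reads = load_read_clustering()
    table = summ.genome_proportion_table(
        {sp: (int(r["total_reads"]), int(r["clustered_reads"]))
         for sp, r in reads.iterrows()})
    for sp in SPECIES:
        assert table.loc[sp, "genome_proportion_pct"] == pytest.approx(
            reads.loc[sp, "genome_proportion_pct"])
    assert table.loc["Helianthus annuus", "genome_proportion_pct"] == 78.44
    assert table.loc["Cynara cardunculus", "genome_proportion_pct"] == 60.44


def test_zero_total_reads_rejected():
    with pytest.raises(RepeatomeError):
        summ.genome_proportion_table({"x": (0, 0)})


def _superfamily_totals():
    props = load_ltr_proportions()
    totals = props[props["lineage"] == "Total"].set_index("superfamily")
    return totals[list(SPECIES)]


def test_gypsy_copia_ratios_reproduce_survey():
    ratios = summ.gypsy_copia_ratio(_superfamily_totals())
    assert ratios["Helianthus annuus"] == 6.47
    assert ratios["Chrysanthemum seticuspe"] == 0.35
    assert ratios["Lactuca sativa"] == 0.63
    assert ratios["Cynara cardunculus"] == 0.45
    assert ratios["Artemisia annua"] == 1.01


def test_zero_copia_ratio_is_na():
    m = pd.DataFrame({"sp": [1.0, 0.0]}, index=["Gypsy", "Copia"])
    assert np.isnan(summ.gypsy_copia_ratio(m)["sp"])


def test_equal_totals_give_unit_ratio():
    m = pd.DataFrame({"sp": [3.3, 3.3]}, index=["Gypsy", "Copia"])
    assert summ.gypsy_copia_ratio(m)["sp"] == 1.00


def test_max_difference_reproduces_survey_column():
    """Every printed max-difference value is recomputed from the printed
    species cells within rounding (0.01)."""
    props = load_ltr_proportions()
    recomputed = summ.max_difference(props[list(SPECIES)])
    for i, row in props.iterrows():
        assert abs(recomputed[i] - row["max_difference"]) <= 0.01 + 1e-9
    # headline values match exactly
    totals = props[props["lineage"] == "Total"].set_index("superfamily")
    md = summ.max_difference(totals[list(SPECIES)])
    assert md["Copia"] == 28.93
    assert md["Gypsy"] == 30.50
    sire = props[props["lineage"] == "SIRE"][list(SPECIES)]
    assert summ.max_difference(sire).iloc[0] == 26.03


def test_constant_row_has_zero_difference():
    m = pd.DataFrame({"a": [2.0], "b": [2.0], "c": [2.0]}, index=["row"])
    assert summ.max_difference(m)["row"] == 0.00


def test_identical_rows_merge_first_at_height_zero():
    m = pd.DataFrame({"s1": [1.0, 1.0, 9.0], "s2": [2.0, 2.0, 0.0]},
                     index=["a", "b", "c"])
    dendro = summ.hierarchical_cluster(m)
    first_a, first_b, height = dendro.merge_order()[0]
    assert first_a | first_b == {"a", "b"}
    assert height == 0.0


def test_average_linkage_merge_order_matches_hand_calculation():
    """4x2 matrix with hand-computable average-linkage Euclidean merges:
    d(a,b)=1, d(c,d)=1, then avg inter-group distance 5.077."""
    m = pd.DataFrame({"x": [0.0, 0.0, 5.0, 5.0], "y": [0.0, 1.0, 0.0, 1.0]},
                     index=["a", "b", "c", "d"])
    merges = summ.hierarchical_cluster(m).merge_order()
    assert merges[0][2] == pytest.approx(1.0)
    assert merges[1][2] == pytest.approx(1.0)
    expected = (5.0 + np.sqrt(26) + np.sqrt(26) + 5.0) / 4
    assert merges[2][2] == pytest.approx(expected)
    assert merges[2][0] | merges[2][1] == {"a", "b", "c", "d"}


def test_dendrogram_heights_non_decreasing():
    rng = np.random.default_rng(4)
    m = pd.DataFrame(rng.uniform(0, 10, size=(8, 3)),
                     index=[f"r{i}" for i in range(8)])
    dendro = summ.hierarchical_cluster(m)
    heights = dendro.merge_heights()
    assert (np.diff(heights) >= -1e-12).all()


def test_species_sharing_repeats_merge_first():
    """Two species with correlated repeat profiles (same tribe) join before
    the others in the column dendrogram."""
    rng = np.random.default_rng(11)
    base = rng.uniform(0, 10, size=12)
    m = pd.DataFrame({
        "ART": base + rng.normal(0, 0.3, 12),
        "CHR": base + rng.normal(0, 0.3, 12),
        "HEL": rng.uniform(0, 10, 12),
        "LAC": rng.uniform(0, 10, 12),
    }, index=[f"cl{i}" for i in range(12)])
    dendro = summ.hierarchical_cluster(m, axis="columns")
    first_a, first_b, _ = dendro.merge_order()[0]
    assert first_a | first_b == {"ART", "CHR"}


def test_dendrogram_newick_is_well_formed():
    m = pd.DataFrame({"a": [0.0, 1.0, 8.0], "b": [0.5, 1.5, 9.0]},
                     index=["r1", "r2", "r3"])
    nwk = summ.hierarchical_cluster(m).newick()
    import dendropy
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert sorted(t.taxon.label for t in tree.leaf_node_iter()) == \
        ["r1", "r2", "r3"]


def test_sharing_report_partitions_rows():
    m = pd.DataFrame({
        "s1": [1.0, 1.0, 0.0], "s2": [0.5, 0.0, 0.0], "s3": [2.0, 0.0, 0.2]},
        index=["rdna", "specific", "pair"])
    report = summ.sharing_report(m, presence_threshold=0.1)
    assert report.loc["rdna", "label"] == "shared-by-all"
    assert report.loc["specific", "label"] == "species-specific"
    assert report.loc["pair", "label"] == "species-specific"
    assert len(report) == len(m)


def test_planted_rdna_shared_by_all_species():
    rng = np.random.default_rng(2)
    data = {f"sp{i}": rng.uniform(0, 5, 6) for i in range(5)}
    m = pd.DataFrame(data, index=[f"c{i}" for i in range(5)] + ["rDNA"])
    m.loc["rDNA"] = [0.9, 1.1, 0.8, 1.0, 0.95]
    report = summ.sharing_report(m)
    assert report.loc["rDNA", "label"] == "shared-by-all"
    assert report.loc["rDNA", "n_species"] == 5
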