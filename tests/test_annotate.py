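import numpy as np
import pytest

from repeatome import annotate as ann
from repeatome import synthetic as syn
from repeatome.detect import LtrCandidate
from repeatome.io_core import GenomeSequence, ParseError
from repeatome.survey_tables import SPECIES, load_element_counts


def _element_on_genome(rng, library, superfamily, lineage, order=None,
                       minus=False, ltr_len=300, internal_len=2600):
    spec = syn.ElementSpec(superfamily, lineage, ltr_len=ltr_len,
                           internal_len=internal_len, domain_order=order)
    consensus = syn.build_consensus(spec, rng, library)
    seq, realized = syn.mutate_copy(consensus, spec, 0.0, 2e-8, 2.0, rng,
                                    minus_strand=minus)
    flank = syn.random_dna(500, rng)
    genome = GenomeSequence("g", flank + seq + flank)
    L = spec.ltr_len
    cand = LtrCandidate("g", (500, 500 + L),
                        (500 + len(seq) - L, 500 + len(seq)), 100.0,
                        tsd="ACGTA", motif_ok=True)
    return genome, cand, spec


def test_planted_domains_found_in_order(rng, library):
    genome, cand, spec = _element_on_genome(rng, library, "Copia", "SIRE")
    hits = ann.detect_domains(cand, genome, library)
    assert [h.domain for h in hits] == ["GAG", "PR", "INT", "RT", "RH"]
    assert all(h.strand == "+" for h in hits)
    assert all(h.lineage == "SIRE" for h in hits)
    istart, iend = cand.ltr5[1], cand.ltr3[0]
    assert all(istart <= h.start < h.end <= iend for h in hits)


def test_random_internal_region_yields_no_hits(rng, library):
    cand = LtrCandidate("g", (0, 300), (3000, 3300), 100.0)
    genome = GenomeSequence("g", syn.random_dna(3300, rng))
    assert ann.detect_domains(cand, genome, library) == []


def test_minus_strand_element_detected_with_minus_strand(rng, library):
    genome, cand, spec = _element_on_genome(rng, library, "Gypsy", "Athila",
                                            minus=True)
    el = ann.FullLengthElement.from_candidate(cand)
    el.domains = ann.detect_domains(el, genome, library)
    assert len(el.domains) == 5
    assert all(h.strand == "-" for h in el.domains)
    el = ann.classify_element(el)
    assert el.strand == "-"
    assert el.superfamily == "Gypsy"
    assert el.lineage == "Athila"


def _hit(domain, start, score=100.0, lineage="SIRE", superfamily="Copia",
         frame=0):
    return ann.DomainHit(domain, start, start + 300, frame, score,
                         f"{superfamily}_{lineage}_{domain}", lineage,
                         superfamily)


def _bare_element(domains):
    el = ann.FullLengthElement("g", (0, 300), (5000, 5300), 100.0)
    el.domains = domains
    return el


@pytest.mark.parametrize("order,expected", [
    (("GAG", "PR", "INT", "RT", "RH"), "Copia"),
    (("GAG", "PR", "RT", "RH", "INT"), "Gypsy"),
    (("GAG", "RT"), "unclassified"),
])
def test_int_position_rule(order, expected):
    hits = [_hit(d, 400 + 400 * i) for i, d in enumerate(order)]
    el = ann.classify_element(_bare_element(hits))
    assert el.superfamily == expected
    assert el.lineage == "SIRE"  # from the RT hit in every case


def test_no_rt_means_unclassified_lineage():
    el = ann.classify_element(_bare_element([_hit("GAG", 400)]))
    assert el.lineage == "unclassified"


def test_nested_pair_outer_removed_inner_retained():
    outer = ann.FullLengthElement("g", (0, 300), (9700, 10_000), 95.0)
    outer.domains = [_hit(d, 400 + 400 * i)
                     for i, d in enumerate(("GAG", "PR", "INT", "RT", "RH"))]
    inner = ann.FullLengthElement("g", (3000, 3300), (5700, 6000), 99.0)
    inner.domains = [_hit(d, 3400 + 400 * i)
                     for i, d in enumerate(("GAG", "PR", "INT", "RT", "RH"))]
    for el in (outer, inner):
        ann.classify_element(el)
    retained, log = ann.filter_elements([outer, inner])
    assert retained == [inner]
    assert outer.status == "removed_nested"
    # keep_outer flips the verdict
    outer.status = inner.status = "retained"
    retained, _ = ann.filter_elements([outer, inner],
                                      nested_policy="keep_outer")
    assert retained == [outer]


def test_duplicate_rt_removed():
    hits = [_hit("GAG", 400), _hit("PR", 800), _hit("INT", 1200),
            _hit("RT", 1600), _hit("RT", 2000), _hit("RH", 2400)]
    el = ann.classify_element(_bare_element(hits))
    retained, log = ann.filter_elements([el])
    assert retained == []
    assert el.status == "removed_domain_order"


def test_order_violation_against_domain_evidence_removed():
    # Copia-labeled domains in a layout neither superfamily allows
    hits = [_hit(d, 400 + 400 * i)
            for i, d in enumerate(("GAG", "PR", "RT", "INT", "RH"))]
    el = ann.classify_element(_bare_element(hits))
    assert el.superfamily == "unclassified"
    retained, _ = ann.filter_elements([el])
    assert retained == []


def test_partial_domain_set_retained_as_unclassified():
    el = ann.classify_element(_bare_element([_hit("GAG", 400),
                                             _hit("RT", 1600)]))
    retained, _ = ann.filter_elements([el])
    assert retained == [el]
    assert el.superfamily == "unclassified"


def test_filter_is_idempotent():
    clean = ann.classify_element(_bare_element(
        [_hit(d, 400 + 400 * i)
         for i, d in enumerate(("GAG", "PR", "INT", "RT", "RH"))]))
    retained, log = ann.filter_elements([clean])
    assert retained == [clean] and log == []
    retained2, log2 = ann.filter_elements(retained)
    assert retained2 == retained and log2 == []


def test_count_table_consistency(rng):
    els = {}
    for sp, spec in (("spA", [("Copia", "SIRE")] * 3 + [("Gypsy", "Tat")] * 2),
                     ("spB", [("Copia", "SIRE")] * 1)):
        rows = []
        for sf, lin in spec:
            el = ann.FullLengthElement("g", (0, 300), (5000, 5300), 99.0,
                                       species=sp, superfamily=sf, lineage=lin)
            el.domains = [_hit("RT", 400, lineage=lin, superfamily=sf)]
            rows.append(el)
        els[sp] = rows
    table = ann.count_table(els)
    summary = ann.summarize_counts(table)
    get = lambda lin, sp: int(summary.loc[summary["lineage"] == lin, sp].iloc[0])
    assert get("SIRE", "spA") == 3 and get("SIRE", "spB") == 1
    assert get("Copia total", "spA") == 3
    assert get("Gypsy total", "spA") == 2
    assert get("TOTAL", "spA") == 5
    assert ann.superfamily_share(summary, "Gypsy", "spA") == 40.0


def test_survey_counts_totals_and_shares():
    """Recomputing the published count table's totals from its lineage rows."""
    counts = load_element_counts()
    hel = "Helianthus annuus"
    copia = int(counts.loc[counts["superfamily"] == "Copia", hel].sum())
    gypsy = int(counts.loc[counts["superfamily"] == "Gypsy", hel].sum())
    total = int(counts[hel].sum())
    assert copia == 7643
    assert total == 34_580
    assert round(100.0 * gypsy / total, 1) == 77.5
    grand = sum(int(counts[sp].sum()) for sp in SPECIES)
    assert grand == 48_872


def test_empty_input_gives_empty_table():
    table = ann.count_table({"spA": []})
    summary = ann.summarize_counts(table)
    assert int(summary.loc[summary["lineage"] == "TOTAL", "spA"].iloc[0]) == 0


def test_library_label_validation(tmp_path):
    p = tmp_path / "lib.fa"
    p.write_text(">x domain=RT superfamily=Copia lineage=NotALineage\nMKV\n")
    with pytest.raises(ParseError, match="lineage"):
        ann.ReferenceDomainLibrary.from_fasta(p)
    p.write_text(">x superfamily=Copia lineage=SIRE\nMKV\n")
    with pytest.raises(ParseError, match="domain"):
        ann.ReferenceDomainLibrary.from_fasta(p)


def test_library_round_trip(tmp_path, library):
    p = tmp_path / "lib.fa"
    library.to_fasta(p)
    back = ann.ReferenceDomainLibrary.from_fasta(p)
    assert len(back) == len(library)
    assert back.peptides[0] == library.peptides[0]
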