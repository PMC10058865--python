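"""Synthetic genomes with planted LTR retrotransposons and known ground truth.

The generator emulates the statistical structure a repeatome analysis
assumes: a random background at plant-like GC, full-length LTR-REs of chosen
superfamily/lineage composition whose two LTRs are identical at insertion
and diverge with age under a Kimura two-parameter substitution process
(per-site substitution count Poisson(r*T) per LTR, transitions favored by
kappa, multiple hits allowed so the K2P correction is actually exercised),
5-bp target-site duplications, optional nested insertions, tandem satellite
and rDNA arrays, decayed (old, high-divergence) copies, and 100-bp
inward-facing paired-end reads.

Every planted feature is recorded in a ground-truth registry (coordinates,
age, realized divergence, nesting), which downstream tests use as the oracle
for detector recall, filter correctness, and age recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .io_core import GenomeSequence, ReadPair, RepeatomeError, reverse_complement
from .annotate import (CANONICAL_ORDER, CHROMOVIRUS_LINEAGES,
                       ReferenceDomainLibrary, default_domain_library)
from .dating import count_substitutions, k2p_from_counts

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
# K2P exchange targets: index 0 = transition partner, 1-2 = transversions
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

MIN_LTR_LEN, MAX_LTR_LEN = 100, 10_000
MIN_ELEMENT_LEN, MAX_ELEMENT_LEN = 1_500, 25_000

_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CodonTable.standard_dna_table.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeDistribution:
    """Insertion-age distribution in MYA: point mass or Gaussian mixture."""

    components: tuple[tuple[float, float, float], ...]  # (weight, mean, sd)

    @classmethod
    def point(cls, mya: float) -> "AgeDistribution":
        return cls(((1.0, mya, 0.0),))

    @classmethod
    def gaussian(cls, mean_mya: float, sd_mya: float) -> "AgeDistribution":
        return cls(((1.0, mean_mya, sd_mya),))

    @classmethod
    def mixture(cls, *components: tuple[float, float, float]) -> "AgeDistribution":
        total = sum(w for w, _, _ in components)
        return cls(tuple((w / total, m, s) for w, m, s in components))

    def draw_years(self, rng: np.random.Generator) -> float:
        weights = [w for w, _, _ in self.components]
        i = rng.choice(len(self.components), p=weights)
        _, mean, sd = self.components[i]
        mya = rng.normal(mean, sd) if sd > 0 else mean
        return max(mya, 0.0) * 1e6


@dataclass(frozen=True)
class ElementSpec:
    """Blueprint for one full-length LTR-RE."""

    superfamily: str
    lineage: str
    ltr_len: int
    internal_len: int
    age_T: float = 0.0          # years
    tsd_len: int = 5
    motif: str = "tgca"
    domain_order: tuple[str, ...] | None = None  # None -> canonical order

    def __post_init__(self):
        if not (MIN_LTR_LEN <= self.ltr_len <= MAX_LTR_LEN):
            raise RepeatomeError(
                f"ltr_len {self.ltr_len} outside [{MIN_LTR_LEN}, {MAX_LTR_LEN}]")
        total = 2 * self.ltr_len + self.internal_len
        if not (MIN_ELEMENT_LEN <= total <= MAX_ELEMENT_LEN):
            raise RepeatomeError(
                f"element length {total} outside "
                f"[{MIN_ELEMENT_LEN}, {MAX_ELEMENT_LEN}]")
        if self.age_T < 0:
            raise RepeatomeError("age_T must be >= 0")

    @property
    def total_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len

    def resolved_order(self) -> tuple[str, ...]:
        if self.domain_order is not None:
            return tuple(self.domain_order)
        if self.superfamily == "Gypsy" and self.lineage in CHROMOVIRUS_LINEAGES:
            return CANONICAL_ORDER["Gypsy"]
        if self.superfamily == "Gypsy":
            return CANONICAL_ORDER["Gypsy"][:5]
        return CANONICAL_ORDER["Copia"]


@dataclass
class RepeatFamily:
    """A family: one consensus element, several age-diverged copies."""

    name: str
    spec: ElementSpec
    copy_number: int
    ages: AgeDistribution
    consensus: str | None = None
    minus_strand_fraction: float = 0.0

    def __post_init__(self):
        if self.copy_number < 0:
            raise RepeatomeError("copy_number must be >= 0")


@dataclass
class TandemSpec:
    """Tandem satellite or rDNA tract: monomer repeated n_copies times."""

    name: str
    kind: str                   # "satellite" | "rDNA"
    monomer_len: int
    n_copies: int
    monomer: str | None = None


@dataclass
class SimRecipe:
    """All knobs of one synthetic genome + read set."""

    genome_length: int
    families: list[RepeatFamily] = field(default_factory=list)
    tandems: list[TandemSpec] = field(default_factory=list)
    nesting_probability: float = 0.0
    gc: float = 0.38
    coverage: float = 5.0
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    read_error_rate: float = 0.0
    kappa: float = 2.0          # transition:transversion rate ratio
    rate: float = 2e-8          # substitutions / site / year
    mutate_tsd: bool = True
    preserve_motif: bool = False

    def __post_init__(self):
        if self.coverage <= 0:
            raise RepeatomeError("coverage must be > 0")
        if self.kappa <= 0:
            raise RepeatomeError("kappa must be > 0")
        if not (0 <= self.gc <= 1):
            raise RepeatomeError("gc must be in [0, 1]")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedElement:
    id: str
    seq_id: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    family: str
    superfamily: str
    lineage: str
    domain_order: tuple[str, ...]
    age_years: float
    divergence: float           # realized inter-LTR p-distance
    k2p: float                  # realized inter-LTR K2P distance
    transitions: int
    transversions: int
    tsd: str | None = None
    tsd_intact: bool = False
    motif_intact: bool = False
    parent: str | None = None
    interrupted: bool = False
    strand: str = "+"

    @property
    def element(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def age_mya(self) -> float:
        return self.age_years / 1e6


@dataclass
class PlantedTandem:
    id: str
    seq_id: str
    start: int
    end: int
    kind: str
    name: str


@dataclass
class GroundTruth:
    seq_id: str
    genome_length: int
    elements: list[PlantedElement] = field(default_factory=list)
    tandems: list[PlantedTandem] = field(default_factory=list)

    @property
    def repeat_fraction(self) -> float:
        # top-level element spans already contain any nested children's bp
        bp = sum(e.end - e.start for e in self.elements if e.parent is None)
        bp += sum(t.end - t.start for t in self.tandems)
        return bp / self.genome_length

    def copy_numbers(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.elements:
            out[e.family] = out.get(e.family, 0) + 1
        return out


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def random_dna(length: int, rng: np.random.Generator, gc: float = 0.38) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def mutate_k2p(seq: str, lam: float, kappa: float,
               rng: np.random.Generator,
               protect: Sequence[int] = ()) -> str:
    """Apply a K2P substitution process with per-site expected count ``lam``.

    The number of hits per site is Poisson(lam); each hit is a transition
    with probability kappa/(kappa+2), else one of the two transversions.
    Multiple hits at a site are applied sequentially, so back-mutations and
    saturation occur naturally.  ``protect`` positions are never mutated.
    """
    if lam < 0:
        raise ValueError("expected substitution count must be >= 0")
    if lam == 0 or not seq:
        return seq
    counts = rng.poisson(lam, size=len(seq))
    for pos in protect:
        counts[pos] = 0
    bases = list(seq)
    p_ts = kappa / (kappa + 2.0)
    hit_sites = np.nonzero(counts)[0]
    for pos in hit_sites:
        base = bases[pos]
        if base not in _TRANSITION:      # N never mutates
            continue
        for _ in range(counts[pos]):
            if rng.random() < p_ts:
                base = _TRANSITION[base]
            else:
                base = _TRANSVERSIONS[base][rng.integers(2)]
        bases[pos] = base
    return "".join(bases)


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """DNA encoding ``peptide`` with codons drawn uniformly per residue."""
    codons = []
    for aa in peptide:
        options = _CODONS.get(aa)
        if options is None:
            raise RepeatomeError(f"cannot encode residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def build_consensus(spec: ElementSpec, rng: np.random.Generator,
                    library: ReferenceDomainLibrary | None = None,
                    gc: float = 0.38) -> str:
    """LTR-internal-LTR consensus with identical LTRs (age zero).

    The LTR starts TG and ends CA; the internal region carries the spec's
    domain peptides (drawn from the reference library) as ordered ORF blocks
    separated by random spacers.
    """
    library = library or default_domain_library()
    m5 = spec.motif[:2].upper()
    m3 = spec.motif[2:].upper()
    ltr = m5 + random_dna(spec.ltr_len - 4, rng, gc) + m3
    orfs = []
    for domain in spec.resolved_order():
        pep = library.get(domain, spec.superfamily, spec.lineage)
        orfs.append(reverse_translate(pep.seq, rng))
    coding = sum(map(len, orfs))
    n_gaps = len(orfs) + 1
    spare = spec.internal_len - coding
    if spare < n_gaps:
        raise RepeatomeError(
            f"internal_len {spec.internal_len} too small for "
            f"{len(orfs)} domain ORFs ({coding} bp)")
    gap_sizes = [spare // n_gaps] * n_gaps
    gap_sizes[-1] += spare - sum(gap_sizes)
    parts = []
    for orf, gap in zip(orfs, gap_sizes[:-1]):
        parts.append(random_dna(gap, rng, gc))
        parts.append(orf)
    parts.append(random_dna(gap_sizes[-1], rng, gc))
    internal = "".join(parts)
    assert len(internal) == spec.internal_len
    return ltr + internal + ltr


def mutate_copy(consensus: str, spec: ElementSpec, age_years: float,
                rate: float, kappa: float, rng: np.random.Generator,
                preserve_motif: bool = False,
                minus_strand: bool = False):
    """Age one copy of a family consensus.

    Each LTR receives an independent K2P process with per-site expectation
    ``rate * age_years`` (so the expected inter-LTR divergence is ~2 r T) and
    the internal region is mutated at the same rate.  Returns the mutated
    element plus realized truth counts.
    """
    L = spec.ltr_len
    lam = rate * age_years
    protect = (0, 1, L - 2, L - 1) if preserve_motif else ()
    ltr5 = mutate_k2p(consensus[:L], lam, kappa, rng, protect)
    ltr3 = mutate_k2p(consensus[:L], lam, kappa, rng, protect)
    internal = mutate_k2p(consensus[L:L + spec.internal_len], lam, kappa, rng)
    seq = ltr5 + internal + ltr3
    n, ts, tv = count_substitutions(ltr5, ltr3)
    dist = k2p_from_counts(n, ts, tv, clamp=1e-9)
    motif = (ltr5.startswith(spec.motif[:2].upper())
             and ltr3.endswith(spec.motif[2:].upper()))
    strand = "-"
    if minus_strand:
        seq = reverse_complement(seq)
        # direct-repeat structure and TG..CA termini are strand-symmetric
    else:
        strand = "+"
    realized = {
        "divergence": (ts + tv) / n if n else 0.0,
        "k2p": dist.K,
        "transitions": ts,
        "transversions": tv,
        "motif_intact": motif,
        "strand": strand,
    }
    return seq, realized


def make_element(spec: ElementSpec, rng: np.random.Generator,
                 library: ReferenceDomainLibrary | None = None,
                 rate: float = 2e-8, kappa: float = 2.0,
                 preserve_motif: bool = False):
    """Build one element from scratch and age it by ``spec.age_T`` years."""
    consensus = build_consensus(spec, rng, library)
    return mutate_copy(consensus, spec, spec.age_T, rate, kappa, rng,
                       preserve_motif=preserve_motif)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

_PLACEMENT_MARGIN = 12
_MAX_PLACEMENT_TRIES = 500


def plant_elements(recipe: SimRecipe, rng: np.random.Generator,
                   library: ReferenceDomainLibrary | None = None,
                   seq_id: str = "genome") -> tuple[GenomeSequence, GroundTruth]:
    """Assemble a genome: background + planted elements/tandems + TSDs.

    Elements are inserted at uniform-random positions outside existing
    features; with probability ``nesting_probability`` an element is instead
    inserted inside a previously placed element's internal region (recorded
    as a parent-child pair; the parent is marked interrupted).  Each element
    insertion duplicates the 5-bp target site on both flanks; TSD copies are
    then mutated according to the element's age unless ``mutate_tsd`` is off.
    """
    library = library or default_domain_library()
    genome = random_dna(recipe.genome_length, rng, recipe.gc)
    truth = GroundTruth(seq_id=seq_id, genome_length=recipe.genome_length)

    # realize all insertions first, then plant in shuffled order
    jobs: list[tuple[str, object]] = []
    for fam in recipe.families:
        if fam.consensus is None:
            fam.consensus = build_consensus(fam.spec, rng, library, recipe.gc)
        for c in range(fam.copy_number):
            age = fam.ages.draw_years(rng)
            minus = rng.random() < fam.minus_strand_fraction
            seq, realized = mutate_copy(
                fam.consensus, fam.spec, age, recipe.rate, recipe.kappa, rng,
                preserve_motif=recipe.preserve_motif, minus_strand=minus)
            jobs.append(("element", (fam, age, seq, realized)))
    for tan in recipe.tandems:
        if tan.monomer is None:
            tan.monomer = random_dna(tan.monomer_len, rng, recipe.gc)
        jobs.append(("tandem", tan))
    total_planted = 0
    for kind, payload in jobs:
        if kind == "element":
            _, _, eseq, _ = payload
            total_planted += len(eseq)
        else:
            total_planted += len(payload.monomer) * payload.n_copies
    if total_planted > recipe.genome_length * 4:
        raise RepeatomeError("planted length vastly exceeds genome length")
    order = rng.permutation(len(jobs))

    def _occupied(pos: int) -> bool:
        for e in truth.elements:
            if e.start - _PLACEMENT_MARGIN < pos < e.end + _PLACEMENT_MARGIN:
                return True
        for t in truth.tandems:
            if t.start - _PLACEMENT_MARGIN < pos < t.end + _PLACEMENT_MARGIN:
                return True
        return False

    def _shift(threshold: int, added: int) -> None:
        for e in truth.elements:
            if e.start > threshold:
                e.start += added
                e.end += added
                e.ltr5 = (e.ltr5[0] + added, e.ltr5[1] + added)
                e.ltr3 = (e.ltr3[0] + added, e.ltr3[1] + added)
            elif e.end > threshold:    # insertion landed inside e
                e.end += added
                e.ltr3 = (e.ltr3[0] + added, e.ltr3[1] + added)
                e.interrupted = True
        for t in truth.tandems:
            if t.start > threshold:
                t.start += added
                t.end += added

    n_el = 0
    for k in order:
        kind, payload = jobs[k]
        if kind == "tandem":
            tan = payload
            array = tan.monomer * tan.n_copies
            pos = _place_background(genome, rng, _occupied)
            genome = genome[:pos] + array + genome[pos:]
            _shift(pos, len(array))
            truth.tandems.append(PlantedTandem(
                id=f"{tan.kind}_{tan.name}", seq_id=seq_id,
                start=pos, end=pos + len(array), kind=tan.kind, name=tan.name))
            continue

        fam, age, eseq, realized = payload
        t = fam.spec.tsd_len
        parent = None
        if truth.elements and rng.random() < recipe.nesting_probability:
            hosts = [e for e in truth.elements
                     if e.ltr3[0] - e.ltr5[1] > 2 * _PLACEMENT_MARGIN + t]
            if hosts:
                parent = hosts[rng.integers(len(hosts))]
        if parent is not None:
            lo = parent.ltr5[1] + _PLACEMENT_MARGIN
            hi = parent.ltr3[0] - _PLACEMENT_MARGIN - t
            pos = int(rng.integers(lo, hi))
        else:
            pos = _place_background(genome, rng, _occupied, margin=t)
        tsd_src = genome[pos:pos + t]
        lam = recipe.rate * age if recipe.mutate_tsd else 0.0
        tsd_left = mutate_k2p(tsd_src, lam, recipe.kappa, rng)
        tsd_right = mutate_k2p(tsd_src, lam, recipe.kappa, rng)
        genome = genome[:pos] + tsd_left + eseq + tsd_right + genome[pos + t:]
        added = len(eseq) + t
        _shift(pos, added)
        n_el += 1
        L = fam.spec.ltr_len
        start = pos + t
        truth.elements.append(PlantedElement(
            id=f"el_{n_el}", seq_id=seq_id,
            start=start, end=start + len(eseq),
            ltr5=(start, start + L),
            ltr3=(start + len(eseq) - L, start + len(eseq)),
            family=fam.name, superfamily=fam.spec.superfamily,
            lineage=fam.spec.lineage,
            domain_order=fam.spec.resolved_order(),
            age_years=age,
            divergence=realized["divergence"], k2p=realized["k2p"],
            transitions=realized["transitions"],
            transversions=realized["transversions"],
            tsd=tsd_src, tsd_intact=(tsd_left == tsd_right),
            motif_intact=realized["motif_intact"],
            parent=parent.id if parent is not None else None,
            strand=realized["strand"]))

    truth.genome_length = len(genome)
    return GenomeSequence(seq_id, genome), truth


def _place_background(genome: str, rng: np.random.Generator, occupied,
                      margin: int = 5) -> int:
    for _ in range(_MAX_PLACEMENT_TRIES):
        pos = int(rng.integers(margin, len(genome) - margin))
        if not occupied(pos):
            return pos
    raise RepeatomeError(
        "infeasible packing: could not place a feature after "
        f"{_MAX_PLACEMENT_TRIES} tries")


def scale_to_fraction(recipe: SimRecipe, target_fraction: float) -> SimRecipe:
    """Scale copy numbers so the planted fraction of the final genome is
    approximately ``target_fraction``."""
    if not (0 < target_fraction < 1):
        raise ValueError("target_fraction must be in (0, 1)")
    per_family = [(f.spec.total_len + f.spec.tsd_len) * f.copy_number
                  for f in recipe.families]
    tandem_bp = sum((t.monomer_len * t.n_copies) for t in recipe.tandems)
    current = sum(per_family) + tandem_bp
    if current == 0:
        raise RepeatomeError("recipe plants nothing; cannot scale")
    needed = target_fraction * recipe.genome_length / (1 - target_fraction)
    factor = max(needed - tandem_bp, 0) / max(sum(per_family), 1)
    families = [replace(f, copy_number=max(int(round(f.copy_number * factor)), 0),
                        consensus=f.consensus)
                for f in recipe.families]
    return replace(recipe, families=families)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(genome: GenomeSequence, recipe: SimRecipe,
                   rng: np.random.Generator,
                   id_prefix: str = "read") -> list[ReadPair]:
    """Uniform fragment sampling; inward-facing ``read_len``-bp mates.

    Expected pair count is coverage * genome_length / (2 * read_len); mates
    share ids.  With ``read_error_rate`` 0 every read is an exact substring
    of the genome or its reverse complement.
    """
    if recipe.coverage <= 0:
        raise RepeatomeError("coverage must be > 0")
    L = len(genome.seq)
    if L < recipe.insert_mean:
        raise RepeatomeError("genome shorter than the mean insert size")
    n_pairs = int(round(recipe.coverage * L / (2 * recipe.read_len)))
    pairs = []
    seq = genome.seq
    for i in range(n_pairs):
        insert = int(round(rng.normal(recipe.insert_mean, recipe.insert_sd)))
        insert = max(insert, 2 * recipe.read_len)
        insert = min(insert, L)
        start = int(rng.integers(0, L - insert + 1))
        frag = seq[start:start + insert]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        m1 = frag[:recipe.read_len]
        m2 = reverse_complement(frag[-recipe.read_len:])
        if recipe.read_error_rate > 0:
            m1 = _sequencing_errors(m1, recipe.read_error_rate, rng)
            m2 = _sequencing_errors(m2, recipe.read_error_rate, rng)
        pairs.append(ReadPair(f"{id_prefix}_{i:07d}", m1, m2))
    return pairs


def _sequencing_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    bases = list(read)
    hits = np.nonzero(rng.random(len(bases)) < rate)[0]
    for pos in hits:
        old = bases[pos]
        choices = [b for b in "ACGT" if b != old]
        bases[pos] = choices[rng.integers(3)]
    return "".join(bases)


# ---------------------------------------------------------------------------
# auxiliary generators for comparative / phylogenetic tests
# ---------------------------------------------------------------------------

def simulate_rt_sequences(lineages: Sequence[tuple[str, str]],
                          n_per_lineage: int,
                          rng: np.random.Generator,
                          species: Sequence[str] = ("spA",),
                          length: int = 600,
                          ancestor_sub: float = 0.25,
                          within_sub: float = 0.02,
                          kappa: float = 2.0) -> list[GenomeSequence]:
    """RT nucleotide cohorts with inter-lineage >> intra-lineage divergence.

    One root sequence; each lineage's ancestor diverges from it by
    ``ancestor_sub`` expected substitutions/site, and each member by a
    further ``within_sub``.  Ids follow ``species|lineage|index`` with
    species labels assigned round-robin within each lineage.
    """
    root = random_dna(length, rng, 0.5)
    out = []
    for superfamily, lineage in lineages:
        ancestor = mutate_k2p(root, ancestor_sub, kappa, rng)
        for i in range(n_per_lineage):
            sp = species[i % len(species)]
            seq = mutate_k2p(ancestor, within_sub, kappa, rng)
            out.append(GenomeSequence(f"{sp}|{lineage}|{i}", seq))
    return out


def write_repeat_library(recipe: SimRecipe, path: str | Path) -> None:
    """Emit the recipe's family consensus + tandem monomers as an annotation
    library FASTA with ``#class/superfamily/lineage`` header tags."""
    with Path(path).open("w") as fh:
        for fam in recipe.families:
            if fam.consensus is None:
                raise RepeatomeError(
                    f"family {fam.name}: consensus not built yet "
                    "(run plant_elements first)")
            fh.write(f">{fam.name}#LTR/{fam.spec.superfamily}/"
                     f"{fam.spec.lineage}\n{fam.consensus}\n")
        for tan in recipe.tandems:
            if tan.monomer is None:
                continue
            cls = "rDNA" if tan.kind == "rDNA" else "Satellite"
            fh.write(f">{tan.name}#{cls}\n{tan.monomer * min(tan.n_copies, 4)}\n")


def default_recipe(genome_length: int = 200_000,
                   repeat_fraction: float | None = None,
                   coverage: float = 4.0,
                   nesting_probability: float = 0.0,
                   seed_families: Sequence[tuple[str, str]] = (
                       ("Copia", "SIRE"), ("Copia", "Angela"),
                       ("Gypsy", "Tekay"), ("Gypsy", "Athila")),
                   copies_per_family: int = 4,
                   age_peaks_mya: Sequence[float] = (1.0, 1.5, 3.0, 5.0),
                   ltr_len: int = 400,
                   internal_len: int = 2400) -> SimRecipe:
    """A small but structurally complete recipe: four LTR-RE families with
    insertion-age peaks inside the last 15 MY, one satellite, one rDNA tract.
    """
    families = []
    for (sf, lin), peak in zip(seed_families, age_peaks_mya):
        spec = ElementSpec(sf, lin, ltr_len=ltr_len, internal_len=internal_len)
        families.append(RepeatFamily(
            name=f"{sf}_{lin}", spec=spec, copy_number=copies_per_family,
            ages=AgeDistribution.gaussian(peak, peak * 0.15)))
    tandems = [
        TandemSpec("sat1", "satellite", monomer_len=180, n_copies=30),
        TandemSpec("rdna", "rDNA", monomer_len=900, n_copies=4),
    ]
    recipe = SimRecipe(genome_length=genome_length, families=families,
                       tandems=tandems, coverage=coverage,
                       nesting_probability=nesting_probability)
    if repeat_fraction is not None:
        recipe = scale_to_fraction(recipe, repeat_fraction)
    return recipe
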