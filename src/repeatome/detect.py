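"""De novo structural detection of full-length LTR retrotransposon candidates.

A full-length LTR-RE is bounded by two direct long terminal repeats (LTRs),
starts with TG and ends with CA, and is flanked by a 5-bp target-site
duplication (TSD).  The detector mirrors the classic constraint set used for
structural annotation of plant genomes:

* LTR length within [100, 10 000] bp
* element span within [1 500, 25 000] bp
* 5-bp TSD and ``tgca`` terminal motif, searched within +-10 bp of the
  provisional boundaries
* inter-LTR identity >= 85 % (the similarity floor is not part of the
  published option string; it is exposed as ``min_ltr_identity``)

The search is seed-and-extend: exact 20-mer matches on the forward strand at
the same diagonal are chained and extended by ungapped X-drop into maximal
direct-repeat pairs, whose identity is then measured by global alignment.
Elements on the minus strand present the same direct-repeat structure, so
strand is assigned later from domain orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from Bio import Align

from .io_core import GenomeSequence, RepeatomeError, logger


@dataclass(frozen=True)
class DetectionParams:
    min_ltr_len: int = 100
    max_ltr_len: int = 10_000
    min_element_len: int = 1_500
    max_element_len: int = 25_000
    tsd_len: int = 5
    motif: str = "tgca"
    vicinity: int = 10
    min_ltr_identity: float = 85.0

    def __post_init__(self):
        if self.min_ltr_len > self.max_ltr_len:
            raise ValueError("min_ltr_len > max_ltr_len")
        if self.min_element_len > self.max_element_len:
            raise ValueError("min_element_len > max_element_len")
        if self.vicinity < 0:
            raise ValueError("vicinity must be >= 0")
        if len(self.motif) != 4:
            raise ValueError("motif must be 4 bases (2 per terminus)")


@dataclass(frozen=True)
class LtrCandidate:
    """A direct-repeat pair satisfying the structural constraints."""

    seq_id: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float
    tsd: str | None = None
    motif_ok: bool = False

    @property
    def element(self) -> tuple[int, int]:
        return self.ltr5[0], self.ltr3[1]

    @property
    def element_len(self) -> int:
        return self.ltr3[1] - self.ltr5[0]


def _ltr_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -16
    aligner.extend_gap_score = -4
    return aligner


_ALIGNER = _ltr_aligner()


def pair_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment (gaps count against)."""
    counts = _ALIGNER.align(a, b)[0].counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / total if total else 0.0


def _xdrop_extend(seq: str, a: int, b: int, step: int, limit: int,
                  match: int = 1, mismatch: int = -2, xdrop: int = 15) -> int:
    """Ungapped extension length from (a, b) in ``step`` direction."""
    n = len(seq)
    best = cur = 0
    best_len = length = 0
    while 0 <= a < n and 0 <= b < n and length < limit:
        c1, c2 = seq[a], seq[b]
        cur += match if (c1 == c2 and c1 != "N") else mismatch
        length += 1
        if cur > best:
            best, best_len = cur, length
        if cur < best - xdrop:
            break
        a += step
        b += step
    return best_len


def find_candidate_pairs(genome: GenomeSequence,
                         params: DetectionParams = DetectionParams(),
                         seed_k: int = 20,
                         min_seeds: int = 2,
                         max_kmer_occ: int = 64,
                         max_seed_gap: int = 500) -> list[LtrCandidate]:
    """Seed-and-extend search for direct-repeat (LTR) pairs.

    Exact ``seed_k``-mer matches at the same separation are chained (runs of
    seeds closer than ``max_seed_gap``); each chain with at least
    ``min_seeds`` seeds is extended outward by ungapped X-drop, and the
    resulting repeat pair is kept iff both repeat lengths, the spanned
    element length and the inter-LTR identity satisfy ``params``.
    k-mers containing N never seed.
    """
    seq = genome.seq
    n = len(seq)
    if n < params.min_element_len:
        return []
    # k-mer index (skip N-containing and hyper-abundant k-mers)
    index: dict[str, list[int]] = {}
    for i in range(n - seed_k + 1):
        kmer = seq[i:i + seed_k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    min_sep = max(params.min_ltr_len,
                  params.min_element_len - params.max_ltr_len)
    max_sep = params.max_element_len - params.min_ltr_len
    diagonals: dict[int, list[int]] = {}
    for positions in index.values():
        m = len(positions)
        if m < 2 or m > max_kmer_occ:
            continue
        for x in range(m):
            for y in range(x + 1, m):
                sep = positions[y] - positions[x]
                if min_sep <= sep <= max_sep:
                    diagonals.setdefault(sep, []).append(positions[x])

    candidates: list[LtrCandidate] = []
    seen_spans: set[tuple[int, int]] = set()
    for sep in sorted(diagonals):
        starts = sorted(set(diagonals[sep]))
        run: list[int] = []
        runs: list[list[int]] = []
        for i in starts:
            if run and i - run[-1] > max_seed_gap:
                runs.append(run)
                run = []
            run.append(i)
        if run:
            runs.append(run)
        for run in runs:
            if len(run) < min_seeds:
                continue
            left, right = run[0], run[-1] + seed_k
            max_len = min(sep, params.max_ltr_len)  # repeats must not overlap
            limit_right = max(0, max_len - (right - left))
            ext_r = _xdrop_extend(seq, right, right + sep, +1, limit_right)
            limit_left = max(0, max_len - (right - left) - ext_r)
            ext_l = _xdrop_extend(seq, left - 1, left - 1 + sep, -1, limit_left)
            s, e = left - ext_l, right + ext_r
            ltr_len = e - s
            if ltr_len > sep:  # chained seeds already span past the partner
                continue
            span = sep + ltr_len
            if not (params.min_ltr_len <= ltr_len <= params.max_ltr_len):
                continue
            if not (params.min_element_len <= span <= params.max_element_len):
                continue
            if (s, e + sep) in seen_spans:
                continue
            identity = pair_identity(seq[s:e], seq[s + sep:e + sep])
            if identity < params.min_ltr_identity:
                logger.debug("decayed repeat pair at %d (identity %.1f%%) "
                             "below threshold", s, identity)
                continue
            seen_spans.add((s, e + sep))
            candidates.append(LtrCandidate(
                seq_id=genome.id, ltr5=(s, e), ltr3=(s + sep, e + sep),
                ltr_identity=round(identity, 2)))
    candidates.sort(key=lambda c: (c.ltr5[0], c.ltr3[1]))
    return candidates


def refine_boundaries(candidate: LtrCandidate, genome: GenomeSequence,
                      params: DetectionParams = DetectionParams()
                      ) -> LtrCandidate | None:
    """Snap boundaries to the TSD + terminal-motif placement, or discard.

    Searches all shifts within +-``vicinity`` of the provisional element start
    and end for a placement where the element starts TG / ends CA and the
    ``tsd_len``-mers immediately flanking the element are identical.  The
    placement with the smallest total shift wins (ties toward the smaller
    start shift, then end shift).  If no placement satisfies both conditions
    the candidate is discarded (returns None).
    """
    seq = genome.seq
    n = len(seq)
    m5 = params.motif[:2].upper()
    m3 = params.motif[2:].upper()
    t = params.tsd_len
    s0, e0 = candidate.ltr5[0], candidate.ltr3[1]
    shifts = sorted(range(-params.vicinity, params.vicinity + 1),
                    key=lambda d: (abs(d), d))
    for ds in shifts:
        s = s0 + ds
        if s < t or s + 2 > n or seq[s:s + 2] != m5:
            continue
        for de in shifts:
            e = e0 + de
            if e + t > n or e - 2 < 0 or seq[e - 2:e] != m3:
                continue
            tsd = seq[s - t:s]
            if "N" in tsd or tsd != seq[e:e + t]:
                continue
            ltr5 = (s, max(candidate.ltr5[1], s + params.min_ltr_len))
            ltr3 = (min(candidate.ltr3[0], e - params.min_ltr_len), e)
            if ltr5[1] > ltr3[0]:
                continue
            if not (params.min_ltr_len <= ltr5[1] - ltr5[0] <= params.max_ltr_len):
                continue
            if not (params.min_ltr_len <= ltr3[1] - ltr3[0] <= params.max_ltr_len):
                continue
            if not (params.min_element_len <= e - s <= params.max_element_len):
                continue
            identity = pair_identity(seq[ltr5[0]:ltr5[1]], seq[ltr3[0]:ltr3[1]])
            if identity < params.min_ltr_identity:
                continue
            return replace(candidate, ltr5=ltr5, ltr3=ltr3, tsd=tsd,
                           motif_ok=True, ltr_identity=round(identity, 2))
    return None


def _mutual_overlap(a: LtrCandidate, b: LtrCandidate) -> bool:
    (a0, a1), (b0, b1) = a.element, b.element
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return False
    return ov >= 0.5 * (a1 - a0) and ov >= 0.5 * (b1 - b0)


def resolve_overlaps(candidates: Iterable[LtrCandidate]) -> list[LtrCandidate]:
    """Keep the best of each group of mutually (>=50 %) overlapping candidates.

    Higher LTR identity wins; ties go to the longer element, then the
    leftmost.  Fully nested candidates with <50 % mutual overlap are kept —
    nesting is resolved downstream after domain annotation.
    """
    ranked = sorted(candidates,
                    key=lambda c: (-c.ltr_identity, -c.element_len,
                                   c.element[0], c.element[1]))
    accepted: list[LtrCandidate] = []
    for cand in ranked:
        if any(cand.seq_id == a.seq_id and _mutual_overlap(cand, a)
               for a in accepted):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda c: (c.seq_id, c.element[0]))
    return accepted


def detect_elements(genome: GenomeSequence,
                    params: DetectionParams = DetectionParams(),
                    **seed_kwargs) -> list[LtrCandidate]:
    """Full detector: seed/extend -> TSD/motif refinement -> overlap resolution."""
    raw = find_candidate_pairs(genome, params, **seed_kwargs)
    refined = [c for c in (refine_boundaries(r, genome, params) for r in raw)
               if c is not None]
    return resolve_overlaps(refined)
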