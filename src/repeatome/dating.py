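"""Insertion-age estimation from LTR divergence.

The two LTRs of a retrotransposon are identical at the moment of insertion
and diverge afterwards, each accumulating substitutions at the per-site rate
``r`` (default 2e-8 substitutions/site/year).  The element's age is therefore

    T = K / (2 r)

where K is the Kimura two-parameter distance between the aligned LTRs,

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions over ungapped,
unambiguous alignment columns.  The K2P correction accounts for multiple
hits, so dating remains (asymptotically) unbiased as divergence grows; pairs
outside the formula's domain (2P + Q >= 1 or 2Q >= 1) are flagged saturated
and excluded from age profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io_core import RepeatomeError

DEFAULT_RATE = 2e-8  # substitutions / site / year

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


class SaturationError(RepeatomeError):
    """Divergence outside the K2P domain."""


@dataclass(frozen=True)
class LtrAlignment:
    aligned5: str
    aligned3: str
    n: int              # ungapped, unambiguous columns
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.n if self.n else 0.0

    @property
    def Q(self) -> float:
        return self.transversions / self.n if self.n else 0.0


@dataclass(frozen=True)
class K2PDistance:
    K: float
    P: float
    Q: float
    saturated: bool = False


@dataclass(frozen=True)
class InsertionAge:
    T: float            # years
    rate: float = DEFAULT_RATE

    @property
    def mya(self) -> float:
        return self.T / 1e6


def _global_aligner(match: float, mismatch: float, gap_open: float,
                    gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_ALIGNER = _global_aligner(5, -4, -16, -4)


def count_substitutions(aligned5: str, aligned3: str) -> tuple[int, int, int]:
    """(n, transitions, transversions) over ungapped unambiguous columns."""
    n = ts = tv = 0
    for a, b in zip(aligned5, aligned3):
        if a not in _BASES or b not in _BASES:
            continue
        n += 1
        if a == b:
            continue
        if (a, b) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def align_ltr_pair(ltr5: str, ltr3: str,
                   scoring: tuple[float, float, float, float] = (5, -4, -16, -4)
                   ) -> LtrAlignment:
    """End-to-end global alignment of the two LTRs of one element.

    Transition (A<->G, C<->T) and transversion counts are tallied over columns
    where both symbols are unambiguous bases; gap and N columns are excluded
    from the site count n.
    """
    if not ltr5 or not ltr3:
        raise RepeatomeError("cannot align an empty LTR sequence")
    aligner = _DEFAULT_ALIGNER if scoring == (5, -4, -16, -4) \
        else _global_aligner(*scoring)
    aln = aligner.align(ltr5, ltr3)[0]
    a5, a3 = str(aln[0]), str(aln[1])
    n, ts, tv = count_substitutions(a5, a3)
    return LtrAlignment(a5, a3, n, ts, tv)


def k2p_distance(alignment: LtrAlignment | None = None, *,
                 P: float | None = None, Q: float | None = None) -> K2PDistance:
    """Kimura two-parameter distance from an alignment or from (P, Q).

    Returns ``saturated=True`` (with infinite K) when the observed proportions
    leave the formula's domain, i.e. 2P + Q >= 1 or 2Q >= 1.
    """
    if alignment is not None:
        P, Q = alignment.P, alignment.Q
    if P is None or Q is None:
        raise ValueError("provide an alignment or both P and Q")
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PDistance(math.inf, P, Q, saturated=True)
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PDistance(max(K, 0.0), P, Q, saturated=False)


def k2p_from_counts(n: int, transitions: int, transversions: int,
                    clamp: float | None = None) -> K2PDistance:
    """K2P from raw counts; ``clamp`` bounds the log arguments away from zero
    (used for tree distances where a finite value is required)."""
    if n <= 0:
        return K2PDistance(0.0, 0.0, 0.0)
    P, Q = transitions / n, transversions / n
    if clamp is not None:
        w1 = max(1.0 - 2.0 * P - Q, clamp)
        w2 = max(1.0 - 2.0 * Q, clamp)
        return K2PDistance(-0.5 * math.log(w1 * math.sqrt(w2)), P, Q,
                           saturated=(1.0 - 2.0 * P - Q <= 0
                                      or 1.0 - 2.0 * Q <= 0))
    return k2p_distance(P=P, Q=Q)


def insertion_age(K: float, rate: float = DEFAULT_RATE) -> InsertionAge:
    """Convert a K2P distance into years since insertion, T = K/(2r).

    Each LTR accumulates substitutions independently at rate ``r`` after the
    insertion event, so the inter-LTR divergence grows at 2r per year.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if K < 0:
        raise ValueError("K2P distance must be non-negative")
    return InsertionAge(T=K / (2.0 * rate), rate=rate)


def date_element(ltr5: str, ltr3: str, rate: float = DEFAULT_RATE
                 ) -> tuple[LtrAlignment, K2PDistance, InsertionAge | None]:
    aln = align_ltr_pair(ltr5, ltr3)
    dist = k2p_distance(aln)
    if dist.saturated:
        return aln, dist, None
    return aln, dist, insertion_age(dist.K, rate)


def date_elements(elements: Sequence, genome, rate: float = DEFAULT_RATE
                  ) -> pd.DataFrame:
    """Per-element dating table (P, Q, K, age in MYA, saturation flag).

    ``elements`` carry ``ltr5``/``ltr3`` intervals on ``genome``; rows keep
    species/lineage labels when present so profiles can be grouped.
    """
    seq = genome.seq if hasattr(genome, "seq") else str(genome)
    rows = []
    for i, el in enumerate(elements):
        ltr5 = seq[el.ltr5[0]:el.ltr5[1]]
        ltr3 = seq[el.ltr3[0]:el.ltr3[1]]
        aln, dist, age = date_element(ltr5, ltr3, rate)
        rows.append({
            "element": getattr(el, "id", i),
            "species": getattr(el, "species", ""),
            "superfamily": getattr(el, "superfamily", ""),
            "lineage": getattr(el, "lineage", ""),
            "n_sites": aln.n,
            "P": dist.P,
            "Q": dist.Q,
            "K": dist.K if not dist.saturated else float("nan"),
            "age_mya": age.mya if age is not None else float("nan"),
            "saturated": dist.saturated,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# insertion-time profiles
# ---------------------------------------------------------------------------

@dataclass
class AgeProfile:
    species: str
    lineage: str
    bin_width: float
    max_mya: float
    counts: np.ndarray
    mean_age: float
    n_elements: int
    n_excluded: int = 0

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, self.max_mya + self.bin_width / 2, self.bin_width)

    @property
    def mode_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.counts))
        return (i * self.bin_width, (i + 1) * self.bin_width)


def age_profile(dated: pd.DataFrame, bin_width_mya: float = 0.5,
                max_mya: float = 15.0,
                by: tuple[str, ...] = ("species", "lineage")) -> list[AgeProfile]:
    """Binned insertion-time histograms per (species, lineage).

    Saturated or undatable elements are excluded and counted in
    ``n_excluded``; ages beyond ``max_mya`` likewise (avoiding an artificial
    boundary peak).  Mean age is computed on the included elements.
    """
    edges = np.arange(0.0, max_mya + bin_width_mya / 2, bin_width_mya)
    profiles = []
    grouped = dated.groupby(list(by), sort=True) if len(dated) else []
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        ages = grp["age_mya"].to_numpy()
        ok = np.isfinite(ages) & (ages <= max_mya)
        counts, _ = np.histogram(ages[ok], bins=edges)
        mean = float(np.mean(ages[ok])) if ok.any() else float("nan")
        profiles.append(AgeProfile(
            species=key[0] if "species" in by else "",
            lineage=key[-1] if "lineage" in by else "",
            bin_width=bin_width_mya, max_mya=max_mya, counts=counts,
            mean_age=mean, n_elements=int(ok.sum()),
            n_excluded=int((~ok).sum())))
    return profiles


def profile_table(profiles: Iterable[AgeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for i, c in enumerate(p.counts):
            rows.append({"species": p.species, "lineage": p.lineage,
                         "bin_start_mya": round(i * p.bin_width, 3),
                         "count": int(c), "mean_age_mya": p.mean_age,
                         "n_elements": p.n_elements})
    return pd.DataFrame(rows)
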