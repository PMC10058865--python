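"""Sequence and annotation I/O, coordinate conventions, and shared domain types.

All coordinates held in memory are 0-based half-open intervals ``[start, end)``.
GFF3 emitted or consumed at the package boundary is 1-based inclusive, per the
GFF3 specification; :func:`to_gff3_coords` / :func:`from_gff3_coords` are the
(tested) bijection between the two conventions.

Sequences are uppercase DNA over ``{A, C, G, T, N}``.  ``U`` is normalized to
``T`` on input; any other ambiguity code is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("repeatome")

VALID_BASES = frozenset("ACGTN")

GFF3_SOURCE = "repeatome"


class RepeatomeError(Exception):
    """Base class for errors raised by this package."""


class ParseError(RepeatomeError):
    """Malformed or inconsistent input file."""


class StageError(RepeatomeError):
    """A pipeline stage is missing its input or failed a precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence (assembly contig, read, or extracted region)."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ParseError("sequence id must be non-empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains unsupported symbols {sorted(bad)}; "
                "only A, C, G, T, N are accepted"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """A 100-bp (by default) paired-end read; both mates share the id."""

    id: str
    mate1: str
    mate2: str

    def __post_init__(self):
        if not self.mate1 or not self.mate2:
            raise ParseError(f"read pair {self.id!r} has an empty mate")


@dataclass
class AnnotationRecord:
    """One GFF3 feature with internal 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "region"
    attributes: dict = field(default_factory=dict)
    score: str = "."
    source: str = GFF3_SOURCE

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ParseError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in "+-.":
            raise ParseError(f"invalid strand {self.strand!r}")


# ---------------------------------------------------------------------------
# coordinate conversion (0-based half-open <-> GFF3 1-based inclusive)
# ---------------------------------------------------------------------------

def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """Internal ``[start, end)`` -> GFF3 1-based inclusive ``(start+1, end)``."""
    if not (0 <= start < end):
        raise ValueError(f"invalid internal interval [{start}, {end})")
    return start + 1, end


def from_gff3_coords(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    if not (1 <= start1 <= end1):
        raise ValueError(f"invalid GFF3 interval ({start1}, {end1})")
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# sequence parsing / writing
# ---------------------------------------------------------------------------

def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ParseError(
            f"record {record_id!r}: unsupported symbols {sorted(bad)} "
            "(ambiguity codes other than N are rejected)"
        )
    return seq


def parse_sequences(path: str | Path, format: str = "fasta") -> list[GenomeSequence]:
    """Read a FASTA or FASTQ file into :class:`GenomeSequence` records.

    Records are returned in file order, uppercased, with U normalized to T.
    Duplicate ids and ambiguity codes other than N raise :class:`ParseError`.
    An empty file yields an empty list.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(GenomeSequence(rec.id, _normalize(str(rec.seq), rec.id)))
    except ValueError as exc:  # Biopython signals malformed records this way
        # approximate the offending line from how many records parsed cleanly
        lines_per = 4 if format == "fastq" else 2
        raise ParseError(
            f"{path}: malformed {format} near line {len(records) * lines_per + 1}: {exc}"
        ) from exc
    return records


def parse_read_pairs(path1: str | Path, path2: str | Path,
                     format: str = "fastq") -> list[ReadPair]:
    """Read two mate files into paired records; mate counts must agree."""
    mates1 = parse_sequences(path1, format)
    mates2 = parse_sequences(path2, format)
    if len(mates1) != len(mates2):
        raise ParseError(
            f"mate-count mismatch: {path1} has {len(mates1)} records, "
            f"{path2} has {len(mates2)}"
        )
    pairs = []
    for m1, m2 in zip(mates1, mates2):
        pid = _strip_mate_suffix(m1.id)
        if _strip_mate_suffix(m2.id) != pid:
            raise ParseError(f"mate ids disagree: {m1.id!r} vs {m2.id!r}")
        pairs.append(ReadPair(pid, m1.seq, m2.seq))
    return pairs


def _strip_mate_suffix(read_id: str) -> str:
    for suffix in ("/1", "/2", ".1", ".2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def write_fasta(records: Iterable[GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_fastq_pair(pairs: Iterable[ReadPair], path1: str | Path,
                     path2: str | Path, quality_char: str = "I") -> None:
    """Write paired reads as two FASTQ files with constant quality."""
    with Path(path1).open("w") as f1, Path(path2).open("w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.mate1}\n+\n{quality_char * len(p.mate1)}\n")
            f2.write(f"@{p.id}/2\n{p.mate2}\n+\n{quality_char * len(p.mate2)}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3 annotation I/O
# ---------------------------------------------------------------------------

_GFF3_HEADER = "##gff-version 3\n"


def _fmt_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(text: str) -> dict:
    if text in (".", ""):
        return {}
    out = {}
    for item in text.rstrip(";").split(";"):
        k, _, v = item.partition("=")
        out[k] = v
    return out


def write_annotation_records(records: Iterable[AnnotationRecord],
                             path: str | Path,
                             seq_lengths: dict[str, int] | None = None) -> None:
    """Write AnnotationRecords as GFF3 (1-based inclusive at the boundary)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_GFF3_HEADER)
        for rec in records:
            if seq_lengths is not None:
                limit = seq_lengths.get(rec.seq_id)
                if limit is not None and rec.end > limit:
                    raise RepeatomeError(
                        f"interval [{rec.start}, {rec.end}) exceeds length "
                        f"{limit} of sequence {rec.seq_id}"
                    )
            s1, e1 = to_gff3_coords(rec.start, rec.end)
            fh.write("\t".join([
                rec.seq_id, rec.source, rec.feature_type, str(s1), str(e1),
                rec.score, rec.strand, ".", _fmt_attrs(rec.attributes),
            ]) + "\n")


def read_annotation_records(path: str | Path) -> list[AnnotationRecord]:
    """Read a GFF3 file back into internal-coordinate AnnotationRecords."""
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, "
                                 f"got {len(cols)}")
            start, end = from_gff3_coords(int(cols[3]), int(cols[4]))
            records.append(AnnotationRecord(
                seq_id=cols[0], source=cols[1], feature_type=cols[2],
                start=start, end=end, score=cols[5], strand=cols[6],
                attributes=_parse_attrs(cols[8]),
            ))
    return records


def element_records(element, element_id: str) -> list[AnnotationRecord]:
    """Annotation records (parent + LTR children + TSD) for one element call.

    Accepts any object with ``seq_id``, ``element``/``ltr5``/``ltr3`` interval
    attributes and optional ``tsd``, ``ltr_identity``, ``superfamily``,
    ``lineage``, ``strand`` metadata (duck-typed so both detector candidates
    and fully annotated elements can be written).
    """
    seq_id = element.seq_id
    (es, ee) = element.element
    strand = getattr(element, "strand", ".") or "."
    attrs = {"ID": element_id}
    for key in ("ltr_identity", "superfamily", "lineage", "status", "age_mya"):
        val = getattr(element, key, None)
        if val is not None:
            attrs[key] = f"{val:.2f}" if isinstance(val, float) else str(val)
    tsd = getattr(element, "tsd", None)
    if tsd:
        attrs["tsd"] = tsd
    recs = [AnnotationRecord(seq_id, es, ee, strand, "LTR_retrotransposon", attrs)]
    for name, (s, e) in (("five_prime", element.ltr5), ("three_prime", element.ltr3)):
        recs.append(AnnotationRecord(
            seq_id, s, e, strand, "long_terminal_repeat",
            {"Parent": element_id, "side": name}))
    if tsd:
        if es - len(tsd) >= 0:
            recs.append(AnnotationRecord(
                seq_id, es - len(tsd), es, strand, "target_site_duplication",
                {"Parent": element_id}))
        recs.append(AnnotationRecord(
            seq_id, ee, ee + len(tsd), strand, "target_site_duplication",
            {"Parent": element_id}))
    return recs


def write_annotations(elements: Sequence, path: str | Path,
                      seq_lengths: dict[str, int] | None = None) -> None:
    """Write element calls as GFF3 with LTR_retrotransposon parent features."""
    records: list[AnnotationRecord] = []
    for i, el in enumerate(elements, start=1):
        records.extend(element_records(el, f"LTRRE_{i}"))
    write_annotation_records(records, path, seq_lengths)


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
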