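"""Sequence I/O, read-pair merging and length filtering.

FASTQ/FASTA parsing is delegated to Biopython; this module adds the
amplicon-specific steps: trailing sliding-window quality trimming,
overlap-based merging of a read pair into a single amplicon sequence,
and the strict >450 bp length filter applied before taxonomic assignment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default minimum length, exclusive: only reads strictly longer pass
MIN_LENGTH_EXCLUSIVE = 450


class FastqParseError(ValueError):
    """Raised for malformed FASTQ input; message names the offending line."""


@dataclasses.dataclass
class SequenceRecord:
    """A nucleotide sequence with optional per-base Phred qualities."""

    id: str
    bases: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise FastqParseError(
                f"record {self.id!r}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass
class MergedRead:
    """Result of merging a forward/reverse pair across their overlap."""

    id: str
    bases: str
    overlap_length: int
    mismatches_in_overlap: int
    qualities: list[int] | None = None

    def __len__(self) -> int:
        return len(self.bases)


def reverse_complement(bases: str) -> str:
    return bases.translate(COMPLEMENT)[::-1]


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Parse a Phred+33 FASTQ file into :class:`SequenceRecord` objects.

    Raises :class:`FastqParseError` naming the line number for truncated
    or malformed records.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                records.append(
                    SequenceRecord(
                        id=rec.id,
                        bases=str(rec.seq),
                        qualities=list(rec.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:
            # approximate line of failure: 4 lines per parsed record
            raise FastqParseError(
                f"{path}: malformed FASTQ near line {4 * len(records) + 1}: {exc}"
            ) from exc
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, bases=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord | MergedRead], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.bases), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seq_records = []
    for r in records:
        if r.qualities is None:
            raise ValueError(f"record {r.id!r} has no qualities; cannot write FASTQ")
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        seq_records.append(rec)
    SeqIO.write(seq_records, str(path), "fastq")


def quality_trim(
    record: SequenceRecord, quality_threshold: int = 20, window: int = 4
) -> SequenceRecord:
    """Trim the 3' tail where sliding-window mean quality drops below threshold.

    Scanning from the 5' end, the first window whose mean quality falls
    below ``quality_threshold`` marks the drop-off; the read is cut at the
    first base within that window whose own quality is below the threshold.
    Never lengthens a read; may return an empty one.
    """
    if record.qualities is None:
        raise ValueError(f"record {record.id!r} has no qualities to trim on")
    quals = record.qualities
    n = len(quals)
    cut = n
    for start in range(0, max(n - window + 1, 1)):
        win = quals[start : start + window]
        if not win:
            break
        if sum(win) / len(win) < quality_threshold:
            cut = start
            for offset, q in enumerate(win):
                if q < quality_threshold:
                    cut = start + offset
                    break
            break
    return SequenceRecord(record.id, record.bases[:cut], quals[:cut])


def merge_pairs(
    fwd: SequenceRecord,
    rev: SequenceRecord,
    min_overlap: int = 20,
    max_mismatch_fraction: float = 0.1,
) -> MergedRead | None:
    """Merge a read pair by their best 3' overlap, or return None if unmergeable.

    The reverse read is reverse-complemented, then every overlap length from
    ``min_overlap`` up to the shorter read is scored; among overlaps whose
    mismatch fraction is <= ``max_mismatch_fraction`` the one with the lowest
    mismatch fraction wins (ties to the longer overlap). Disagreeing bases in
    the overlap are resolved to the higher-quality base, ties to the forward
    base.
    """
    if not fwd.bases or not rev.bases:
        raise ValueError("cannot merge empty reads")
    rc = reverse_complement(rev.bases)
    rc_quals = rev.qualities[::-1] if rev.qualities is not None else None

    best: tuple[float, int, int] | None = None  # (mismatch_frac, -overlap, mism)
    max_olap = min(len(fwd.bases), len(rc))
    for olap in range(min_overlap, max_olap + 1):
        f_tail = fwd.bases[-olap:]
        r_head = rc[:olap]
        mism = sum(a != b for a, b in zip(f_tail, r_head))
        frac = mism / olap
        if frac <= max_mismatch_fraction:
            key = (frac, -olap, mism)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    _, neg_olap, mism = best
    olap = -neg_olap

    f_len = len(fwd.bases)
    merged = list(fwd.bases[: f_len - olap])
    merged_quals: list[int] = list(
        (fwd.qualities or [40] * f_len)[: f_len - olap]
    )
    for i in range(olap):
        fb = fwd.bases[f_len - olap + i]
        rb = rc[i]
        fq = fwd.qualities[f_len - olap + i] if fwd.qualities is not None else 40
        rq = rc_quals[i] if rc_quals is not None else 40
        if fb == rb:
            merged.append(fb)
            merged_quals.append(max(fq, rq))
        elif rq > fq:
            merged.append(rb)
            merged_quals.append(rq)
        else:  # ties to forward
            merged.append(fb)
            merged_quals.append(fq)
    merged.extend(rc[olap:])
    merged_quals.extend(rc_quals[olap:] if rc_quals is not None else [40] * (len(rc) - olap))

    return MergedRead(
        id=fwd.id,
        bases="".join(merged),
        overlap_length=olap,
        mismatches_in_overlap=mism,
        qualities=merged_quals,
    )


def length_filter(
    records: Sequence, min_exclusive: int = MIN_LENGTH_EXCLUSIVE
) -> list:
    """Retain records strictly longer than ``min_exclusive`` bases, in order.

    The boundary is exclusive: a read of exactly ``min_exclusive`` bases is
    dropped. Idempotent.
    """
    return [r for r in records if len(r) > min_exclusive]
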