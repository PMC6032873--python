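"""Consensus taxonomic assignment of barcode reads against a reference library.

Each merged read is compared to a local reference database by k-mer
prefiltering followed by local alignment, the best-scoring hits are kept
(top 20 bit scores by default, ties at the cut retained), and a consensus
rule assigns the read to a taxon:

* all retained hits one species -> that species;
* else if >= 60% of hits share one genus -> that genus;
* else the read is "various": resolved to family/tribe level when >= 90%
  of hits share one family, otherwise "unknown".

An allow-list of regionally recorded taxa can then be applied, and
per-insect read counts are converted to percentages of identified reads
to control for amplification differences between samples.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

RANKS = ("species", "genus", "family_tribe", "unknown")

_BASE_CODES = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODES[ord(_b)] = _i
    _BASE_CODES[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODES[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw_score(
    a: np.ndarray,
    b: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
) -> int:
    """Smith-Waterman/Gotoh local alignment score (integer scheme).

    Affine gaps: a gap of length L costs open + extend*(L-1), matching the
    convention where the first gap base pays the open penalty.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    h_row = np.zeros(m + 1, dtype=np.int64)
    e_row = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        diag_prev = h_row[0]  # H[i-1][j-1], updated as we sweep j
        f = NEG  # gap in b (horizontal) for this row
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if ai == b[j - 1] else mismatch
            diag = diag_prev + sub
            e = max(h_row[j] + gap_open, e_row[j] + gap_extend)  # gap in a
            f = max(h_row[j - 1] + gap_open, f + gap_extend)
            diag_prev = h_row[j]
            h = max(0, max(diag, max(e, f)))
            h_row[j] = h
            e_row[j] = e
            if h > best:
                best = h
    return best


@dataclasses.dataclass(frozen=True)
class ScoringConfig:
    """Alignment and bit-score constants (megablast-style +1/-2 scheme).

    ``lambda_`` and ``k`` enter only the reported bit score
    ``(lambda * S - ln K) / ln 2``, a strictly increasing transform of the
    raw score S, so they never change which hits rank highest.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lambda_: float = 1.28
    k: float = 0.46

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k)) / math.log(2)


@dataclasses.dataclass(frozen=True)
class Hit:
    reference_id: str
    raw_score: float
    bit_score: float


@dataclasses.dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    taxon_label: str
    rank: str  # species | genus | family_tribe | unknown
    supporting_hit_fraction: float

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"invalid rank {self.rank!r}")


@dataclasses.dataclass
class PollenProfile:
    """Per-insect pollen load: read counts and percentages per taxon."""

    insect_id: str
    insect_species: str
    sex: str
    site: str
    period: str
    counts: dict[str, int]
    percents: dict[str, float]
    excluded: bool = False  # True when no reads identified for this insect

    @property
    def total_identified(self) -> int:
        return sum(self.counts.values())

    @property
    def top_taxon(self) -> str | None:
        if not self.percents:
            return None
        top = max(self.percents.values())
        return min(t for t, p in self.percents.items() if p == top)


class ReferenceDB:
    """Reference sequences labelled at species/genus/family rank, k-mer indexed."""

    def __init__(self, records: Mapping[str, tuple[str, str, str, str]], k: int = 8):
        """``records`` maps reference id -> (sequence, species, genus, family)."""
        if not records:
            raise ValueError("empty reference database")
        self.k = k
        self.records = dict(records)
        shortest = min(len(seq) for seq, *_ in self.records.values())
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds shortest reference length {shortest}"
            )
        self.index: dict[str, set[str]] = defaultdict(set)
        self._encoded: dict[str, np.ndarray] = {}
        for ref_id, (seq, *_rest) in self.records.items():
            self._encoded[ref_id] = _encode(seq)
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].add(ref_id)

    def lineage(self, reference_id: str) -> tuple[str, str, str]:
        _, sp, gen, fam = self.records[reference_id]
        return sp, gen, fam

    def taxon_ancestors(self) -> dict[str, set[str]]:
        """Map every taxon label to itself plus its ancestor labels."""
        anc: dict[str, set[str]] = {}
        for _, sp, gen, fam in self.records.values():
            anc.setdefault(sp, set()).update({sp, gen, fam})
            anc.setdefault(gen, set()).update({gen, fam})
            anc.setdefault(fam, set()).add(fam)
        return anc


def build_reference_index(fasta: str | Path, k: int = 8) -> ReferenceDB:
    """Load a reference FASTA with ``>species|genus|family`` headers.

    Reference id is the species field; duplicate ids or headers lacking all
    three ranks are rejected.
    """
    records: dict[str, tuple[str, str, str, str]] = {}
    header: str | None = None
    chunks: list[str] = []

    def _store(hdr: str, seq: str) -> None:
        parts = hdr.split("|")
        if len(parts) != 3 or not all(parts):
            raise ValueError(
                f"reference header {hdr!r} must be 'species|genus|family'"
            )
        sp, gen, fam = parts
        if sp in records:
            raise ValueError(f"duplicate reference id {sp!r}")
        records[sp] = (seq.upper(), sp, gen, fam)

    with open(fasta) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    _store(header, "".join(chunks))
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if header is not None:
        _store(header, "".join(chunks))
    return ReferenceDB(records, k=k)


def score_hits(
    read: str,
    db: ReferenceDB,
    scoring: ScoringConfig | None = None,
    min_shared_kmers: int = 1,
    report_bit_fraction: float = 0.98,
) -> list[Hit]:
    """Score a read against all k-mer-sharing references by local alignment.

    Candidates must share at least ``min_shared_kmers`` k-mers with the read;
    each is scored with the configured local-alignment scheme and reported
    with its bit score. Like a BLAST search, only significant hits are
    reported: anything scoring below ``report_bit_fraction`` of the best
    bit score for the read is dropped (set to 0 to report everything).
    Hits are sorted by bit score descending, ties broken by reference id
    for determinism.
    """
    scoring = scoring or ScoringConfig()
    if len(read) <= db.k:
        raise ValueError(f"read shorter than k={db.k}")
    read = read.upper()
    shared: Counter[str] = Counter()
    seen_kmers = set()
    for i in range(len(read) - db.k + 1):
        kmer = read[i : i + db.k]
        if kmer in seen_kmers:
            continue
        seen_kmers.add(kmer)
        for ref_id in db.index.get(kmer, ()):
            shared[ref_id] += 1
    candidates = [r for r, c in shared.items() if c >= min_shared_kmers]
    if not candidates:
        return []
    encoded_read = _encode(read)
    hits = []
    for ref_id in candidates:
        raw = _sw_score(
            db._encoded[ref_id],
            encoded_read,
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
        )
        hits.append(Hit(ref_id, float(raw), scoring.bit_score(raw)))
    hits.sort(key=lambda h: (-h.bit_score, h.reference_id))
    if hits and report_bit_fraction > 0:
        cutoff = report_bit_fraction * hits[0].bit_score
        hits = [h for h in hits if h.bit_score >= cutoff]
    return hits


def top_hits(hits: Sequence[Hit], n: int = 20) -> list[Hit]:
    """Keep the ``n`` highest bit scores; hits tied with the n-th are kept too."""
    if len(hits) <= n:
        return list(hits)
    ordered = sorted(hits, key=lambda h: (-h.bit_score, h.reference_id))
    cutoff = ordered[n - 1].bit_score
    return [h for h in ordered if h.bit_score >= cutoff]


def assign_taxon(
    top: Sequence[Hit],
    db: ReferenceDB,
    read_id: str = "",
    genus_threshold: float = 0.60,
    family_threshold: float = 0.90,
) -> TaxonAssignment:
    """Apply the consensus rules to a read's retained top hits.

    Thresholds are inclusive ("60% or more"). An empty hit table yields an
    unknown call with zero support.
    """
    if not top:
        return TaxonAssignment(read_id, "unknown", "unknown", 0.0)
    lineages = [db.lineage(h.reference_id) for h in top]
    n = len(lineages)
    species = {sp for sp, _, _ in lineages}
    if len(species) == 1:
        return TaxonAssignment(read_id, next(iter(species)), "species", 1.0)
    genus_counts = Counter(gen for _, gen, _ in lineages)
    gen, gen_n = max(genus_counts.items(), key=lambda kv: (kv[1], kv[0]))
    if gen_n / n >= genus_threshold:
        return TaxonAssignment(read_id, gen, "genus", gen_n / n)
    # "various": resolve to family/tribe where possible
    family_counts = Counter(fam for _, _, fam in lineages)
    fam, fam_n = max(family_counts.items(), key=lambda kv: (kv[1], kv[0]))
    if fam_n / n >= family_threshold:
        return TaxonAssignment(read_id, fam, "family_tribe", fam_n / n)
    return TaxonAssignment(read_id, "unknown", "unknown", fam_n / n)


def assign_reads(
    reads: Iterable,
    db: ReferenceDB,
    scoring: ScoringConfig | None = None,
    top_n: int = 20,
    genus_threshold: float = 0.60,
    family_threshold: float = 0.90,
    report_bit_fraction: float = 0.98,
) -> list[TaxonAssignment]:
    """Full per-read assignment: score, keep top hits, call consensus."""
    scoring = scoring or ScoringConfig()
    out = []
    for read in reads:
        hits = score_hits(
            read.bases, db, scoring, report_bit_fraction=report_bit_fraction
        )
        call = assign_taxon(
            top_hits(hits, top_n),
            db,
            read_id=read.id,
            genus_threshold=genus_threshold,
            family_threshold=family_threshold,
        )
        out.append(call)
    return out


def filter_allowlist(
    assignments: Sequence[TaxonAssignment],
    allowlist: set[str] | None,
    db: ReferenceDB,
) -> list[TaxonAssignment]:
    """Drop assignments whose taxon (and every ancestor) is off the allow-list.

    ``allowlist`` holds labels at any rank; a species-level call is retained
    when its genus or family is listed. ``None`` disables filtering.
    """
    if allowlist is None:
        return list(assignments)
    ancestors = db.taxon_ancestors()
    kept = []
    for a in assignments:
        if a.rank == "unknown":
            kept.append(a)
            continue
        lineage = ancestors.get(a.taxon_label, {a.taxon_label})
        if lineage & allowlist:
            kept.append(a)
    return kept


def profile_insect(
    assignments: Sequence[TaxonAssignment],
    metadata: Mapping[str, str],
) -> PollenProfile:
    """Aggregate one insect's read assignments into a pollen profile.

    Unknown-rank reads are excluded from counts; percentages are of
    identified reads. An insect with zero identified reads is flagged
    excluded (it contributes to no downstream analysis).
    """
    required = ("insect_id", "insect_species", "sex", "site", "period")
    missing = [f for f in required if f not in metadata]
    if missing:
        raise ValueError(f"metadata missing fields: {missing}")
    counts: Counter[str] = Counter(
        a.taxon_label for a in assignments if a.rank != "unknown"
    )
    total = sum(counts.values())
    percents = (
        {t: 100.0 * c / total for t, c in counts.items()} if total else {}
    )
    return PollenProfile(
        insect_id=metadata["insect_id"],
        insect_species=metadata["insect_species"],
        sex=metadata["sex"],
        site=metadata["site"],
        period=metadata["period"],
        counts=dict(counts),
        percents=percents,
        excluded=total == 0,
    )


def profiles_to_frame(profiles: Sequence[PollenProfile]) -> pd.DataFrame:
    """Tidy long-format table: one row per insect x taxon."""
    rows = []
    for p in profiles:
        if p.excluded:
            continue
        for taxon, count in sorted(p.counts.items()):
            rows.append(
                {
                    "insect_id": p.insect_id,
                    "insect_species": p.insect_species,
                    "sex": p.sex,
                    "site": p.site,
                    "period": p.period,
                    "taxon": taxon,
                    "count": count,
                    "percent": p.percents[taxon],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "insect_id",
            "insect_species",
            "sex",
            "site",
            "period",
            "taxon",
            "count",
            "percent",
        ],
    )
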