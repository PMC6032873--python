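"""Synthetic reference libraries, pollen mixtures and amplicon reads.

Generates data with the statistical structure the downstream analysis
assumes: a hierarchical plant taxonomy (family > genus > species) with
controllable sequence divergence, per-insect pollen mixtures in which a
period-dependent fraction of insects are near-pure single-taxon carriers,
lognormal read depths, and substitution-only sequencing errors on paired
reads. Every generated read is tracked in a ground-truth table so that
assignment accuracy and composition recovery can be measured exactly.

The defaults emulate the study conditions the pipeline is designed for:
four grassland sites, two seasonal periods (early/late), and six hoverfly
species with highly uneven capture frequencies.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pollennet.seqio import SequenceRecord, reverse_complement

BASES = np.array(list("ACGT"))

#: hoverfly species pool with default capture weights (relative frequencies
#: of the six Eristalis species in the study system: 5, 57, 2, 41, 53, 17)
DEFAULT_INSECT_SPECIES = {
    "E_arbustorum": 5,
    "E_horticola": 57,
    "E_intricaria": 2,
    "E_nemorum": 41,
    "E_pertinax": 53,
    "E_tenax": 17,
}

DEFAULT_SITES = ("CAD", "LLC", "RHC", "TRE")
PERIODS = ("early", "late")


@dataclasses.dataclass
class DivergenceParams:
    """Expected pairwise substitution fractions between reference sequences."""

    within_genus: float = 0.03
    between_genus: float = 0.08
    between_family: float = 0.15

    def __post_init__(self) -> None:
        for name in ("within_genus", "between_genus", "between_family"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.within_genus > self.between_genus:
            raise ValueError(
                "within-genus divergence must not exceed between-genus "
                f"({self.within_genus} > {self.between_genus})"
            )
        if self.between_genus > self.between_family:
            raise ValueError(
                "between-genus divergence must not exceed between-family "
                f"({self.between_genus} > {self.between_family})"
            )


@dataclasses.dataclass
class TaxonomyTruth:
    """A reference library: labelled taxa plus their barcode sequences."""

    taxa: list[tuple[str, str, str]]  # (species_id, genus_id, family_id)
    reference_sequences: dict[str, str]  # species_id -> nucleotides
    divergence_params: DivergenceParams

    def __post_init__(self) -> None:
        species = [s for s, _, _ in self.taxa]
        if len(set(species)) != len(species):
            raise ValueError("duplicate species ids in taxonomy")
        missing = set(species) - set(self.reference_sequences)
        if missing:
            raise ValueError(f"species without sequences: {sorted(missing)}")

    @property
    def species_ids(self) -> list[str]:
        return [s for s, _, _ in self.taxa]

    def lineage(self, species_id: str) -> tuple[str, str, str]:
        for s, g, f in self.taxa:
            if s == species_id:
                return s, g, f
        raise KeyError(species_id)

    def to_fasta(self, path: str | Path) -> None:
        """Write the reference FASTA with ``>species|genus|family`` headers."""
        with open(path, "w") as fh:
            for s, g, f in self.taxa:
                fh.write(f">{s}|{g}|{f}\n{self.reference_sequences[s]}\n")


@dataclasses.dataclass
class SyntheticMixture:
    """Ground-truth pollen composition carried by one insect."""

    insect_id: str
    insect_species: str
    sex: str  # "F" or "M"
    site: str
    period: str  # "early" or "late"
    true_proportions: dict[str, float]  # plant species_id -> fraction
    specialist_flag: bool
    specialist_floor: float = 0.9

    def __post_init__(self) -> None:
        total = sum(self.true_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        if any(p < 0 for p in self.true_proportions.values()):
            raise ValueError("negative proportion")
        if self.specialist_flag and max(self.true_proportions.values()) < self.specialist_floor:
            raise ValueError("specialist mixture below specialist floor")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}")


@dataclasses.dataclass
class ReadSimConfig:
    """Knobs for paired-read simulation.

    Depth is drawn per insect from a lognormal (mean/sigma on the log scale)
    unless ``fixed_depth`` is set. Errors are i.i.d. substitutions; no indels
    are simulated, so merged-read lengths are deterministic.
    """

    read_length: int = 300
    amplicon_length: int = 500
    depth_lognormal_mean: float = 5.5  # exp(5.5) ~ 245 reads
    depth_lognormal_sigma: float = 0.6
    fixed_depth: int | None = None
    error_rate: float = 0.005
    quality_score: int = 35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.25:
            raise ValueError(f"error rate must be in [0, 0.25], got {self.error_rate}")
        if self.fixed_depth is not None and self.fixed_depth < 0:
            raise ValueError("depth must be >= 0")
        if self.read_length > self.amplicon_length:
            raise ValueError(
                f"read_length {self.read_length} exceeds amplicon_length "
                f"{self.amplicon_length}"
            )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = BASES[BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_reference_db(
    n_families: int = 4,
    genera_per_family: int = 2,
    species_per_genus: int = 2,
    divergence_params: DivergenceParams | None = None,
    seed: int = 0,
    amplicon_length: int = 500,
    min_species_distance: float = 0.01,
) -> TaxonomyTruth:
    """Evolve a hierarchical reference library from a random root sequence.

    Each family ancestor, genus ancestor and species tip accumulates
    independent substitutions, with per-branch rates chosen so expected
    pairwise divergence within a genus equals ``within_genus``, between
    genera ``between_genus``, and between families ``between_family``
    (ignoring multiple hits at the same position). Deterministic in ``seed``.

    Unless the within-genus divergence is zero, every pair of species is
    kept at least ``min_species_distance`` (fraction of amplicon length)
    apart by deterministic re-draws, mirroring the fact that a curated
    barcode library only resolves species the marker can distinguish.
    Set ``min_species_distance=0`` to allow (or force, with zero
    divergence) identical reference species.
    """
    if min(n_families, genera_per_family, species_per_genus) < 1:
        raise ValueError("all taxonomy counts must be >= 1")
    div = divergence_params or DivergenceParams()
    rng = np.random.default_rng(seed)
    root = rng.choice(BASES, size=amplicon_length)

    # per-branch rates: pairwise distance ~ 2 * branch rate accumulated below
    # the shared ancestor
    sp_rate = div.within_genus / 2
    gen_rate = (div.between_genus - div.within_genus) / 2
    fam_rate = (div.between_family - div.between_genus) / 2

    min_dist = (
        int(np.ceil(min_species_distance * amplicon_length))
        if div.within_genus > 0
        else 0
    )

    taxa: list[tuple[str, str, str]] = []
    seqs: dict[str, str] = {}
    arrays: list[np.ndarray] = []
    for fi in range(n_families):
        fam_id = f"Fam{fi + 1}"
        fam_seq = _mutate(root, fam_rate, rng)
        for gi in range(genera_per_family):
            gen_id = f"{fam_id}_Gen{gi + 1}"
            gen_seq = _mutate(fam_seq, gen_rate, rng)
            for si in range(species_per_genus):
                sp_id = f"{gen_id}_Sp{si + 1}"
                for _attempt in range(1000):
                    sp_seq = _mutate(gen_seq, sp_rate, rng)
                    if min_dist == 0 or all(
                        int((sp_seq != prev).sum()) >= min_dist for prev in arrays
                    ):
                        break
                else:
                    raise RuntimeError(
                        "could not satisfy min_species_distance; divergence "
                        "parameters too small for the requested library"
                    )
                arrays.append(sp_seq)
                taxa.append((sp_id, gen_id, fam_id))
                seqs[sp_id] = "".join(sp_seq)
    return TaxonomyTruth(taxa=taxa, reference_sequences=seqs, divergence_params=div)


def _draw_specialist_share(rng: np.random.Generator, floor: float) -> float:
    """Dominant-taxon share for a specialist: Beta(20, 1) truncated >= floor.

    Models near-pure pollen loads with a little heterospecific carry-over.
    """
    while True:
        p = rng.beta(20, 1)
        if p >= floor:
            return p


def generate_insects(
    n: int,
    site: str,
    period: str,
    specialist_prob: float,
    availability: Mapping[str, float],
    concentration: float = 1.0,
    specialist_floor: float = 0.9,
    species_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[SyntheticMixture]:
    """Draw ground-truth pollen mixtures for ``n`` insects at one site/period.

    With probability ``specialist_prob`` an insect is a single-plant
    specialist: one taxon drawn proportional to ``availability`` receives a
    share >= ``specialist_floor``, the remainder spread over up to three
    other taxa. Otherwise proportions come from a Dirichlet (parameter
    ``concentration`` x normalised availability) over 2-6 available taxa.
    """
    if not 0 <= specialist_prob <= 1:
        raise ValueError("specialist_prob must be in [0, 1]")
    avail_taxa = [t for t, w in availability.items() if w > 0]
    if not avail_taxa:
        raise ValueError("availability is empty or all-zero")
    weights = np.array([availability[t] for t in avail_taxa], dtype=float)
    weights /= weights.sum()

    pool = species_weights or DEFAULT_INSECT_SPECIES
    pool_names = list(pool)
    pool_w = np.array([pool[s] for s in pool_names], dtype=float)
    pool_w /= pool_w.sum()

    rng = np.random.default_rng(seed)
    prefix = id_prefix or f"{site}_{period}"
    mixtures: list[SyntheticMixture] = []
    for i in range(n):
        insect_species = rng.choice(pool_names, p=pool_w)
        sex = "F" if rng.random() < 0.5 else "M"
        is_specialist = rng.random() < specialist_prob
        if is_specialist or len(avail_taxa) == 1:
            main_idx = rng.choice(len(avail_taxa), p=weights)
            main = avail_taxa[main_idx]
            share = _draw_specialist_share(rng, specialist_floor)
            props = {main: share}
            others = [t for t in avail_taxa if t != main]
            if others and share < 1.0:
                k = min(len(others), int(rng.integers(1, 4)))
                o_w = np.array([availability[t] for t in others])
                o_idx = rng.choice(
                    len(others), size=k, replace=False, p=o_w / o_w.sum()
                )
                split = rng.dirichlet(np.ones(k))
                for j, oi in enumerate(o_idx):
                    props[others[oi]] = (1 - share) * split[j]
            else:
                props[main] = 1.0
            is_specialist = True
        else:
            k = min(len(avail_taxa), int(rng.integers(2, 7)))
            idx = rng.choice(len(avail_taxa), size=k, replace=False, p=weights)
            # alpha blends availability with a uniform floor and sums to ~k,
            # so a generalist's load is spread over its taxa and only rarely
            # dominated by a single one even under skewed availability
            w = weights[idx] / weights[idx].sum()
            alpha = concentration * np.maximum((k * w + 1.0) / 2, 0.05)
            p = rng.dirichlet(alpha)
            props = {avail_taxa[j]: p[h] for h, j in enumerate(idx)}
            is_specialist = max(props.values()) >= specialist_floor
        total = sum(props.values())
        props = {t: v / total for t, v in props.items()}
        mixtures.append(
            SyntheticMixture(
                insect_id=f"{prefix}_ins{i + 1:03d}",
                insect_species=str(insect_species),
                sex=sex,
                site=site,
                period=period,
                true_proportions=props,
                specialist_flag=bool(is_specialist),
                specialist_floor=specialist_floor,
            )
        )
    return mixtures


def generate_reads(
    mixture: SyntheticMixture,
    taxonomy: TaxonomyTruth,
    config: ReadSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Simulate paired reads for one insect; returns (fwd, rev, truth table).

    Each read's source taxon is sampled from the mixture's true proportions;
    the forward read covers the first ``read_length`` bases of the source
    amplicon and the reverse read is the reverse complement of the last
    ``read_length`` bases. Substitution errors are i.i.d. per base. The truth
    table maps read id to source species.
    """
    unknown = set(mixture.true_proportions) - set(taxonomy.reference_sequences)
    if unknown:
        raise ValueError(f"mixture taxa absent from taxonomy: {sorted(unknown)}")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)

    if config.fixed_depth is not None:
        depth = config.fixed_depth
    else:
        depth = int(
            round(rng.lognormal(config.depth_lognormal_mean, config.depth_lognormal_sigma))
        )

    taxa = sorted(mixture.true_proportions)
    probs = np.array([mixture.true_proportions[t] for t in taxa])
    fwd_reads: list[SequenceRecord] = []
    rev_reads: list[SequenceRecord] = []
    truth_rows = []
    quals = [config.quality_score] * config.read_length
    for r in range(depth):
        source = taxa[rng.choice(len(taxa), p=probs)]
        amplicon = taxonomy.reference_sequences[source]
        if len(amplicon) < config.read_length:
            raise ValueError(
                f"amplicon of {source} shorter than read length"
            )
        fwd_seq = np.array(list(amplicon[: config.read_length]))
        rev_seq = np.array(list(reverse_complement(amplicon[-config.read_length :])))
        if config.error_rate > 0:
            fwd_seq = _mutate(fwd_seq, config.error_rate, rng)
            rev_seq = _mutate(rev_seq, config.error_rate, rng)
        read_id = f"{mixture.insect_id}_r{r + 1:05d}"
        fwd_reads.append(SequenceRecord(read_id, "".join(fwd_seq), list(quals)))
        rev_reads.append(SequenceRecord(read_id, "".join(rev_seq), list(quals)))
        truth_rows.append((read_id, mixture.insect_id, source))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "insect_id", "source_species"])
    return fwd_reads, rev_reads, truth


def mixtures_metadata(mixtures: Sequence[SyntheticMixture]) -> pd.DataFrame:
    """Tidy per-insect metadata table for a set of mixtures."""
    return pd.DataFrame(
        [
            {
                "insect_id": m.insect_id,
                "insect_species": m.insect_species,
                "sex": m.sex,
                "site": m.site,
                "period": m.period,
                "specialist_flag": m.specialist_flag,
            }
            for m in mixtures
        ]
    )
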