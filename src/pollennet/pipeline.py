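"""End-to-end pipeline: simulate -> assign -> networks -> classify -> report.

Every stage writes plain TSV/FASTA/FASTQ intermediates into the output
directory so any stage can be inspected, re-run or replaced, and a summary
log records per-stage record counts (reads in = merged + unmerged;
merged = passing + failing the length filter; assigned + unknown =
passing reads), in the style of amplicon-pipeline accounting.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from pollennet import assignment, networks, seqio, specialisation, synthetic

logger = logging.getLogger("pollennet")

STAGES = ("simulate", "assign", "networks", "classify", "report")


@dataclasses.dataclass
class PipelineConfig:
    """All paths, thresholds and simulation knobs for one pipeline run."""

    output_dir: str = "pollennet_out"
    reads_r1: str | None = None  # forward FASTQ; default: simulated
    reads_r2: str | None = None
    reference_fasta: str | None = None
    allowlist_path: str | None = None  # one taxon label per line; None = off
    metadata_path: str | None = None  # insect metadata TSV

    # sequence processing thresholds
    quality_threshold: int = 20
    trim_window: int = 4
    min_overlap: int = 20
    max_mismatch_fraction: float = 0.1
    min_length_exclusive: int = 450

    # assignment thresholds
    kmer_size: int = 8
    report_bit_fraction: float = 0.98
    top_n: int = 20
    genus_threshold: float = 0.60
    family_threshold: float = 0.90
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    # network / classification thresholds
    presence_min_percent: float = 0.0
    classify_threshold: float = 90.0
    pool_threshold: float = 1.0

    # simulation (study-condition defaults; sizes configurable)
    sites: tuple[str, ...] = synthetic.DEFAULT_SITES
    n_insects_early: int = 14
    n_insects_late: int = 31
    specialist_prob_early: float = 0.40
    specialist_prob_late: float = 0.24
    n_families: int = 4
    genera_per_family: int = 2
    species_per_genus: int = 2
    within_genus_divergence: float = 0.03
    between_genus_divergence: float = 0.08
    read_length: int = 300
    amplicon_length: int = 500
    error_rate: float = 0.005
    fixed_depth: int | None = None
    seed: int = 0

    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not 0 <= self.genus_threshold <= 1 or not 0 <= self.family_threshold <= 1:
            raise ValueError("consensus thresholds must be in [0, 1]")
        if not 0 <= self.classify_threshold <= 100:
            raise ValueError("classification threshold must be in [0, 100]")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def scoring(self) -> assignment.ScoringConfig:
        return assignment.ScoringConfig(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sites"] = list(self.sites)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["sites"] = tuple(data.get("sites", synthetic.DEFAULT_SITES))
        data["stages"] = tuple(data.get("stages", STAGES))
        return cls(**data)


def flower_unit_score(survey: pd.DataFrame, site: str, period: str) -> int:
    """Total floral units over all quadrats for one site and period.

    ``survey`` is tidy with columns site, period, quadrat_id, plant_species,
    floral_units (one floral unit per flower, or per umbel/spike for taxa
    counted that way).
    """
    sel = survey[(survey["site"] == site) & (survey["period"] == period)]
    return int(sel["floral_units"].sum())


def simulate_flower_survey(
    sites: Sequence[str],
    availability: Mapping[tuple[str, str], Mapping[str, float]],
    n_quadrats: int = 30,
    units_scale: float = 150.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Quadrat survey with Poisson floral-unit counts proportional to availability.

    Each site/period's expected total floral-unit score is ``units_scale``
    times a lognormal site/period factor, spread over the quadrats in
    proportion to normalised availability — emulating totals that range
    from a few tens to several hundred units and rise or fall between
    periods.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for site in sites:
        for period in synthetic.PERIODS:
            weights = availability[(site, period)]
            total_w = sum(weights.values()) or 1.0
            site_factor = rng.lognormal(0.0, 0.8)
            for q in range(1, n_quadrats + 1):
                for species, w in weights.items():
                    lam = units_scale * site_factor * w / (total_w * n_quadrats)
                    units = int(rng.poisson(lam))
                    if units > 0:
                        rows.append(
                            {
                                "site": site,
                                "period": period,
                                "quadrat_id": f"{site}_{period}_q{q:02d}",
                                "plant_species": species,
                                "floral_units": units,
                            }
                        )
    return pd.DataFrame(
        rows, columns=["site", "period", "quadrat_id", "plant_species", "floral_units"]
    )


def pooled_proportions(
    profiles: Sequence[assignment.PollenProfile],
    site: str,
    period: str,
    pool_threshold: float = 1.0,
) -> pd.DataFrame:
    """Site/period aggregate read percentages with minor taxa pooled.

    Taxa contributing ``pool_threshold`` percent or less of the aggregate
    (inclusive) are combined into an "others" category; percentages sum
    to 100 after pooling.
    """
    totals: dict[str, int] = {}
    for p in profiles:
        if p.excluded or p.site != site or p.period != period:
            continue
        for taxon, c in p.counts.items():
            totals[taxon] = totals.get(taxon, 0) + c
    grand = sum(totals.values())
    rows = []
    others = 0.0
    for taxon in sorted(totals, key=lambda t: (-totals[t], t)):
        pct = 100.0 * totals[taxon] / grand
        if pct <= pool_threshold:
            others += pct
        else:
            rows.append({"site": site, "period": period, "taxon": taxon, "percent": pct})
    if others > 0:
        rows.append({"site": site, "period": period, "taxon": "others", "percent": others})
    return pd.DataFrame(rows, columns=["site", "period", "taxon", "percent"])


def _availability_for(
    taxonomy: synthetic.TaxonomyTruth,
    sites: Sequence[str],
    rng: np.random.Generator,
) -> dict[tuple[str, str], dict[str, float]]:
    """Gamma-distributed plant availability varying by site and period.

    Late summer gets an independent draw with a higher scale, emulating the
    seasonal increase and turnover in flowering resources.
    """
    species = taxonomy.species_ids
    out: dict[tuple[str, str], dict[str, float]] = {}
    for site in sites:
        for period in synthetic.PERIODS:
            scale = 1.0 if period == "early" else 2.0
            w = rng.gamma(0.8, scale, len(species))
            # a few taxa not flowering at this site/period
            off = rng.random(len(species)) < 0.25
            w[off] = 0.0
            if w.sum() == 0:
                w[rng.integers(len(species))] = 1.0
            out[(site, period)] = dict(zip(species, w))
    return out


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and offending input."""


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Deterministic given the seed and inputs. Raises
    :class:`PipelineError` before any stage runs if a required input is
    missing.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # input validation up front
    if "assign" in config.stages and "simulate" not in config.stages:
        for name, path in (
            ("reads_r1", config.reads_r1),
            ("reads_r2", config.reads_r2),
            ("reference_fasta", config.reference_fasta),
            ("metadata_path", config.metadata_path),
        ):
            if path is None or not Path(path).exists():
                raise PipelineError(
                    f"stage 'assign': required input {name} missing ({path})"
                )

    rng = np.random.default_rng(config.seed)

    # ---- simulate -------------------------------------------------------
    if "simulate" in config.stages:
        sim_dir = out / "sim"
        sim_dir.mkdir(exist_ok=True)
        taxonomy = synthetic.generate_reference_db(
            config.n_families,
            config.genera_per_family,
            config.species_per_genus,
            synthetic.DivergenceParams(
                within_genus=config.within_genus_divergence,
                between_genus=config.between_genus_divergence,
                between_family=min(2 * config.between_genus_divergence, 0.99),
            ),
            seed=int(rng.integers(2**31)),
            amplicon_length=config.amplicon_length,
        )
        taxonomy.to_fasta(sim_dir / "reference.fasta")
        availability = _availability_for(taxonomy, config.sites, rng)

        mixtures = []
        for site in config.sites:
            for period in synthetic.PERIODS:
                n = (
                    config.n_insects_early
                    if period == "early"
                    else config.n_insects_late
                )
                sp_prob = (
                    config.specialist_prob_early
                    if period == "early"
                    else config.specialist_prob_late
                )
                mixtures.extend(
                    synthetic.generate_insects(
                        n,
                        site,
                        period,
                        specialist_prob=sp_prob,
                        availability=availability[(site, period)],
                        seed=int(rng.integers(2**31)),
                    )
                )
        sim_cfg = synthetic.ReadSimConfig(
            read_length=config.read_length,
            amplicon_length=config.amplicon_length,
            error_rate=config.error_rate,
            fixed_depth=config.fixed_depth,
        )
        fwd_all, rev_all, truths = [], [], []
        read_rng = np.random.default_rng(int(rng.integers(2**31)))
        for mix in mixtures:
            fwd, rev, truth = synthetic.generate_reads(
                mix, taxonomy, sim_cfg, rng=read_rng
            )
            fwd_all.extend(fwd)
            rev_all.extend(rev)
            truths.append(truth)
        seqio.write_fastq(fwd_all, sim_dir / "reads_R1.fastq")
        seqio.write_fastq(rev_all, sim_dir / "reads_R2.fastq")
        pd.concat(truths, ignore_index=True).to_csv(
            sim_dir / "truth.tsv", sep="\t", index=False
        )
        synthetic.mixtures_metadata(mixtures).to_csv(
            sim_dir / "metadata.tsv", sep="\t", index=False
        )
        survey = simulate_flower_survey(
            config.sites,
            availability,
            units_scale=200.0,
            seed=int(rng.integers(2**31)),
        )
        survey.to_csv(sim_dir / "flower_survey.tsv", sep="\t", index=False)
        config = dataclasses.replace(
            config,
            reads_r1=str(sim_dir / "reads_R1.fastq"),
            reads_r2=str(sim_dir / "reads_R2.fastq"),
            reference_fasta=str(sim_dir / "reference.fasta"),
            metadata_path=str(sim_dir / "metadata.tsv"),
        )
        log(
            f"simulate: {len(mixtures)} insects, {len(fwd_all)} read pairs, "
            f"{len(taxonomy.species_ids)} reference species"
        )

    # ---- assign ---------------------------------------------------------
    profiles: list[assignment.PollenProfile] = []
    if "assign" in config.stages:
        try:
            fwd = seqio.read_fastq(config.reads_r1)
            rev = seqio.read_fastq(config.reads_r2)
        except seqio.FastqParseError as exc:
            raise PipelineError(f"stage 'assign': {exc}") from exc
        if len(fwd) != len(rev):
            raise PipelineError(
                "stage 'assign': forward and reverse FASTQ differ in read count"
            )
        merged, unmerged_ids = [], []
        for f, r in zip(fwd, rev):
            f = seqio.quality_trim(f, config.quality_threshold, config.trim_window)
            r = seqio.quality_trim(r, config.quality_threshold, config.trim_window)
            if not f.bases or not r.bases:
                unmerged_ids.append(f.id or r.id)
                continue
            m = seqio.merge_pairs(
                f, r, config.min_overlap, config.max_mismatch_fraction
            )
            if m is None:
                unmerged_ids.append(f.id)
            else:
                merged.append(m)
        passing = seqio.length_filter(merged, config.min_length_exclusive)
        log(
            f"assign: {len(fwd)} pairs in = {len(merged)} merged + "
            f"{len(unmerged_ids)} unmerged; {len(passing)} passed "
            f">{config.min_length_exclusive} bp filter"
        )
        pd.DataFrame({"read_id": unmerged_ids}).to_csv(
            out / "unmerged_reads.tsv", sep="\t", index=False
        )
        seqio.write_fasta(passing, out / "merged_filtered.fasta")

        db = assignment.build_reference_index(config.reference_fasta, config.kmer_size)
        calls = assignment.assign_reads(
            passing,
            db,
            scoring=config.scoring(),
            top_n=config.top_n,
            genus_threshold=config.genus_threshold,
            family_threshold=config.family_threshold,
            report_bit_fraction=config.report_bit_fraction,
        )
        allowlist = None
        if config.allowlist_path:
            allowlist = {
                line.strip()
                for line in Path(config.allowlist_path).read_text().splitlines()
                if line.strip()
            }
        kept = assignment.filter_allowlist(calls, allowlist, db)
        pd.DataFrame(
            [
                {
                    "read_id": a.read_id,
                    "taxon": a.taxon_label,
                    "rank": a.rank,
                    "support": a.supporting_hit_fraction,
                }
                for a in kept
            ]
        ).to_csv(out / "assignments.tsv", sep="\t", index=False)
        n_unknown = sum(a.rank == "unknown" for a in kept)
        log(
            f"assign: {len(kept) - n_unknown} identified + {n_unknown} unknown "
            f"of {len(passing)} passing reads"
        )

        meta = pd.read_csv(config.metadata_path, sep="\t", dtype=str)
        by_insect: dict[str, list[assignment.TaxonAssignment]] = {}
        for a in kept:
            insect_id = a.read_id.rsplit("_r", 1)[0]
            by_insect.setdefault(insect_id, []).append(a)
        for _, row in meta.iterrows():
            profile = assignment.profile_insect(
                by_insect.get(row["insect_id"], []), row.to_dict()
            )
            profiles.append(profile)
        n_ok = sum(not p.excluded for p in profiles)
        log(f"assign: pollen recovered from {n_ok} out of {len(profiles)} insects")
        assignment.profiles_to_frame(profiles).to_csv(
            out / "profiles.tsv", sep="\t", index=False
        )

    if not profiles and (out / "profiles.tsv").exists():
        profiles = load_profiles(out / "profiles.tsv")

    site_periods = sorted({(p.site, p.period) for p in profiles if not p.excluded})

    # ---- networks -------------------------------------------------------
    if "networks" in config.stages and profiles:
        summaries = []
        for site, period in site_periods:
            mat = networks.build_interaction_matrix(
                profiles, site, period, config.presence_min_percent
            )
            mat.counts.to_csv(out / f"matrix_{site}_{period}.tsv", sep="\t")
            summaries.append(networks.network_summary(mat))
        metrics = pd.concat(summaries, ignore_index=True)
        metrics.to_csv(out / "network_metrics.tsv", sep="\t", index=False)
        log(f"networks: metrics for {len(site_periods)} site x period networks")

    # ---- classify -------------------------------------------------------
    if "classify" in config.stages and profiles:
        classifications = [
            specialisation.classify_individual(p, config.classify_threshold)
            for p in profiles
            if not p.excluded
        ]
        pd.DataFrame(
            [
                {
                    "insect_id": c.insect_id,
                    "insect_species": c.insect_species,
                    "sex": c.sex,
                    "site": c.site,
                    "period": c.period,
                    "top_taxon": c.top_taxon,
                    "top_percent": c.top_percent,
                    "visitor_class": c.visitor_class,
                    "tied_top": c.tied_top,
                }
                for c in classifications
            ]
        ).to_csv(out / "classifications.tsv", sep="\t", index=False)
        specialisation.classification_summary(
            classifications, thresholds=(config.classify_threshold, 60.0)
        ).to_csv(out / "classification_summary.tsv", sep="\t", index=False)
        table = pd.DataFrame(
            [
                {
                    "visitor_class": c.visitor_class,
                    "period": c.period,
                    "sex": c.sex,
                    "site": c.site,
                    "insect_species": c.insect_species,
                }
                for c in classifications
            ]
        )
        try:
            fit = specialisation.fit_binomial_glmm(table)
            coef = fit.coef_table()
            coef.to_csv(out / "glmm_coefficients.tsv", sep="\t", index=False)
            with open(out / "glmm_variances.tsv", "w") as fh:
                fh.write("component\tsd\n")
                fh.write(f"site\t{fit.site_sd}\n")
                fh.write(f"species\t{fit.species_sd}\n")
            log(
                "classify: GLMM period z = "
                f"{coef.loc[coef.term == 'period_late', 'z'].iloc[0]:.3f}"
            )
        except (specialisation.SeparationError, ValueError, np.linalg.LinAlgError) as exc:
            log(f"classify: GLMM skipped ({exc})")
        log(f"classify: {len(classifications)} insects classified")

    # ---- report ---------------------------------------------------------
    if "report" in config.stages and profiles:
        pooled = [
            pooled_proportions(profiles, site, period, config.pool_threshold)
            for site, period in site_periods
        ]
        pd.concat(pooled, ignore_index=True).to_csv(
            out / "pooled_proportions.tsv", sep="\t", index=False
        )
        survey_path = out / "sim" / "flower_survey.tsv"
        if survey_path.exists():
            survey = pd.read_csv(survey_path, sep="\t")
            scores = pd.DataFrame(
                [
                    {
                        "site": site,
                        "period": period,
                        "flower_unit_score": flower_unit_score(survey, site, period),
                    }
                    for site in sorted(survey["site"].unique())
                    for period in synthetic.PERIODS
                ]
            )
            scores.to_csv(out / "flower_unit_scores.tsv", sep="\t", index=False)
        log("report: pooled proportions and survey summaries written")

    (out / "pipeline_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def load_profiles(path: str | Path) -> list[assignment.PollenProfile]:
    """Rebuild :class:`PollenProfile` objects from a saved profiles TSV."""
    frame = pd.read_csv(path, sep="\t", dtype={"insect_id": str})
    profiles = []
    for insect_id, group in frame.groupby("insect_id", sort=True):
        first = group.iloc[0]
        counts = dict(zip(group["taxon"], group["count"].astype(int)))
        total = sum(counts.values())
        profiles.append(
            assignment.PollenProfile(
                insect_id=str(insect_id),
                insect_species=first["insect_species"],
                sex=first["sex"],
                site=first["site"],
                period=first["period"],
                counts=counts,
                percents={t: 100.0 * c / total for t, c in counts.items()},
                excluded=total == 0,
            )
        )
    return profiles
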