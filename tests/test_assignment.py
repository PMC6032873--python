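"""Reference indexing, hit scoring and consensus taxon calls."""

import math

import numpy as np
import pytest

from pollennet import assignment, synthetic
from pollennet.assignment import (
    Hit,
    ScoringConfig,
    assign_taxon,
    build_reference_index,
    filter_allowlist,
    profile_insect,
    score_hits,
    top_hits,
)
from tests.conftest import make_profile


def write_ref(tmp_path, entries, name="ref.fasta"):
    path = tmp_path / name
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path


class TestReferenceIndex:
    def test_every_kmer_indexed(self, tmp_path):
        rng = np.random.default_rng(0)
        entries = [
            (f"sp{i}|gen{i}|fam{i}", "".join(rng.choice(list("ACGT"), 40)))
            for i in range(3)
        ]
        db = build_reference_index(write_ref(tmp_path, entries), k=8)
        for header, seq in entries:
            sp = header.split("|")[0]
            for i in range(len(seq) - 8 + 1):
                assert sp in db.index[seq[i : i + 8]]

    def test_header_missing_rank_rejected(self, tmp_path):
        path = write_ref(tmp_path, [("sp1|gen1", "ACGTACGTACGT")])
        with pytest.raises(ValueError, match="header"):
            build_reference_index(path, k=4)

    def test_k_larger_than_shortest_reference_rejected(self, tmp_path):
        path = write_ref(tmp_path, [("sp1|g|f", "ACGTAC")])
        with pytest.raises(ValueError, match="k="):
            build_reference_index(path, k=8)

    def test_duplicate_id_rejected(self, tmp_path):
        path = write_ref(
            tmp_path, [("sp1|g|f", "ACGTACGTACGT"), ("sp1|g|f", "ACGTACGTACGT")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_reference_index(path, k=4)


class TestScoreHits:
    def test_identical_read_scores_full_length(self, taxonomy, ref_db):
        sp = taxonomy.species_ids[0]
        read = taxonomy.reference_sequences[sp]
        hits = score_hits(read, ref_db)
        assert hits[0].reference_id == sp
        assert hits[0].raw_score == 500
        expected_bit = (1.28 * 500 - math.log(0.46)) / math.log(2)
        assert hits[0].bit_score == pytest.approx(expected_bit, abs=1e-9)

    def test_single_central_mismatch_costs_three(self, taxonomy, ref_db):
        sp = taxonomy.species_ids[0]
        seq = list(taxonomy.reference_sequences[sp])
        seq[250] = "A" if seq[250] != "A" else "G"
        hits = score_hits("".join(seq), ref_db)
        best = {h.reference_id: h for h in hits}[sp]
        assert best.raw_score == 497  # 499 matches - 2 mismatch penalty

    def test_no_shared_kmer_empty_table(self, ref_db):
        # homopolymer shares no 8-mer with the random references
        assert score_hits("A" * 100, ref_db) == []

    def test_reporting_cutoff_thins_distant_hits(self, taxonomy, ref_db):
        sp = taxonomy.species_ids[0]
        read = taxonomy.reference_sequences[sp]
        all_hits = score_hits(read, ref_db, report_bit_fraction=0.0)
        reported = score_hits(read, ref_db)
        assert len(all_hits) == len(ref_db.records)
        assert len(reported) < len(all_hits)
        assert reported[0].reference_id == sp

    def test_short_read_rejected(self, ref_db):
        with pytest.raises(ValueError):
            score_hits("ACGT", ref_db)


def _hits(labels_scores):
    return [Hit(lab, s, float(s)) for lab, s in labels_scores]


class TestTopHits:
    def test_all_ties_retained(self):
        hits = _hits([(f"r{i}", 100) for i in range(25)])
        assert len(top_hits(hits, 20)) == 25

    def test_fewer_than_n(self):
        hits = _hits([(f"r{i}", 100 - i) for i in range(5)])
        assert len(top_hits(hits, 20)) == 5

    def test_distinct_scores_truncate_exactly(self):
        hits = _hits([(f"r{i:02d}", 100 - i) for i in range(25)])
        kept = top_hits(hits, 20)
        assert len(kept) == 20
        assert min(h.bit_score for h in kept) == 81


def _db_from(tmp_path, lineages):
    """Tiny db purely for lineage lookup: (species, genus, family) triples."""
    rng = np.random.default_rng(1)
    entries = [
        (f"{sp}|{gen}|{fam}", "".join(rng.choice(list("ACGT"), 30)))
        for sp, gen, fam in lineages
    ]
    return build_reference_index(write_ref(tmp_path, entries), k=8)


class TestAssignTaxon:
    @pytest.fixture
    def db(self, tmp_path):
        return _db_from(
            tmp_path,
            [(f"sp{i}", f"gen{i // 2}", f"fam{i // 4}") for i in range(20)],
        )

    def test_single_species_rule(self, db):
        hits = _hits([("sp0", 500)] * 20)
        call = assign_taxon(hits, db)
        assert (call.taxon_label, call.rank) == ("sp0", "species")
        assert call.supporting_hit_fraction == 1.0

    def test_genus_threshold_inclusive_at_60_percent(self, db):
        hits = _hits([("sp0", 500)] * 6 + [("sp1", 500)] * 6 + [("sp2", 500)] * 8)
        call = assign_taxon(hits, db)  # 12/20 = 60% in gen0
        assert (call.taxon_label, call.rank) == ("gen0", "genus")
        assert call.supporting_hit_fraction == pytest.approx(0.60)

    def test_below_genus_falls_to_family_consensus(self, db):
        # 11/20 = 55% gen0, but all 20 hits share fam0
        hits = _hits(
            [("sp0", 500)] * 6 + [("sp1", 500)] * 5 + [("sp2", 500)] * 9
        )
        call = assign_taxon(hits, db)
        assert (call.taxon_label, call.rank) == ("fam0", "family_tribe")

    def test_no_consensus_is_unknown(self, db):
        hits = _hits([(f"sp{i}", 500) for i in range(0, 20, 4)])  # 5 families
        call = assign_taxon(hits, db)
        assert call.rank == "unknown"

    def test_empty_table_unknown_zero_support(self, db):
        call = assign_taxon([], db, read_id="r")
        assert (call.rank, call.supporting_hit_fraction) == ("unknown", 0.0)

    def test_scale_free_under_hit_duplication(self, db):
        base = _hits([("sp0", 500)] * 3 + [("sp2", 500)] * 2)
        doubled = base + base
        a, b = assign_taxon(base, db), assign_taxon(doubled, db)
        assert (a.taxon_label, a.rank) == (b.taxon_label, b.rank)

    def test_bit_constants_affect_reporting_only(self, taxonomy, ref_db):
        """Any strictly monotone rescaling of raw scores keeps calls fixed."""
        sp = taxonomy.species_ids[0]
        read = taxonomy.reference_sequences[sp]
        calls = []
        for lam, k in ((1.28, 0.46), (0.7, 0.1)):
            sc = ScoringConfig(lambda_=lam, k=k)
            hits = top_hits(score_hits(read, ref_db, sc), 20)
            calls.append(assign_taxon(hits, ref_db))
        assert (calls[0].taxon_label, calls[0].rank) == (
            calls[1].taxon_label,
            calls[1].rank,
        )


class TestAllowlist:
    @pytest.fixture
    def db(self, tmp_path):
        return _db_from(
            tmp_path,
            [("spA", "genA", "famA"), ("spB", "genB", "famB")],
        )

    def test_species_off_list_removed(self, db):
        calls = [assignment.TaxonAssignment("r1", "spA", "species", 1.0)]
        assert filter_allowlist(calls, {"spB"}, db) == []

    def test_genus_on_list_retains_species_call(self, db):
        calls = [assignment.TaxonAssignment("r1", "spA", "species", 1.0)]
        assert filter_allowlist(calls, {"genA"}, db) == calls

    def test_disabled_filter_is_identity(self, db):
        calls = [assignment.TaxonAssignment("r1", "spA", "species", 1.0)]
        assert filter_allowlist(calls, None, db) == calls


class TestProfileInsect:
    META = {
        "insect_id": "i1",
        "insect_species": "E_tenax",
        "sex": "F",
        "site": "CAD",
        "period": "early",
    }

    def _calls(self, spec):
        return [
            assignment.TaxonAssignment(f"r{i}", taxon, rank, 1.0)
            for i, (taxon, rank) in enumerate(spec)
        ]

    def test_percent_arithmetic(self):
        calls = self._calls([("X", "species")] * 900 + [("Y", "species")] * 100)
        prof = profile_insect(calls, self.META)
        assert prof.percents == {"X": 90.0, "Y": 10.0}
        assert prof.counts == {"X": 900, "Y": 100}

    def test_only_unknowns_flagged_excluded(self):
        calls = self._calls([("unknown", "unknown")] * 5)
        prof = profile_insect(calls, self.META)
        assert prof.excluded and prof.percents == {}

    def test_single_taxon_is_100_percent(self):
        prof = profile_insect(self._calls([("X", "species")] * 7), self.META)
        assert prof.percents == {"X": 100.0}

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            profile_insect([], {"insect_id": "i1"})

    def test_percents_total_100(self):
        calls = self._calls(
            [("X", "species")] * 3 + [("Y", "genus")] * 4 + [("Z", "species")] * 6
        )
        prof = profile_insect(calls, self.META)
        assert sum(prof.percents.values()) == pytest.approx(100.0, abs=1e-6)


class TestEndToEndRecovery:
    def test_reads_recover_true_species(self, taxonomy, ref_db):
        """Error-bearing reads overwhelmingly map back to their source species."""
        rng = np.random.default_rng(7)
        cfg = synthetic.ReadSimConfig(fixed_depth=10, error_rate=0.005)
        correct = total = 0
        for sp in taxonomy.species_ids[:4]:
            mix = synthetic.SyntheticMixture(
                "i", "E_tenax", "F", "CAD", "early", {sp: 1.0}, True
            )
            fwd, rev, truth = synthetic.generate_reads(mix, taxonomy, cfg, rng=rng)
            from pollennet import seqio

            for f, r in zip(fwd, rev):
                merged = seqio.merge_pairs(f, r)
                hits = top_hits(score_hits(merged.bases, ref_db), 20)
                call = assign_taxon(hits, ref_db, read_id=f.id)
                total += 1
                correct += call.rank == "species" and call.taxon_label == sp
        assert correct / total >= 0.99

    def test_identical_references_resolve_at_genus(self, tmp_path):
        tax = synthetic.generate_reference_db(
            1, 1, 2, synthetic.DivergenceParams(0.0, 0.0, 0.0), seed=5
        )
        path = tmp_path / "twins.fasta"
        tax.to_fasta(path)
        db = build_reference_index(path)
        read = tax.reference_sequences[tax.species_ids[0]]
        call = assign_taxon(top_hits(score_hits(read, db), 20), db)
        assert call.rank == "genus"
        assert call.taxon_label == tax.taxa[0][1]
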