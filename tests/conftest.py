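import pytest

from pollennet import assignment, synthetic


@pytest.fixture(scope="session")
def taxonomy():
    """Small 4-family x 2-genus x 2-species reference library."""
    return synthetic.generate_reference_db(4, 2, 2, seed=11)


@pytest.fixture(scope="session")
def ref_db(taxonomy, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "reference.fasta"
    taxonomy.to_fasta(path)
    return assignment.build_reference_index(path)


def make_profile(
    insect_id="ins1",
    counts=None,
    insect_species="E_tenax",
    sex="F",
    site="CAD",
    period="early",
):
    counts = counts if counts is not None else {"X": 900, "Y": 100}
    total = sum(counts.values())
    return assignment.PollenProfile(
        insect_id=insect_id,
        insect_species=insect_species,
        sex=sex,
        site=site,
        period=period,
        counts=dict(counts),
        percents={t: 100.0 * c / total for t, c in counts.items()} if total else {},
        excluded=total == 0,
    )
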