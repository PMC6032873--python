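"""Interaction matrices and the H2'/d' specialisation indices."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pollennet import networks
from pollennet.networks import (
    InteractionMatrix,
    build_interaction_matrix,
    d_prime,
    enumerate_entropy_extremes,
    h2_bounds,
    h2_prime,
    network_summary,
    shannon_entropy,
)
from tests.conftest import make_profile


def im(array, rows=None, cols=None, **kw):
    a = np.asarray(array, dtype=int)
    rows = rows or [f"sp{i}" for i in range(a.shape[0])]
    cols = cols or [f"t{j}" for j in range(a.shape[1])]
    return InteractionMatrix(pd.DataFrame(a, index=rows, columns=cols), **kw)


class TestBuildMatrix:
    def test_counts_individuals(self):
        profiles = [
            make_profile("i1", {"X": 10}, insect_species="A"),
            make_profile("i2", {"X": 5}, insect_species="A"),
        ]
        mat = build_interaction_matrix(profiles, "CAD", "early")
        assert mat.counts.loc["A", "X"] == 2

    def test_presence_absence_ignores_abundance(self):
        profiles = [make_profile("i1", {"X": 99, "Y": 1}, insect_species="A")]
        mat = build_interaction_matrix(profiles, "CAD", "early")
        assert mat.counts.loc["A", "X"] == 1
        assert mat.counts.loc["A", "Y"] == 1

    def test_excluded_insect_contributes_nothing(self):
        profiles = [
            make_profile("i1", {}, insect_species="A"),
            make_profile("i2", {"X": 5}, insect_species="B"),
        ]
        mat = build_interaction_matrix(profiles, "CAD", "early")
        assert "A" not in mat.counts.index
        assert mat.m == 1

    def test_other_site_period_filtered(self):
        profiles = [make_profile("i1", {"X": 5}, site="LLC")]
        mat = build_interaction_matrix(profiles, "CAD", "early")
        assert mat.m == 0


class TestEntropy:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[1, 1], [1, 1]], np.log(4)),
            ([[4, 0], [0, 0]], 0.0),
            ([[2, 0], [0, 2]], np.log(2)),
        ],
    )
    def test_closed_forms(self, matrix, expected):
        assert shannon_entropy(np.array(matrix)) == pytest.approx(expected)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.zeros((2, 2)))


class TestBounds:
    def test_two_by_two_even_marginals(self):
        h2min, h2max = h2_bounds([2, 2], [2, 2])
        assert h2min == pytest.approx(np.log(2), abs=1e-12)
        assert h2max == pytest.approx(np.log(4), abs=1e-12)

    def test_single_cell_forced(self):
        assert h2_bounds([5], [5]) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_unit_marginals_all_permutations(self):
        # every matrix with unit marginals is a permutation matrix
        h2min, h2max = h2_bounds([1, 1, 1, 1], [1, 1, 1, 1])
        emin, emax = enumerate_entropy_extremes([1, 1, 1, 1], [1, 1, 1, 1])
        assert h2min == pytest.approx(emin, abs=1e-9)
        assert h2max == pytest.approx(emax, abs=1e-9)
        assert h2min == pytest.approx(np.log(4))

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(ValueError, match="marginals"):
            h2_bounds([2, 2], [3])

    def test_previously_hard_minimum(self):
        # marginals whose entropy minimum hides behind an uphill move
        h2min, _ = h2_bounds([4, 3], [3, 2, 2])
        emin, _ = enumerate_entropy_extremes([4, 3], [3, 2, 2])
        assert h2min == pytest.approx(emin, abs=1e-9)

    def test_large_network_bounds_bracket_observed(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 9, (6, 15))
        a[0, 0] += 1
        h2min, h2max = h2_bounds(a.sum(axis=1), a.sum(axis=0))
        h2 = shannon_entropy(a)
        assert h2min - 1e-9 <= h2 <= h2max + 1e-9


class TestH2Prime:
    def test_perfect_diagonal_fully_specialised(self):
        assert h2_prime(im([[2, 0], [0, 2]])).H2prime == pytest.approx(1.0)

    def test_uniform_fully_generalised(self):
        assert h2_prime(im([[1, 1], [1, 1]])).H2prime == pytest.approx(0.0)

    def test_degenerate_single_cell_is_zero(self):
        assert h2_prime(im([[7]])).H2prime == 0.0

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_diagonal_any_size(self, n):
        assert h2_prime(im(3 * np.eye(n, dtype=int))).H2prime == pytest.approx(1.0)

    def test_rows_proportional_to_columns_generalised(self):
        a = np.outer([1, 2, 3], [2, 1, 1])  # p_ij = row x col product
        assert h2_prime(im(a)).H2prime == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, (3, 4))
        a[0, 0] += 1
        base = h2_prime(im(a)).H2prime
        perm = h2_prime(im(a[np.argsort(rng.random(3))][:, np.argsort(rng.random(4))]))
        assert perm.H2prime == pytest.approx(base, abs=1e-9)


class TestDPrime:
    def test_row_matching_availability_no_exclusivity(self):
        spec = d_prime(im([[1, 1], [1, 1]]), "sp0")
        assert spec.d == pytest.approx(0.0)
        assert spec.dprime == pytest.approx(0.0)

    def test_exclusive_diagonal_row(self):
        spec = d_prime(im([[2, 0], [0, 2]]), "sp0")
        assert spec.d == pytest.approx(np.log(2))
        assert spec.dmax == pytest.approx(np.log(2))
        assert spec.dmin == pytest.approx(0.0)
        assert spec.dprime == pytest.approx(1.0)

    def test_clipped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 6, (3, 4))
            a[a.sum(axis=1) == 0, 0] += 1
            mat = im(a)
            for sp in mat.counts.index:
                assert 0.0 <= d_prime(mat, sp).dprime <= 1.0

    def test_zero_row_undefined(self):
        with pytest.raises(ValueError, match="no interactions"):
            d_prime(im([[0, 0], [1, 1]]), "sp0")

    def test_concentration_on_rare_partner_raises_d(self):
        # moving a generalist row onto its rarest partner increases KL
        spread = d_prime(im([[2, 2], [1, 7]]), "sp0").d
        concentrated = d_prime(im([[4, 0], [1, 7]]), "sp0").d
        assert concentrated > spread

    def test_dmin_allocation_matches_enumeration(self):
        # brute-force the best integer allocation for a small row total
        a = np.array([[3, 1], [1, 5]])
        mat = im(a)
        q = a.sum(axis=0) / a.sum()
        A = 4
        best = min(
            (
                sum(
                    (n / A) * np.log((n / A) / qj)
                    for n, qj in zip((k, A - k), q)
                    if n > 0
                )
                for k in range(A + 1)
            )
        )
        assert d_prime(mat, "sp0").dmin == pytest.approx(best, abs=1e-12)


class TestEnumerationOracle:
    @pytest.mark.parametrize(
        "rows,cols,expected",
        [
            ((2, 2), (2, 2), (np.log(2), np.log(4))),
            ((1, 1), (1, 1), (np.log(2), np.log(2))),
            ((4,), (4,), (0.0, 0.0)),
        ],
    )
    def test_known_extremes(self, rows, cols, expected):
        emin, emax = enumerate_entropy_extremes(rows, cols)
        assert emin == pytest.approx(expected[0], abs=1e-12)
        assert emax == pytest.approx(expected[1], abs=1e-12)

    def test_refuses_above_cap(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_entropy_extremes([10, 3], [7, 6])


class TestSummary:
    def test_species_level_table(self):
        profiles = [
            make_profile("i1", {"X": 9, "Y": 1}, insect_species="A"),
            make_profile("i2", {"X": 5}, insect_species="B"),
        ]
        mat = build_interaction_matrix(profiles, "CAD", "early")
        table = network_summary(mat)
        assert set(table["species"]) == {"A", "B"}
        assert (table["H2prime"] >= 0).all() and (table["H2prime"] <= 1).all()
        assert table.loc[table.species == "A", "n"].iloc[0] == 2

    def test_empty_matrix_empty_table(self):
        mat = build_interaction_matrix([], "CAD", "early")
        assert network_summary(mat).empty
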