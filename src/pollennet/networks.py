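"""Bipartite pollen-transport networks and specialisation indices H2' and d'.

The interaction matrix for one site and period counts, for each
insect-species row i and plant-taxon column j, the number of individual
insects of species i that carried taxon j (presence/absence per
individual, ignoring read abundance). From the matrix:

* H2, the two-dimensional Shannon entropy of the interaction
  probabilities p_ij = a_ij / m, is standardised between the extremes
  attainable with the observed marginal totals to give the network-level
  specialisation index H2' in [0, 1] (0 = complete generalisation,
  1 = complete specialisation);
* d, the Kullback-Leibler divergence of a species' interaction
  proportions from overall partner availability q_j = C_j / m, is
  standardised between its integer-allocation minimum and the ceiling
  ln(m / A_i) to give the species-level exclusivity index d' in [0, 1].

An exhaustive enumerator over all integer matrices with given marginals
(feasible for m <= 12) serves as the exact oracle for the heuristic
entropy bounds.
"""

from __future__ import annotations

import dataclasses
import heapq
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from pollennet.assignment import PollenProfile

ENUMERATION_CAP = 12


@dataclasses.dataclass
class InteractionMatrix:
    """Insect-species x plant-taxon interaction counts for one site/period."""

    counts: pd.DataFrame  # rows: insect species, cols: plant taxa, ints
    site: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and ((arr < 0).any() or not np.issubdtype(arr.dtype, np.integer)):
            raise ValueError("interaction counts must be nonnegative integers")

    @property
    def a(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def m(self) -> int:
        return int(self.a.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.a.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.a.sum(axis=0)


@dataclasses.dataclass
class NetworkSpecialisation:
    H2: float
    H2min: float
    H2max: float
    H2prime: float


@dataclasses.dataclass
class SpeciesSpecialisation:
    species: str
    d: float
    dmin: float
    dmax: float
    dprime: float
    n_interactions: int


def build_interaction_matrix(
    profiles: Sequence[PollenProfile],
    site: str,
    period: str,
    presence_min_percent: float = 0.0,
) -> InteractionMatrix:
    """Tally individuals carrying each taxon, per insect species.

    A profile contributes one interaction for every taxon present above
    ``presence_min_percent`` percent of its identified reads. Excluded
    insects (no identified reads) and profiles from other site/periods
    contribute nothing.
    """
    tallies: dict[tuple[str, str], int] = {}
    for p in profiles:
        if p.excluded or p.site != site or p.period != period:
            continue
        for taxon, pct in p.percents.items():
            if pct > presence_min_percent:
                key = (p.insect_species, taxon)
                tallies[key] = tallies.get(key, 0) + 1
    if not tallies:
        return InteractionMatrix(pd.DataFrame(dtype=int), site=site, period=period)
    rows = sorted({k[0] for k in tallies})
    cols = sorted({k[1] for k in tallies})
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (sp, taxon), n in tallies.items():
        mat.loc[sp, taxon] = n
    return InteractionMatrix(mat, site=site, period=period)


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of a nonnegative count array; 0 ln 0 = 0."""
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_entropy(matrix: InteractionMatrix | np.ndarray) -> float:
    """Two-dimensional Shannon entropy H2 = -sum p_ij ln p_ij."""
    a = matrix.a if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    if a.sum() == 0:
        raise ValueError("entropy undefined for an empty matrix (m = 0)")
    return _entropy(a.ravel().astype(float))


def _check_marginals(row_totals: np.ndarray, col_totals: np.ndarray) -> int:
    if row_totals.sum() != col_totals.sum():
        raise ValueError(
            f"inconsistent marginals: rows sum {row_totals.sum()}, "
            f"cols sum {col_totals.sum()}"
        )
    if (row_totals < 0).any() or (col_totals < 0).any():
        raise ValueError("marginals must be nonnegative")
    m = int(row_totals.sum())
    if m == 0:
        raise ValueError("marginals sum to zero")
    return m


def _max_fill(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Near-proportional integer fill maximising entropy under the marginals.

    Cells start at floor(A_i C_j / m); the remaining units are placed one at
    a time in the feasible cell lying furthest below its expected value
    A_i C_j / m, keeping the table as even as the integer constraint allows.
    """
    m = row_totals.sum()
    expected = np.outer(row_totals, col_totals) / m
    a = np.floor(expected).astype(np.int64)
    row_rem = row_totals - a.sum(axis=1)
    col_rem = col_totals - a.sum(axis=0)
    while row_rem.sum() > 0:
        rows = np.flatnonzero(row_rem > 0)
        cols = np.flatnonzero(col_rem > 0)
        deficit = expected[np.ix_(rows, cols)] - a[np.ix_(rows, cols)]
        ri, ci = np.unravel_index(np.argmax(deficit), deficit.shape)
        i, j = rows[ri], cols[ci]
        a[i, j] += 1
        row_rem[i] -= 1
        col_rem[j] -= 1
    return a


def _min_fill(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Greedy concentration: repeatedly saturate the largest remaining marginals."""
    row_rem = row_totals.astype(np.int64).copy()
    col_rem = col_totals.astype(np.int64).copy()
    a = np.zeros((len(row_totals), len(col_totals)), dtype=np.int64)
    while row_rem.sum() > 0:
        i = int(np.argmax(row_rem))
        j = int(np.argmax(col_rem))
        placed = min(row_rem[i], col_rem[j])
        a[i, j] += placed
        row_rem[i] -= placed
        col_rem[j] -= placed
    return a


def _refine(a: np.ndarray, maximise: bool) -> np.ndarray:
    """Polish a table by 2x2 transfer moves that improve its entropy.

    A transfer of t units along cells (i,j)->(i,j') and (i',j')->(i',j)
    preserves both marginals. Entropy is concave along such a line, so for
    maximisation single-unit steps suffice, while for minimisation the best
    move is at an extreme of the feasible range; both are tried to a
    fixpoint.
    """
    a = a.copy()
    n_rows, n_cols = a.shape
    improved = True
    while improved:
        improved = False
        best_h = _entropy(a.ravel())
        for i, i2 in itertools.combinations(range(n_rows), 2):
            for j, j2 in itertools.combinations(range(n_cols), 2):
                # moving t > 0: a[i,j]-t, a[i,j2]+t, a[i2,j]+t, a[i2,j2]-t
                for sign in (1, -1):
                    if sign == 1:
                        limit = min(a[i, j], a[i2, j2])
                    else:
                        limit = min(a[i, j2], a[i2, j])
                    if limit == 0:
                        continue
                    steps = (1,) if maximise else (limit,)
                    for t in steps:
                        b = a.copy()
                        b[i, j] -= sign * t
                        b[i2, j2] -= sign * t
                        b[i, j2] += sign * t
                        b[i2, j] += sign * t
                        h = _entropy(b.ravel())
                        if (maximise and h > best_h + 1e-12) or (
                            not maximise and h < best_h - 1e-12
                        ):
                            a, best_h = b, h
                            improved = True
    return a


def _min_entropy_vertices(row_totals: np.ndarray, col_totals: np.ndarray) -> float:
    """Exact minimum entropy over matrices with the given marginals.

    Entropy is concave over the transportation polytope, so its minimum is
    attained at a vertex; every vertex arises from some order of saturating
    placements (place min(remaining row, remaining col), drop whichever is
    exhausted). The recursion searches all such orders with memoisation on
    the reduced marginal multisets. Feasible only for small networks.
    """
    m = float(row_totals.sum())
    cache: dict[tuple, float] = {}

    def g(v: int) -> float:
        return -(v / m) * np.log(v / m) if v else 0.0

    def best(rows: tuple[int, ...], cols: tuple[int, ...]) -> float:
        if not rows or not cols:
            return 0.0
        key = (rows, cols)
        if key in cache:
            return cache[key]
        out = np.inf
        seen: set[tuple[int, int]] = set()
        for ri, r in enumerate(rows):
            for ci, c in enumerate(cols):
                if (r, c) in seen:  # identical marginal pairs are symmetric
                    continue
                seen.add((r, c))
                t = min(r, c)
                new_rows = list(rows)
                new_cols = list(cols)
                if r <= c:
                    new_rows.pop(ri)
                if c <= r:
                    new_cols.pop(ci)
                if r > c:
                    new_rows[ri] = r - t
                if c > r:
                    new_cols[ci] = c - t
                val = g(t) + best(
                    tuple(sorted(new_rows)), tuple(sorted(new_cols))
                )
                if val < out:
                    out = val
        cache[key] = out
        return out

    return best(
        tuple(sorted(int(r) for r in row_totals if r > 0)),
        tuple(sorted(int(c) for c in col_totals if c > 0)),
    )


#: exact vertex-search minimum is used up to this many total interactions
#: (and at most 6x6 marginals); larger networks fall back to the greedy
#: concentration heuristic with 2x2 transfer polishing
EXACT_MIN_CAP = 40


def h2_bounds(
    row_totals: Sequence[int], col_totals: Sequence[int]
) -> tuple[float, float]:
    """Entropy extremes (H2min, H2max) attainable with the given marginals.

    H2max comes from a near-proportional even fill polished by
    marginal-preserving 2x2 transfer moves. H2min is exact (vertex search)
    for small networks and falls back to greedy concentration plus the same
    polishing for large ones.
    """
    rows = np.asarray(row_totals, dtype=np.int64)
    cols = np.asarray(col_totals, dtype=np.int64)
    m = _check_marginals(rows, cols)
    h2max = _entropy(_refine(_max_fill(rows, cols), maximise=True).ravel())
    if m <= EXACT_MIN_CAP and len(rows) <= 6 and len(cols) <= 6:
        h2min = _min_entropy_vertices(rows, cols)
    else:
        h2min = _entropy(_refine(_min_fill(rows, cols), maximise=False).ravel())
    return h2min, h2max


def h2_prime(matrix: InteractionMatrix | np.ndarray) -> NetworkSpecialisation:
    """Standardised network specialisation H2' in [0, 1]."""
    a = matrix.a if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    h2 = shannon_entropy(a)
    h2min, h2max = h2_bounds(a.sum(axis=1), a.sum(axis=0))
    if h2max - h2min <= 1e-12:
        prime = 0.0
    else:
        prime = float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))
    return NetworkSpecialisation(H2=h2, H2min=h2min, H2max=h2max, H2prime=prime)


def _dmin_allocation(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` units over partners minimising KL from q.

    The objective is separable and convex in each partner's count, so the
    greedy unit-by-unit allocation (always add where the marginal cost is
    lowest) is exact.
    """
    n = np.zeros(len(q), dtype=np.int64)
    # marginal cost of raising partner j from c to c+1:
    #   (c+1)ln(c+1) - c ln c - ln(total * q_j)
    heap = [(0.0 - np.log(total * qj), j) for j, qj in enumerate(q) if qj > 0]
    heapq.heapify(heap)
    for _ in range(total):
        _, j = heapq.heappop(heap)
        c = n[j]
        n[j] += 1
        c2 = c + 1
        cost = (c2 + 1) * np.log(c2 + 1) - c2 * np.log(c2) - np.log(total * q[j])
        heapq.heappush(heap, (cost, j))
    return n


def d_prime(
    matrix: InteractionMatrix, species_row: str
) -> SpeciesSpecialisation:
    """Standardised species-level exclusivity d' for one insect-species row.

    d is the KL divergence of the row's interaction proportions from the
    overall partner availability q; dmax = ln(m / A_i); dmin is the
    divergence of the best integer allocation of the row total across
    partners. Species absent from the period (A_i = 0) are undefined.
    """
    a = matrix.a
    i = list(matrix.counts.index).index(species_row)
    row = a[i].astype(float)
    A_i = row.sum()
    if A_i == 0:
        raise ValueError(f"species {species_row!r} has no interactions")
    m = a.sum()
    q = a.sum(axis=0) / m
    p = row / A_i
    nz = p > 0
    d = float((p[nz] * np.log(p[nz] / q[nz])).sum())
    dmax = float(np.log(m / A_i))
    nmin = _dmin_allocation(int(A_i), q)
    pmin = nmin / A_i
    nzm = pmin > 0
    dmin = float((pmin[nzm] * np.log(pmin[nzm] / q[nzm])).sum())
    if dmax - dmin <= 1e-12:
        prime = 0.0
    else:
        prime = float(np.clip((d - dmin) / (dmax - dmin), 0.0, 1.0))
    return SpeciesSpecialisation(
        species=species_row,
        d=d,
        dmin=dmin,
        dmax=dmax,
        dprime=prime,
        n_interactions=int(A_i),
    )


def network_summary(matrix: InteractionMatrix) -> pd.DataFrame:
    """Tidy site/period metrics table: H2' plus per-species d'."""
    rows = []
    if matrix.m > 0:
        net = h2_prime(matrix)
        for sp in matrix.counts.index:
            if matrix.counts.loc[sp].sum() == 0:
                continue  # absent species are omitted, not reported as 0
            spec = d_prime(matrix, sp)
            rows.append(
                {
                    "site": matrix.site,
                    "period": matrix.period,
                    "H2prime": net.H2prime,
                    "species": sp,
                    "n": spec.n_interactions,
                    "dprime": spec.dprime,
                }
            )
    return pd.DataFrame(
        rows, columns=["site", "period", "H2prime", "species", "n", "dprime"]
    )


def enumerate_entropy_extremes(
    row_totals: Sequence[int], col_totals: Sequence[int]
) -> tuple[float, float]:
    """Exact entropy extremes by exhaustive enumeration (test oracle).

    Enumerates every nonnegative integer matrix with the given marginals;
    refuses above m = 12 where the enumeration explodes.
    """
    rows = np.asarray(row_totals, dtype=np.int64)
    cols = np.asarray(col_totals, dtype=np.int64)
    m = _check_marginals(rows, cols)
    if m > ENUMERATION_CAP:
        raise ValueError(f"enumeration capped at m={ENUMERATION_CAP}, got {m}")

    n_cols = len(cols)
    best_min, best_max = np.inf, -np.inf

    def fill(row_idx: int, col_rem: tuple[int, ...], cells: list[int]) -> None:
        nonlocal best_min, best_max
        if row_idx == len(rows):
            h = _entropy(np.array(cells, dtype=float))
            best_min = min(best_min, h)
            best_max = max(best_max, h)
            return
        target = rows[row_idx]

        def compositions(j: int, remaining: int, row: list[int]) -> None:
            if j == n_cols - 1:
                if remaining <= col_rem[j]:
                    yield_row = row + [remaining]
                    new_rem = tuple(
                        col_rem[c] - yield_row[c] for c in range(n_cols)
                    )
                    fill(row_idx + 1, new_rem, cells + yield_row)
                return
            for v in range(min(remaining, col_rem[j]) + 1):
                compositions(j + 1, remaining - v, row + [v])

        compositions(0, int(target), [])

    fill(0, tuple(int(c) for c in cols), [])
    return float(best_min), float(best_max)
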