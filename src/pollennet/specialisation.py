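"""Individual-level specialisation: single- vs multi-plant visitors.

An individual insect is a "single-plant visitor" when its dominant pollen
taxon accounts for at least 90% of its identified reads (inclusive), a
threshold chosen because heterospecific carry-over and windblown pollen
make perfectly pure loads unrealistic. The binary classification is then
modelled against seasonal period and sex with a logistic mixed-effects
model carrying crossed Gaussian random intercepts for site and insect
species, fitted by maximising the Laplace-approximated marginal
likelihood (the standard single-node adaptive Gauss-Hermite scheme of
mixed-model software).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.stats import norm

from pollennet.assignment import PollenProfile

SINGLE_PLANT_THRESHOLD = 90.0

#: fixed-effect coding, so signs are interpretable
PERIOD_CODES = {"early": 0.0, "late": 1.0}
SEX_CODES = {"F": 0.0, "M": 1.0}


class SeparationError(RuntimeError):
    """Raised when the response is degenerate (complete separation)."""


@dataclasses.dataclass
class VisitorClassification:
    insect_id: str
    top_taxon: str
    top_percent: float
    visitor_class: str  # "single" | "multi"
    threshold_percent: float = SINGLE_PLANT_THRESHOLD
    tied_top: bool = False
    # carried metadata for modelling
    insect_species: str = ""
    sex: str = ""
    site: str = ""
    period: str = ""


@dataclasses.dataclass
class GlmmFit:
    """Fixed effects, Wald tests and variance components of the fitted model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    site_sd: float
    species_sd: float
    loglik: float
    converged: bool

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )


def classify_individual(
    profile: PollenProfile, threshold_percent: float = SINGLE_PLANT_THRESHOLD
) -> VisitorClassification:
    """Classify one insect by its dominant pollen taxon (inclusive threshold).

    Ties for the top taxon are broken lexicographically and flagged.
    """
    if profile.excluded or not profile.percents:
        raise ValueError(
            f"profile {profile.insect_id!r} has no identified reads"
        )
    top_pct = max(profile.percents.values())
    tied = [t for t, p in profile.percents.items() if p == top_pct]
    return VisitorClassification(
        insect_id=profile.insect_id,
        top_taxon=min(tied),
        top_percent=top_pct,
        visitor_class="single" if top_pct >= threshold_percent else "multi",
        threshold_percent=threshold_percent,
        tied_top=len(tied) > 1,
        insect_species=profile.insect_species,
        sex=profile.sex,
        site=profile.site,
        period=profile.period,
    )


def classification_summary(
    classifications: Sequence[VisitorClassification],
    thresholds: Sequence[float] = (90.0, 60.0),
) -> pd.DataFrame:
    """Per-period counts/percentages at each dominance threshold, plus decile bins.

    Returns a tidy frame with rows of kind ``threshold`` (count and percent
    of insects whose top taxon is at/above the threshold) and kind
    ``decile`` (histogram of top-taxon percentages in 10-point bins,
    mirroring the usual presentation of individual constancy).
    """
    rows = []
    by_period: dict[str, list[VisitorClassification]] = {}
    for c in classifications:
        by_period.setdefault(c.period, []).append(c)
    for period in sorted(by_period):
        group = by_period[period]
        n = len(group)
        for thr in thresholds:
            k = sum(c.top_percent >= thr for c in group)
            rows.append(
                {
                    "period": period,
                    "kind": "threshold",
                    "bin": f">={thr:g}",
                    "count": k,
                    "n": n,
                    "percent": 100.0 * k / n if n else float("nan"),
                }
            )
        for lo in range(0, 100, 10):
            hi = lo + 10
            # top bin inclusive of 100%
            k = sum(
                lo <= c.top_percent < hi or (hi == 100 and c.top_percent == 100)
                for c in group
            )
            rows.append(
                {
                    "period": period,
                    "kind": "decile",
                    "bin": f"{lo}-{hi}",
                    "count": k,
                    "n": n,
                    "percent": 100.0 * k / n if n else float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["period", "kind", "bin", "count", "n", "percent"]
    )


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build y, X and the two random-effect indicator matrices."""
    y = np.asarray(
        [1.0 if v in (1, True, "single") else 0.0 for v in table["visitor_class"]]
    )
    period = np.asarray([PERIOD_CODES[v] for v in table["period"]])
    sex = np.asarray([SEX_CODES[v] for v in table["sex"]])
    X = np.column_stack([np.ones(len(table)), period, sex])
    sites = pd.Categorical(table["site"])
    species = pd.Categorical(table["insect_species"])
    Z_site = sparse.coo_matrix(
        (np.ones(len(table)), (np.arange(len(table)), sites.codes))
    ).toarray()
    Z_species = sparse.coo_matrix(
        (np.ones(len(table)), (np.arange(len(table)), species.codes))
    ).toarray()
    return y, X, Z_site, Z_species


def _logistic_irls(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-12, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Plain logistic regression by Newton iteration (the variance-zero model)."""
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1 / (1 + np.exp(-eta))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    return beta, np.sqrt(np.diag(cov)), ll, converged


def _laplace_loglik(
    beta: np.ndarray,
    sigmas: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    n_levels: tuple[int, int],
) -> float:
    """Laplace-approximate marginal log-likelihood at given fixed effects/SDs."""
    q = Z.shape[1]
    var = np.concatenate(
        [np.full(n_levels[0], sigmas[0] ** 2), np.full(n_levels[1], sigmas[1] ** 2)]
    )
    prec = 1.0 / np.maximum(var, 1e-12)
    b = np.zeros(q)
    for _ in range(100):  # Newton for the conditional mode of b
        eta = X @ beta + Z @ b
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = Z.T @ (y - mu) - prec * b
        H = Z.T @ (Z * W[:, None]) + np.diag(prec)
        step = np.linalg.solve(H, grad)
        b = b + step
        if np.abs(step).max() < 1e-10:
            break
    eta = X @ beta + Z @ b
    mu = 1 / (1 + np.exp(-eta))
    ll_cond = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    W = mu * (1 - mu)
    H = Z.T @ (Z * W[:, None]) + np.diag(prec)
    sign, logdet_H = np.linalg.slogdet(H)
    logdet_prec = float(np.sum(np.log(prec)))
    # marginal ll = ll(y|b̂) − ½ b̂'Λ⁻¹b̂ + ½ log det Λ⁻¹ − ½ log det H
    return ll_cond - 0.5 * float(b @ (prec * b)) + 0.5 * logdet_prec - 0.5 * logdet_H


def fit_binomial_glmm(
    table: pd.DataFrame,
    fix_variances_to_zero: bool = False,
) -> GlmmFit:
    """Fit single- vs multi-plant class against period and sex.

    ``table`` needs columns visitor_class ("single"/"multi"), period
    ("early"/"late"), sex ("F"/"M"), site and insect_species. Random
    intercepts for site and species are crossed, not nested. With
    ``fix_variances_to_zero`` the model reduces exactly to ordinary
    logistic regression (fitted by Newton iteration).
    """
    for col in ("visitor_class", "period", "sex", "site", "insect_species"):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
    y, X, Z_site, Z_species = _design(table)
    terms = ["intercept", "period_late", "sex_male"]
    if len(set(y)) < 2:
        raise SeparationError("all responses identical; model is separated")
    for j, name in ((1, "period"), (2, "sex")):
        if len(set(X[:, j])) < 2:
            raise ValueError(f"fixed effect {name!r} has a single level")

    if fix_variances_to_zero:
        beta, se, ll, conv = _logistic_irls(y, X)
        z = beta / se
        return GlmmFit(
            terms=terms,
            beta=beta,
            se=se,
            z=z,
            p=2 * norm.sf(np.abs(z)),
            site_sd=0.0,
            species_sd=0.0,
            loglik=ll,
            converged=conv,
        )

    Z = np.hstack([Z_site, Z_species])
    n_levels = (Z_site.shape[1], Z_species.shape[1])
    beta0, _, _, _ = _logistic_irls(y, X)

    def negll(params: np.ndarray) -> float:
        beta = params[:3]
        sigmas = np.exp(params[3:])
        return -_laplace_loglik(beta, sigmas, y, X, Z, n_levels)

    x0 = np.concatenate([beta0, np.log([0.5, 0.5])])
    res = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None)] * 3 + [(np.log(1e-4), np.log(20.0))] * 2,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[:3]
    sigmas = np.exp(res.x[3:])

    # Wald SEs from the curvature of the Laplace log-likelihood in beta
    def nll_beta(b: np.ndarray) -> float:
        return -_laplace_loglik(b, sigmas, y, X, Z, n_levels)

    h = 1e-4
    k = len(beta)
    H = np.zeros((k, k))
    f0 = nll_beta(beta)
    for a in range(k):
        for c in range(a, k):
            ea = np.zeros(k)
            ec = np.zeros(k)
            ea[a] = h
            ec[c] = h
            H[a, c] = H[c, a] = (
                nll_beta(beta + ea + ec)
                - nll_beta(beta + ea)
                - nll_beta(beta + ec)
                + f0
            ) / h**2
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = beta / se
    return GlmmFit(
        terms=terms,
        beta=beta,
        se=se,
        z=z,
        p=2 * norm.sf(np.abs(z)),
        site_sd=float(sigmas[0]),
        species_sd=float(sigmas[1]),
        loglik=float(-res.fun),
        converged=bool(res.success),
    )


def simulate_classification_data(
    n: int = 400,
    beta: Sequence[float] = (-0.5, 1.0, 0.0),
    site_sd: float = 0.5,
    species_sd: float = 0.5,
    n_sites: int = 4,
    n_species: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a classification table from the mixed logistic model.

    ``beta`` is (intercept, period effect with late = 1, sex effect with
    male = 1) on the log-odds scale; used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    sites = [f"S{i + 1}" for i in range(n_sites)]
    species = [f"sp{i + 1}" for i in range(n_species)]
    u_site = rng.normal(0, site_sd, n_sites)
    u_species = rng.normal(0, species_sd, n_species)
    site_idx = rng.integers(0, n_sites, n)
    sp_idx = rng.integers(0, n_species, n)
    period = rng.integers(0, 2, n)
    sex = rng.integers(0, 2, n)
    eta = (
        beta[0]
        + beta[1] * period
        + beta[2] * sex
        + u_site[site_idx]
        + u_species[sp_idx]
    )
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame(
        {
            "insect_id": [f"ins{i}" for i in range(n)],
            "visitor_class": np.where(y, "single", "multi"),
            "period": np.where(period == 1, "late", "early"),
            "sex": np.where(sex == 1, "M", "F"),
            "site": [sites[i] for i in site_idx],
            "insect_species": [species[i] for i in sp_idx],
        }
    )
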