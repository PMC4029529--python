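"""Synthetic genotype/phenotype generator and power-study driver.

Emulates a population-cohort GWAS panel: independent loci in Hardy-Weinberg
equilibrium, binary traits at ~9-13% prevalence with pairwise correlations
around 0.3-0.5, age/sex/BMI-like covariates, and an embedded two-locus
penetrance-model interaction.  Correlated binary occasions come from a
shared latent Gaussian factor (exchangeable latent correlation) thresholded
per subject so each marginal hits its penetrance-implied probability; the
latent correlation can be calibrated numerically to a target binary (phi)
correlation.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .gee import fit_null_model, residual_scores
from .gmdr import (cross_validate, enumerate_combinations, run_gmdr_analysis,
                   select_best_model)
from .io import CovariateTable, GenotypeMatrix, PhenotypePanel


def hwe_weights(maf: float) -> np.ndarray:
    """Genotype frequencies ((1-f)^2, 2f(1-f), f^2) under HWE."""
    f = float(maf)
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])


# ---------------------------------------------------------------------------
# penetrance models
# ---------------------------------------------------------------------------

@dataclass
class PenetranceModel:
    """P(trait | genotype cell) table over the 3^k cells of k causal loci.

    ``loci`` are column indices into the simulated genotype matrix.  For the
    gaussian family the table holds cell mean shifts instead of
    probabilities.
    """

    loci: tuple
    table: np.ndarray
    marginal_effects: bool = False

    def __post_init__(self):
        self.loci = tuple(int(l) for l in self.loci)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3,) * len(self.loci):
            raise ValueError("table must have shape (3,)*k")

    def cell_values(self, dosages: np.ndarray) -> np.ndarray:
        """Per-subject table value given the causal-locus dosage columns."""
        idx = tuple(dosages[:, j].astype(int) for j in range(dosages.shape[1]))
        return self.table[idx]


def marginal_penetrances(table: np.ndarray, maf: float):
    """Allele-frequency-weighted single-locus penetrance margins."""
    w = hwe_weights(maf)
    row = (table * w[None, :]).sum(axis=1)     # margin over locus 2
    col = (table * w[:, None]).sum(axis=0)     # margin over locus 1
    return row, col


def pure_epistasis_table(maf: float = 0.3, prevalence: float = 0.13,
                         relative_risk: float = 2.0, n_iter: int = 400,
                         tol: float = 1e-10) -> np.ndarray:
    """Two-locus checkerboard penetrance with (numerically) flat margins.

    Starts from an XOR-like pattern — cells with an odd dosage sum carry
    ``relative_risk`` times the risk of even cells at overall prevalence
    ``prevalence`` — then iteratively rescales rows and columns (IPF) until
    both HWE-weighted single-locus margins equal the prevalence, leaving a
    pure interaction with no marginal effects.
    """
    w = hwe_weights(maf)
    odd = (np.add.outer(np.arange(3), np.arange(3)) % 2).astype(float)
    w_hi = float((np.outer(w, w) * odd).sum())
    p_lo = prevalence / (relative_risk * w_hi + (1 - w_hi))
    table = np.where(odd > 0, relative_risk * p_lo, p_lo)
    for _ in range(n_iter):
        row, _ = marginal_penetrances(table, maf)
        table = table * (prevalence / row)[:, None]
        _, col = marginal_penetrances(table, maf)
        table = table * (prevalence / col)[None, :]
        row, col = marginal_penetrances(table, maf)
        if max(abs(row - prevalence).max(), abs(col - prevalence).max()) < tol:
            break
    if table.max() >= 1.0 or table.min() <= 0.0:
        raise ValueError("penetrance table left (0,1); lower the relative "
                         "risk or prevalence")
    return table


# ---------------------------------------------------------------------------
# latent-threshold correlation calibration
# ---------------------------------------------------------------------------

def binary_corr_from_latent(rho: float, prevalence: float) -> float:
    """Phi correlation of two equal-margin binaries from latent corr rho."""
    if rho >= 1.0:
        return 1.0
    z = ndtri(prevalence)
    p11 = float(stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([z, z]))
    return (p11 - prevalence ** 2) / (prevalence * (1 - prevalence))


def latent_corr_for_binary(target: float, prevalence: float) -> float:
    """Invert :func:`binary_corr_from_latent` by root finding."""
    lo, hi = -0.999, 0.999
    flo = binary_corr_from_latent(lo, prevalence) - target
    fhi = binary_corr_from_latent(hi, prevalence) - target
    if flo * fhi > 0:
        raise ValueError(
            f"binary correlation {target} infeasible at prevalence "
            f"{prevalence}; feasible range is "
            f"[{binary_corr_from_latent(lo, prevalence):.3f}, "
            f"{binary_corr_from_latent(hi, prevalence):.3f}]")
    return float(optimize.brentq(
        lambda r: binary_corr_from_latent(r, prevalence) - target, lo, hi,
        xtol=1e-6))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default probit-scale covariate effects (applied to standardized values).
DEFAULT_COVARIATE_EFFECTS = {"age": 0.25, "sex": 0.15, "bmi": 0.20}


@dataclass
class SimConfig:
    """Study-condition bundle for one synthetic dataset.

    Defaults emulate the cohort setting the package targets: binary traits
    at 13% prevalence, two occasions with binary correlation ~0.35, MAF-0.3
    loci, and (when ``penetrance`` is set) a shared two-locus interaction.
    ``rho`` is the latent exchangeable correlation; when None it is
    calibrated so the binary phi correlation hits ``target_corr``.
    """

    n: int = 1000
    n_loci: int = 10
    maf: object = 0.3
    t: int = 2
    family: str = "binomial"
    prevalence: float = 0.13
    target_corr: float = 0.35
    rho: float | None = None
    penetrance: PenetranceModel | None = None
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    seed: int = 0

    def maf_vector(self) -> np.ndarray:
        m = np.asarray(self.maf, dtype=float)
        if m.ndim == 0:
            m = np.full(self.n_loci, float(m))
        if not ((m > 0) & (m <= 0.5)).all():
            raise ValueError("MAFs must lie in (0, 0.5]")
        return m

    def latent_rho(self) -> float:
        if self.rho is not None:
            r = float(self.rho)
        elif self.family == "binomial":
            r = latent_corr_for_binary(self.target_corr, self.prevalence)
        else:
            r = float(self.target_corr)
        if self.t > 1 and r < -1.0 / (self.t - 1):
            raise ValueError(f"exchangeable correlation {r} not positive "
                             f"definite for t={self.t} (needs >= "
                             f"{-1.0 / (self.t - 1):.3f})")
        return r


def default_epistasis_scenario(**overrides) -> SimConfig:
    """Shared pure two-locus interaction at MAF 0.3, prevalence 0.13, RR ~2."""
    cfg = SimConfig(**overrides)
    if cfg.penetrance is None:
        m = cfg.maf_vector()
        cfg = replace(cfg, penetrance=PenetranceModel(
            (0, 1), pure_epistasis_table(float(m[0]), cfg.prevalence, 2.0)))
    return cfg


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genotypes(n: int, maf_vector, seed=0) -> GenotypeMatrix:
    """Independent HWE loci: dosage ~ Binomial(2, MAF), no missingness."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng([int(seed), 0])
    mafs = np.asarray(maf_vector, dtype=float)
    if not ((mafs >= 0) & (mafs <= 0.5)).all():
        raise ValueError("MAFs must lie in [0, 0.5]")
    d = rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)
    ids = [f"S{i:05d}" for i in range(n)]
    loci = [f"L{j:03d}" for j in range(len(mafs))]
    return GenotypeMatrix.from_dosages(ids, loci, d)


def _simulate_covariates(n: int, rng) -> tuple[CovariateTable, np.ndarray]:
    """Age/sex/BMI-like covariates; returns the table and standardized block."""
    age = rng.normal(51.4, 8.8, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(24.4, 3.1, n)
    Z = CovariateTable(
        [f"S{i:05d}" for i in range(n)],
        ["intercept", "age", "sex", "bmi"],
        np.column_stack([np.ones(n), age, sex, bmi]), True)
    zstd = np.column_stack([(age - 51.4) / 8.8, sex - 0.5,
                            (bmi - 24.4) / 3.1])
    return Z, zstd


def simulate_phenotypes(G: GenotypeMatrix, config: SimConfig):
    """Generate (PhenotypePanel, CovariateTable) for simulated genotypes.

    Binomial: per-subject success probability on the probit scale combines
    the penetrance-cell effect and covariate effects, recentred so the
    population prevalence matches ``config.prevalence``; occasions share one
    latent factor with exchangeable latent correlation.  Gaussian: linear
    cell/covariate effects plus exchangeable-correlated unit-variance noise.
    The cell effect is shared across occasions.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    n, t = G.n_subjects, config.t
    Z, zstd = _simulate_covariates(n, rng)
    Z = CovariateTable(G.subject_ids, Z.names, Z.values, True)
    eff = config.covariate_effects or {}
    gamma = np.array([eff.get("age", 0.0), eff.get("sex", 0.0),
                      eff.get("bmi", 0.0)])
    lin = zstd @ gamma

    if config.penetrance is not None:
        cols = np.asarray(config.penetrance.loci)
        cell_val = config.penetrance.cell_values(G.dosages[:, cols])
    else:
        cell_val = np.full(n, config.prevalence if config.family == "binomial"
                           else 0.0)

    if config.family == "gaussian" and config.rho is None:
        # shared covariate effects already correlate occasions; set the
        # error correlation so the total phenotype correlation hits target
        v = float(lin.var())
        rho = config.target_corr * (1 + v) - v
        if t > 1 and rho < -1.0 / (t - 1):
            raise ValueError("target correlation infeasible given covariate "
                             "effects")
    else:
        rho = config.latent_rho()
    e = rng.standard_normal((n, t))
    R = (1 - rho) * np.eye(t) + rho * np.ones((t, t))
    L = e @ np.linalg.cholesky(R).T

    if config.family == "binomial":
        q = ndtri(np.clip(cell_val, 1e-12, 1 - 1e-12)) + lin

        def mean_prev(d):
            return ndtr(q + d).mean() - config.prevalence

        try:
            d = optimize.brentq(mean_prev, -8.0, 8.0, xtol=1e-10)
        except ValueError as exc:
            raise ValueError(
                "prevalence target infeasible for the given penetrance and "
                "covariate effects") from exc
        tau = ndtri(np.clip(ndtr(q + d), 1e-12, 1 - 1e-12))
        y = (L < tau[:, None]).astype(float)
    elif config.family == "gaussian":
        y = cell_val[:, None] + lin[:, None] + L
    else:
        raise ValueError(f"unknown family {config.family!r}")

    occ = [f"occ{j + 1}" for j in range(t)]
    P = PhenotypePanel(G.subject_ids, occ, y, config.family,
                       np.zeros_like(y, dtype=bool))
    return P, Z


def simulate_dataset(config: SimConfig):
    """One-call (G, P, Z) generation, bit-reproducible per (config, seed)."""
    mafs = config.maf_vector()
    G = simulate_genotypes(config.n, mafs, config.seed)
    P, Z = simulate_phenotypes(G, config)
    return G, P, Z


# ---------------------------------------------------------------------------
# power / type-I studies
# ---------------------------------------------------------------------------

def _analyse_rep(G, P, Z, order, n_folds, cv_seed, structure):
    fit = fit_null_model(P, Z, structure=structure)
    scores = residual_scores(fit, P)
    combos = enumerate_combinations(G.locus_ids, order)
    results = cross_validate(G, scores, combos, n_folds=n_folds, seed=cv_seed)
    best = select_best_model(results)
    return best, {r.combination: r for r in results}


def run_power_study(scenarios, reps: int = 50, seed: int = 0,
                    n_folds: int = 10, order: int = 2,
                    progress=None) -> pd.DataFrame:
    """Selection power and test-BA stability, multivariate vs univariate.

    For each scenario and replicate, runs multivariate GMDR on all
    occasions jointly and univariate GMDR per occasion over all k-locus
    models.  Power is the fraction of replicates in which the planted pair
    is the selected best model; for null scenarios (no penetrance) power is
    reported as nan and the test-BA distribution is the object of interest.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    master = np.random.default_rng(seed)
    rows = []
    for s_idx, cfg in enumerate(scenarios):
        planted = (frozenset(f"L{j:03d}" for j in cfg.penetrance.loci)
                   if cfg.penetrance is not None else None)
        t = cfg.t
        hits = {m: [] for m in ["multivariate"] + [f"univariate_occ{j+1}"
                                                   for j in range(t)]}
        bas = {m: [] for m in hits}
        cvcs = {m: [] for m in hits}
        fold_sds = {m: [] for m in hits}
        for rep in range(reps):
            child = int(master.integers(2 ** 31))
            G, P, Z = simulate_dataset(replace(cfg, seed=child))
            structure = "exchangeable" if t > 1 else "independence"
            best, by_combo = _analyse_rep(G, P, Z, order, n_folds, child,
                                          structure)
            _record(hits, bas, cvcs, fold_sds, "multivariate", best,
                    by_combo, planted)
            for j in range(t):
                bj, byj = _analyse_rep(G, P.occasion(j), Z, order, n_folds,
                                       child, "independence")
                _record(hits, bas, cvcs, fold_sds, f"univariate_occ{j+1}",
                        bj, byj, planted)
            if progress is not None:
                progress(s_idx, rep)
        for m in hits:
            rows.append({
                "scenario": s_idx, "method": m, "n": cfg.n, "reps": reps,
                "order": order,
                "power": (float(np.mean(hits[m])) if planted is not None
                          else np.nan),
                "median_planted_cvc": (float(np.median(cvcs[m]))
                                       if planted is not None else np.nan),
                "mean_test_ba": float(np.mean(bas[m])),
                "sd_test_ba": float(np.std(bas[m], ddof=1)) if reps > 1
                              else np.nan,
                "mean_fold_sd_test_ba": float(np.mean(fold_sds[m])),
            })
    return pd.DataFrame(rows)


def _record(hits, bas, cvcs, fold_sds, method, best, by_combo, planted):
    """Per-replicate bookkeeping for one analysis route.

    ``mean_fold_sd_test_ba`` averages the across-fold SD of the selected
    model's test BA: the within-study spread of the fold-level test BAs,
    which is the distribution the method's stability claim is about.
    """
    bas[method].append(best.mean_test_ba)
    fold_sds[method].append(float(np.nanstd(best.test_ba, ddof=1)))
    if planted is not None:
        hits[method].append(float(frozenset(best.combination) == planted))
        key = next((c for c in by_combo if frozenset(c) == planted), None)
        cvcs[method].append(by_combo[key].cvc if key is not None else 0)
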