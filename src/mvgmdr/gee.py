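"""Marginal GLM/GEE engine and residual prediction scores.

Fits the marginal model g(mu_i) = X_i beta + Z_i gamma for a subjects x
occasions outcome panel, where the working covariance of the t outcomes of a
subject is V_i = phi * B_i^{1/2} R(alpha) B_i^{1/2} with B_i the diagonal
variance-function matrix and R(alpha) a working correlation (independence,
exchangeable or unstructured).  Estimation iterates a Fisher-scoring update
of the regression coefficients (canonical links, so d mu/d delta = B C) with
moment re-estimation of alpha and phi from Pearson residuals.

Under the null model of no genetic effect (covariates only), each subject's
residual score vector is

    S*_i = B_hat_i V_hat_i^{-1} (y_i - mu_hat_i),

and the per-subject prediction score is its within-subject sum
S_i = sum_j S_ij.  These scores drive the multivariate GMDR cell labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy import special, stats

from .io import CovariateTable, PhenotypePanel

# numerical policy
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 50
ALPHA_EPS = 1e-4        # keep R(alpha) strictly positive definite
ETA_MAX = 30.0          # linear-predictor clip for the logit link
PHI_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    """Raised for degenerate fits (separation, constant binary outcome)."""


class SingularityError(np.linalg.LinAlgError):
    """Raised when a working covariance or information matrix is singular."""


# ---------------------------------------------------------------------------
# family and working-correlation specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Exponential-family spec with canonical link.

    ``variance`` is the variance function b''(theta) evaluated at the mean;
    ``phi_fixed_default`` says whether the dispersion is held at 1 by
    convention (binomial) or estimated (gaussian).
    """

    name: str
    link: Callable[[np.ndarray], np.ndarray]
    inv_link: Callable[[np.ndarray], np.ndarray]
    variance: Callable[[np.ndarray], np.ndarray]
    phi_fixed_default: bool


BINOMIAL = FamilySpec(
    "binomial", special.logit, special.expit,
    lambda mu: mu * (1.0 - mu), phi_fixed_default=True)
GAUSSIAN = FamilySpec(
    "gaussian", lambda x: x, lambda x: x,
    lambda mu: np.ones_like(mu), phi_fixed_default=False)

_FAMILIES = {"binomial": BINOMIAL, "gaussian": GAUSSIAN,
             "binomial-logit": BINOMIAL, "gaussian-identity": GAUSSIAN}


def get_family(name) -> FamilySpec:
    if isinstance(name, FamilySpec):
        return name
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}") from None


@dataclass
class WorkingCorrelation:
    """Working correlation R(alpha) of the t occasions.

    ``alpha`` is None for independence, a scalar for exchangeable, and a
    t x t matrix for unstructured.
    """

    structure: str
    alpha: object
    t: int

    def matrix(self) -> np.ndarray:
        if self.structure == "independence":
            return np.eye(self.t)
        if self.structure == "exchangeable":
            a = float(self.alpha)
            return (1.0 - a) * np.eye(self.t) + a * np.ones((self.t, self.t))
        if self.structure == "unstructured":
            return np.asarray(self.alpha, dtype=float)
        raise ValueError(f"unknown structure {self.structure!r}")


# ---------------------------------------------------------------------------
# fitted-model containers
# ---------------------------------------------------------------------------

@dataclass
class GEEFit:
    """Estimates for delta = (beta, gamma) with robust/model covariances."""

    params: np.ndarray
    names: list
    n_beta: int                  # leading genotype coefficients
    cov_model: np.ndarray
    cov_robust: np.ndarray
    phi: float
    working_corr: WorkingCorrelation
    family: str
    effect_structure: str | None
    converged: bool
    n_iter: int
    mu: np.ndarray = field(repr=False, default=None)

    @property
    def beta(self) -> np.ndarray:
        return self.params[: self.n_beta]

    @property
    def gamma(self) -> np.ndarray:
        return self.params[self.n_beta:]

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_robust if robust else self.cov_model
        return np.sqrt(np.diag(cov))


@dataclass
class NullModelFit:
    """Null-model (no genetic effect) fit used to produce prediction scores."""

    gamma: np.ndarray
    names: list
    mu_hat: np.ndarray            # n x t fitted means (defined everywhere)
    phi: float
    working_corr: WorkingCorrelation
    family: str
    cov_model: np.ndarray
    cov_robust: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class ScoreSet:
    """Per-occasion residual scores and their within-subject sums."""

    subject_ids: np.ndarray
    per_occasion: np.ndarray      # n x t, nan at missing occasions
    aggregated: np.ndarray        # length n row sums over observed occasions

    def __post_init__(self):
        agg = np.nansum(np.nan_to_num(self.per_occasion, nan=0.0), axis=1)
        if not np.allclose(agg, self.aggregated, rtol=0, atol=0):
            raise ValueError("aggregated scores must equal per-occasion row sums")


class WaldTest(NamedTuple):
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# moment estimators
# ---------------------------------------------------------------------------

def estimate_dispersion_and_alpha(residuals: np.ndarray, structure: str,
                                  ddof: int = 0):
    """Moment estimators (phi_hat, alpha_hat) from a Pearson-residual matrix.

    phi_hat = sum r^2 / (N_obs - ddof).  Exchangeable alpha_hat averages
    within-subject cross-products of standardized residuals over the total
    pair count (minus ddof), divided by phi_hat, clipped so R stays positive
    definite.  Unstructured alpha is the full residual correlation matrix
    (complete data only).
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    obs = ~np.isnan(r)
    t = r.shape[1]
    n_obs = int(obs.sum())
    rz = np.nan_to_num(r, nan=0.0)
    phi = float((rz ** 2).sum() / max(n_obs - ddof, 1))
    phi_guard = max(phi, PHI_FLOOR)

    if structure == "independence":
        return phi, None
    if structure == "exchangeable":
        if t < 2:
            raise ValueError("exchangeable correlation undefined for t=1")
        rowsum = rz.sum(axis=1)
        num = float(((rowsum ** 2) - (rz ** 2).sum(axis=1)).sum() / 2.0)
        m = obs.sum(axis=1)
        pairs = float((m * (m - 1) / 2.0).sum())
        alpha = num / (max(pairs - ddof, 1.0) * phi_guard)
        lo = -1.0 / (t - 1) + ALPHA_EPS
        alpha = float(np.clip(alpha, lo, 1.0 - ALPHA_EPS))
        return phi, alpha
    if structure == "unstructured":
        if t < 2:
            raise ValueError("unstructured correlation undefined for t=1")
        if not obs.all():
            raise ValueError("unstructured correlation requires complete occasions")
        n = r.shape[0]
        R = (rz.T @ rz) / (max(n - ddof, 1) * phi_guard)
        d = np.sqrt(np.clip(np.diag(R), PHI_FLOOR, None))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        R = (R + R.T) / 2.0
        # shrink toward identity if numerically indefinite
        w = np.linalg.eigvalsh(R)
        if w.min() < ALPHA_EPS:
            lam = (ALPHA_EPS - w.min()) / (1.0 - w.min())
            R = (1 - lam) * R + lam * np.eye(t)
        return phi, R
    raise ValueError(f"unknown structure {structure!r}")


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def _pattern_groups(obs: np.ndarray):
    """Group subjects by observed-occasion pattern for block-wise algebra."""
    uniq, inv = np.unique(obs, axis=0, return_inverse=True)
    groups = []
    for g, pattern in enumerate(uniq):
        cols = np.flatnonzero(pattern)
        if cols.size == 0:
            continue
        groups.append((cols, np.flatnonzero(inv == g)))
    return groups


def _accumulate(A, r, groups, R):
    """H = sum A_i' Rinv A_i,  u = sum A_i' Rinv r_i,  per-subject scores."""
    p = A.shape[2]
    H = np.zeros((p, p))
    u = np.zeros(p)
    n = A.shape[0]
    subj_scores = np.zeros((n, p))
    for cols, idx in groups:
        Rsub = R[np.ix_(cols, cols)]
        try:
            Rinv = np.linalg.inv(Rsub)
        except np.linalg.LinAlgError as e:
            raise SingularityError("working correlation block is singular") from e
        Asub = A[np.ix_(idx, cols)]
        rsub = r[np.ix_(idx, cols)]
        T1 = np.einsum("nmp,ms->nsp", Asub, Rinv)
        H += np.einsum("nsp,nsq->pq", T1, Asub)
        s = np.einsum("nsp,ns->np", T1, rsub)
        subj_scores[idx] = s
        u += s.sum(axis=0)
    return H, u, subj_scores


def _solve_gee(y, obs, X, family: FamilySpec, structure: str,
               estimate_phi: bool, tol: float, max_iter: int):
    n, t = y.shape
    p = X.shape[2]
    groups = _pattern_groups(obs)
    n_obs = int(obs.sum())
    q = p
    if n_obs <= p:
        raise ValueError("more parameters than observations")
    yobs = y[obs]
    if family.name == "binomial" and (yobs == yobs[0]).all():
        raise ConvergenceError("binary outcome is constant; model is separated")
    Xstack = X[obs]
    if np.linalg.matrix_rank(Xstack) < p:
        raise ValueError("design matrix is rank deficient")

    yz = np.where(obs, y, 0.0)
    delta = np.zeros(p)
    phi, alpha = 1.0, None
    R = np.eye(t)
    n_iter = 0
    converged = False

    def state(delta):
        eta = np.einsum("ntp,p->nt", X, delta)
        eta = np.clip(eta, -ETA_MAX, ETA_MAX)
        mu = family.inv_link(eta)
        b = family.variance(mu)
        b = np.clip(b, PHI_FLOOR, None)
        sb = np.sqrt(b)
        r = np.where(obs, (yz - mu) / sb, 0.0)
        A = sb[:, :, None] * X
        return mu, b, sb, r, A

    # phase 1: independence fit (the GLM fit for t=1), used as initialization
    # phase 2: iterate with the requested working correlation
    for phase_structure in (["independence"] if structure == "independence"
                            else ["independence", structure]):
        for _ in range(max_iter):
            mu, b, sb, r, A = state(delta)
            if phase_structure != "independence":
                rmat = np.where(obs, r, np.nan)
                phi_m, alpha = estimate_dispersion_and_alpha(
                    rmat, phase_structure, ddof=q)
                if estimate_phi:
                    phi = max(phi_m, PHI_FLOOR)
                R = WorkingCorrelation(phase_structure, alpha, t).matrix()
            else:
                R = np.eye(t)
            H, u, _ = _accumulate(A, r, groups, R)
            try:
                step = np.linalg.solve(H, u)
            except np.linalg.LinAlgError as e:
                raise SingularityError("information matrix is singular") from e
            delta = delta + step
            n_iter += 1
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        else:
            converged = False
        if not converged:
            break

    mu, b, sb, r, A = state(delta)
    if family.name == "binomial":
        muo = mu[obs]
        if (muo < 1e-10).any() or (muo > 1 - 1e-10).any():
            raise ConvergenceError(
                "fitted probabilities pinned to 0/1 (separation)")
    rmat = np.where(obs, r, np.nan)
    if structure == "independence":
        phi_m, alpha = estimate_dispersion_and_alpha(rmat, "independence",
                                                     ddof=q)
        R = np.eye(t)
    else:
        phi_m, alpha = estimate_dispersion_and_alpha(rmat, structure, ddof=q)
        R = WorkingCorrelation(structure, alpha, t).matrix()
    phi = max(phi_m, PHI_FLOOR) if estimate_phi else 1.0

    H, u, subj_scores = _accumulate(A, r, groups, R)
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as e:
        raise SingularityError("information matrix is singular") from e
    meat = subj_scores.T @ subj_scores
    cov_model = phi * Hinv
    cov_robust = Hinv @ meat @ Hinv
    corr = WorkingCorrelation(structure, alpha, t)
    return delta, cov_model, cov_robust, phi, corr, converged, n_iter, mu


# ---------------------------------------------------------------------------
# public fitting operations
# ---------------------------------------------------------------------------

def _build_design(Z: CovariateTable, t: int, genotype=None,
                  effect_structure: str = "heterogeneous"):
    """Stacked (n, t, p) design with genotype block first, then covariates."""
    n, qz = Z.values.shape
    Zblk = np.broadcast_to(Z.values[:, None, :], (n, t, qz))
    names = list(Z.names)
    if genotype is None:
        return np.ascontiguousarray(Zblk), names, 0
    g = np.asarray(genotype, dtype=float)
    if g.shape != (n,):
        raise ValueError("genotype must be a length-n dosage vector")
    if effect_structure == "heterogeneous":
        Xg = np.zeros((n, t, t))
        for j in range(t):
            Xg[:, j, j] = g
        gnames = [f"geno[occ{j}]" for j in range(t)]
    elif effect_structure == "homogeneous":
        Xg = np.broadcast_to(g[:, None, None], (n, t, 1)).copy()
        gnames = ["geno"]
    else:
        raise ValueError(f"unknown effect_structure {effect_structure!r}")
    X = np.concatenate([Xg, Zblk], axis=2)
    return X, gnames + names, Xg.shape[2]


def fit_marginal_model(P: PhenotypePanel, Z: CovariateTable | None = None,
                       family=None, structure: str = "exchangeable",
                       genotype=None, effect_structure: str = "heterogeneous",
                       estimate_phi: bool | None = None,
                       tol: float = DEFAULT_TOL,
                       max_iter: int = DEFAULT_MAX_ITER) -> GEEFit:
    """Fit the marginal model, optionally with a genotype effect block.

    With ``structure='independence'`` and t=1 this reproduces the ordinary
    GLM maximum-likelihood fit.  Non-convergence is reported via the
    ``converged`` flag; separation and constant binary outcomes raise
    :class:`ConvergenceError`.
    """
    fam = get_family(family if family is not None else P.family)
    if Z is None:
        Z = CovariateTable.intercept_only(P.subject_ids)
    if Z.n_subjects != P.n_subjects:
        raise ValueError("covariates and phenotypes are not aligned")
    if estimate_phi is None:
        estimate_phi = not fam.phi_fixed_default
    t = P.n_occasions
    X, names, n_beta = _build_design(Z, t, genotype, effect_structure)
    obs = ~P.missing_mask
    if genotype is not None and np.isnan(np.asarray(genotype, float)).any():
        raise ValueError("genotype vector contains missing values; restrict "
                         "subjects first")
    delta, cov_m, cov_r, phi, corr, conv, n_iter, mu = _solve_gee(
        np.nan_to_num(P.y, nan=0.0), obs, X, fam, structure,
        estimate_phi, tol, max_iter)
    return GEEFit(delta, names, n_beta if genotype is not None else 0,
                  cov_m, cov_r, phi, corr, fam.name,
                  effect_structure if genotype is not None else None,
                  conv, n_iter, mu)


def fit_null_model(P: PhenotypePanel, Z: CovariateTable | None = None,
                   family=None, structure: str = "exchangeable",
                   estimate_phi: bool | None = None,
                   tol: float = DEFAULT_TOL,
                   max_iter: int = DEFAULT_MAX_ITER) -> NullModelFit:
    """Fit the covariates-only null model (no genetic effect) for scoring."""
    fit = fit_marginal_model(P, Z, family=family, structure=structure,
                             genotype=None, estimate_phi=estimate_phi,
                             tol=tol, max_iter=max_iter)
    return NullModelFit(fit.params, fit.names, fit.mu, fit.phi,
                        fit.working_corr, fit.family, fit.cov_model,
                        fit.cov_robust, fit.converged, fit.n_iter)


def residual_scores(fit: NullModelFit, P: PhenotypePanel) -> ScoreSet:
    """Residual score vectors S*_i = B_hat V_hat^{-1}(y_i - mu_hat_i).

    Writing V = phi B^{1/2} R B^{1/2}, the per-occasion scores reduce to
    phi^{-1} B^{1/2} R^{-1} r_i with r_i the Pearson residual vector; subjects
    with partial occasions use the corresponding submatrices of R.  The
    aggregated prediction score is the within-subject sum of the observed
    occasions.
    """
    if not fit.converged:
        raise ConvergenceError("null model did not converge; scores undefined")
    fam = get_family(fit.family)
    obs = ~P.missing_mask
    mu = fit.mu_hat
    b = np.clip(fam.variance(mu), PHI_FLOOR, None)
    sb = np.sqrt(b)
    r = np.where(obs, (np.nan_to_num(P.y, nan=0.0) - mu) / sb, 0.0)
    if fit.working_corr.structure == "independence":
        # B V^{-1} collapses to phi^{-1} I: scores are plain residuals
        per = np.where(obs, (np.nan_to_num(P.y, nan=0.0) - mu) / fit.phi,
                       np.nan)
        aggregated = np.nansum(np.nan_to_num(per, nan=0.0), axis=1)
        return ScoreSet(P.subject_ids, per, aggregated)
    R = fit.working_corr.matrix()
    per = np.full(P.y.shape, np.nan)
    for cols, idx in _pattern_groups(obs):
        Rsub = R[np.ix_(cols, cols)]
        try:
            Rinv = np.linalg.inv(Rsub)
        except np.linalg.LinAlgError as e:
            raise SingularityError(
                f"singular working covariance for subject "
                f"{P.subject_ids[idx[0]]!r}") from e
        rsub = r[np.ix_(idx, cols)]
        per[np.ix_(idx, cols)] = (sb[np.ix_(idx, cols)] *
                                  (rsub @ Rinv.T)) / fit.phi
    aggregated = np.nansum(np.nan_to_num(per, nan=0.0), axis=1)
    return ScoreSet(P.subject_ids, per, aggregated)


def wald_test_genetic_effect(fit: GEEFit) -> WaldTest:
    """Joint Wald test of the genotype block using the sandwich covariance."""
    if fit.n_beta == 0:
        raise ValueError("fit has no genotype block")
    beta = fit.beta
    cov = fit.cov_robust[: fit.n_beta, : fit.n_beta]
    if not np.all(np.isfinite(cov)) or np.linalg.cond(cov) > 1e12:
        raise SingularityError("robust covariance of the genetic block is "
                               "singular")
    stat = float(beta @ np.linalg.solve(cov, beta))
    df = fit.n_beta
    return WaldTest(stat, df, float(stats.chi2.sf(stat, df)))
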