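"""Combinatorial GMDR engine: cell labelling, balanced accuracy, CV search.

For a candidate combination of k loci, subjects are binned into the 3^k
multi-locus genotype cells.  A cell is labelled high-risk when the sum of
the subjects' prediction scores in that cell exceeds a threshold T0
(default 0; strictly greater-than, so a zero sum is low-risk).  Model
quality is measured by balanced accuracy against pseudo-case status
(positive prediction score), and the final model among all enumerated
combinations is chosen by cross-validation consistency (CVC), then mean
test BA, then lexicographic order.

With a single binary trait, an intercept-only null model and dispersion
fixed at 1, the scores are y_i - ybar and the cell rule reproduces
classical MDR with threshold T = n_cases/n_controls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gee import ScoreSet, fit_null_model, residual_scores
from .io import CovariateTable, GenotypeMatrix, PhenotypePanel

HIGH, LOW, EMPTY = 1, 0, -1

LocusCombination = tuple  # ordered tuple of distinct locus ids


# ---------------------------------------------------------------------------
# enumeration and cell labelling
# ---------------------------------------------------------------------------

def enumerate_combinations(locus_ids, k: int) -> list:
    """All C(p, k) k-locus combinations in lexicographic (input) order."""
    locus_ids = list(locus_ids)
    if k <= 0:
        raise ValueError("combination order k must be >= 1")
    if k > len(locus_ids):
        raise ValueError("k exceeds the number of loci")
    return [tuple(c) for c in itertools.combinations(locus_ids, k)]


def cell_codes(dosages: np.ndarray) -> np.ndarray:
    """Map each subject's k dosages to a cell index in [0, 3^k); -1 = missing."""
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    k = d.shape[1]
    valid = ~np.isnan(d).any(axis=1)
    codes = np.full(d.shape[0], -1, dtype=np.int64)
    if valid.any():
        weights = 3 ** np.arange(k)
        codes[valid] = (d[valid].astype(np.int64) * weights).sum(axis=1)
    return codes


@dataclass
class RiskModel:
    """High/low/empty labelling of the 3^k genotype cells of a combination."""

    combination: LocusCombination
    labels: np.ndarray           # length 3^k, values in {HIGH, LOW, EMPTY}
    threshold: float
    cell_sums: np.ndarray
    cell_counts: np.ndarray
    trained_on: object = None

    @property
    def cell_labels(self) -> dict:
        """Map genotype tuple -> 'high' | 'low' | 'empty'."""
        k = len(self.combination)
        out = {}
        names = {HIGH: "high", LOW: "low", EMPTY: "empty"}
        for code, lab in enumerate(self.labels):
            cell = tuple((code // 3 ** j) % 3 for j in range(k))
            out[cell] = names[int(lab)]
        return out


def _train_labels(codes, scores, k, t0):
    m = 3 ** k
    valid = codes >= 0
    sums = np.bincount(codes[valid], weights=scores[valid], minlength=m)
    counts = np.bincount(codes[valid], minlength=m)
    # score-scaled tolerance: a sum that is zero up to accumulated rounding
    # must take the low branch of the strict > rule
    tol = 1e-12 * np.abs(scores[valid]).sum()
    labels = np.where(sums > t0 + tol, HIGH, LOW).astype(np.int8)
    labels[counts == 0] = EMPTY
    return labels, sums, counts


def classify_cells(G: GenotypeMatrix, combination, scores,
                   t0: float = 0.0) -> RiskModel:
    """Label each occupied genotype cell high iff its score sum exceeds t0.

    Subjects with a missing genotype at any of the combination's loci are
    excluded from cell assignment.  ``scores`` may be a ScoreSet or a plain
    aggregated-score vector aligned with G's subjects.
    """
    S = scores.aggregated if isinstance(scores, ScoreSet) else np.asarray(scores)
    idx = G.locus_index(combination)
    codes = cell_codes(G.dosages[:, idx])
    labels, sums, counts = _train_labels(codes, S, len(combination), t0)
    return RiskModel(tuple(combination), labels, t0, sums, counts)


# ---------------------------------------------------------------------------
# balanced accuracy
# ---------------------------------------------------------------------------

def _ba_from_high(high: np.ndarray, S: np.ndarray, weighting: str) -> float:
    case = S > 0
    ctrl = ~case
    if weighting == "count":
        w = np.ones_like(S)
    elif weighting == "score":
        w = np.abs(S)
    else:
        raise ValueError(f"unknown BA weighting {weighting!r}")
    w_case = w[case].sum()
    w_ctrl = w[ctrl].sum()
    if w_case <= 0 or w_ctrl <= 0:
        return np.nan                      # undefined; caller flags/skips
    sens = w[case & high].sum() / w_case
    spec = w[ctrl & ~high].sum() / w_ctrl
    return 0.5 * (sens + spec)


def balanced_accuracy(model: RiskModel, G: GenotypeMatrix, scores,
                      weighting: str = "score",
                      empty_policy: str = "low") -> float:
    """BA of a trained risk model on an evaluation set.

    Pseudo-cases are subjects with positive prediction score.  Subjects in
    cells that were empty (or unseen) at training time are treated as
    low-risk by default, or dropped with ``empty_policy='exclude'``.
    Returns nan when either pseudo-class is absent.
    """
    S = scores.aggregated if isinstance(scores, ScoreSet) else np.asarray(scores)
    idx = G.locus_index(model.combination)
    codes = cell_codes(G.dosages[:, idx])
    valid = codes >= 0
    lab = np.full(codes.shape, EMPTY, dtype=np.int8)
    lab[valid] = model.labels[codes[valid]]
    if empty_policy == "low":
        keep = valid
        high = lab == HIGH
    elif empty_policy == "exclude":
        keep = valid & (lab != EMPTY)
        high = lab == HIGH
    else:
        raise ValueError(f"unknown empty_policy {empty_policy!r}")
    return _ba_from_high(high[keep], S[keep], weighting)


# ---------------------------------------------------------------------------
# cross-validation and model selection
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold train/test BA and cross-validation consistency of one model."""

    combination: LocusCombination
    train_ba: np.ndarray
    test_ba: np.ndarray
    mean_train_ba: float
    mean_test_ba: float
    cvc: int


def make_folds(n: int, n_folds: int, seed: int, scores=None,
               stratify: bool = False) -> np.ndarray:
    """Seeded fold assignment (0..n_folds-1) per subject.

    Default is an unstratified uniform shuffle; with ``stratify`` the split
    balances the sign of the prediction score across folds.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=np.int64)
    if stratify and scores is not None:
        S = scores.aggregated if isinstance(scores, ScoreSet) else np.asarray(scores)
        for grp in (np.flatnonzero(S > 0), np.flatnonzero(S <= 0)):
            perm = rng.permutation(grp)
            for f, chunk in enumerate(np.array_split(perm, n_folds)):
                assign[chunk] = f
    else:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            assign[chunk] = f
    return assign


def cross_validate(G: GenotypeMatrix, scores, combinations,
                   n_folds: int = 10, seed: int = 0, t0: float = 0.0,
                   weighting: str = "score", empty_policy: str = "low",
                   stratify: bool = False) -> list:
    """k-fold CV over a list of locus combinations.

    Scores are computed once on all subjects by the null model (they do not
    depend on genotypes), so only the cell labelling is re-trained per fold.
    The fold-best combination maximizes train BA (ties break to the first,
    i.e. lexicographically earliest, combination); CVC counts fold-best wins
    and sums to n_folds over the offered combinations.
    """
    S = scores.aggregated if isinstance(scores, ScoreSet) else np.asarray(scores)
    n = G.n_subjects
    if len(S) != n:
        raise ValueError("scores are not aligned with the genotype matrix")
    combos = [tuple(c) for c in combinations]
    if not combos:
        raise ValueError("no combinations offered")
    folds = make_folds(n, n_folds, seed, S, stratify)

    codes_by_combo = []
    for c in combos:
        idx = G.locus_index(c)
        codes_by_combo.append(cell_codes(G.dosages[:, idx]))

    C = len(combos)
    train_ba = np.full((C, n_folds), np.nan)
    test_ba = np.full((C, n_folds), np.nan)
    for f in range(n_folds):
        te = folds == f
        tr = ~te
        for ci, (c, codes) in enumerate(zip(combos, codes_by_combo)):
            k = len(c)
            valid = codes >= 0
            labels, _, _ = _train_labels(codes[tr], S[tr], k, t0)
            for part, mask, arr in (("train", tr, train_ba), ("test", te, test_ba)):
                sel = mask & valid
                lab = labels[codes[sel]]
                if empty_policy == "exclude":
                    keep = lab != EMPTY
                    arr[ci, f] = _ba_from_high(lab[keep] == HIGH,
                                               S[sel][keep], weighting)
                else:
                    arr[ci, f] = _ba_from_high(lab == HIGH, S[sel], weighting)

    fold_best = np.empty(n_folds, dtype=np.int64)
    for f in range(n_folds):
        col = np.where(np.isnan(train_ba[:, f]), -np.inf, train_ba[:, f])
        fold_best[f] = int(np.argmax(col))   # first max -> lexicographic tie
    cvc = np.bincount(fold_best, minlength=C)

    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan folds
        for ci, c in enumerate(combos):
            if np.isnan(test_ba[ci]).any():
                warnings.warn(f"fold(s) with undefined BA for {c}; excluded "
                              f"from means", stacklevel=2)
            results.append(CVResult(
                c, train_ba[ci].copy(), test_ba[ci].copy(),
                float(np.nanmean(train_ba[ci])),
                float(np.nanmean(test_ba[ci])), int(cvc[ci])))
    return results


def select_best_model(results) -> CVResult:
    """Max CVC, then max mean test BA, then lexicographically first."""
    if not results:
        raise ValueError("no CV results to select from")
    def key(r: CVResult):
        mtb = r.mean_test_ba if np.isfinite(r.mean_test_ba) else -np.inf
        return (-r.cvc, -mtb, r.combination)
    return min(results, key=key)


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

def run_gmdr_analysis(G: GenotypeMatrix, P: PhenotypePanel,
                      Z: CovariateTable | None = None, family=None,
                      structure: str | None = None, orders=(1, 2),
                      n_folds: int = 10, seed: int = 0, t0: float = 0.0,
                      weighting: str = "score", empty_policy: str = "low",
                      estimate_phi: bool | None = None,
                      method_label: str | None = None):
    """Null fit -> prediction scores -> exhaustive CV search per order.

    Returns (summary DataFrame with the usual No. of Loci / Method /
    Best model / Train BA / Test BA / CVC columns, dict order -> CVResult
    list, ScoreSet).
    """
    if structure is None:
        structure = "independence" if P.n_occasions == 1 else "exchangeable"
    max_k = max(orders)
    if max_k > 4 or (max_k > 2 and G.n_loci > 64):
        raise ValueError("exhaustive search capped at order 4 (order >2 only "
                         "for <=64 loci)")
    fit = fit_null_model(P, Z, family=family, structure=structure,
                         estimate_phi=estimate_phi)
    scores = residual_scores(fit, P)
    if method_label is None:
        method_label = "Multivariate GMDR" if P.n_occasions > 1 else "GMDR"
    rows = []
    details = {}
    for k in orders:
        combos = enumerate_combinations(G.locus_ids, k)
        results = cross_validate(G, scores, combos, n_folds=n_folds,
                                 seed=seed, t0=t0, weighting=weighting,
                                 empty_policy=empty_policy)
        best = select_best_model(results)
        details[k] = results
        rows.append({
            "No. of Loci": k,
            "Method": method_label,
            "Best model": ", ".join(str(l) for l in best.combination),
            "Train BA": round(best.mean_train_ba, 6),
            "Test BA": round(best.mean_test_ba, 6),
            "CVC": best.cvc,
        })
    return pd.DataFrame(rows), details, scores
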