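"""Two-stage marker pre-selection ahead of the combinatorial search.

Stage 1 fits one covariate-adjusted univariate marginal model per locus and
trait, ranks loci per trait by p-value, and takes the union of the per-trait
top-N lists.  Stage 2 refits the candidates jointly across traits with a
heterogeneous-effect GEE and keeps loci whose joint (robust Wald) p-value
falls below a threshold.  Both stages are pure filters: they only ever
narrow the locus set and are deterministic given the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gee import (ConvergenceError, SingularityError, fit_marginal_model,
                  wald_test_genetic_effect)
from .io import CovariateTable, GenotypeMatrix, PhenotypePanel


@dataclass
class ScreeningResult:
    """Per-locus screening table and the surviving locus list."""

    table: pd.DataFrame
    selected: list
    p_threshold: float
    fell_back: bool = False      # empty survivor set -> candidates kept


def _locus_subjects(G: GenotypeMatrix, j: int):
    """Complete-genotype subject mask for locus column j."""
    return ~G.missing_mask[:, j]


def marginal_screen(G: GenotypeMatrix, P: PhenotypePanel,
                    Z: CovariateTable | None = None, family=None,
                    top_n: int = 50):
    """Per-trait univariate GLM screen; returns ranked tables and the union.

    Each locus is fit per occasion with additive genotype coding and the
    null-model covariates; ranking is by model-based Wald p-value ascending.
    Non-convergent fits are kept with p = nan and ranked last.
    Returns (dict occasion_id -> ranked DataFrame, union locus list in
    genotype-column order, provenance DataFrame).
    """
    if Z is None:
        Z = CovariateTable.intercept_only(P.subject_ids)
    per_trait = {}
    chosen = set()
    prov_rows = []
    for jt, occ in enumerate(P.occasion_ids):
        Pj = P.occasion(jt)
        rows = []
        for jl, locus in enumerate(G.locus_ids):
            keep = _locus_subjects(G, jl) & ~Pj.missing_mask[:, 0]
            g = G.dosages[keep, jl]
            try:
                fit = fit_marginal_model(
                    Pj.restrict(keep), Z.restrict(keep), family=family,
                    structure="independence", genotype=g,
                    effect_structure="homogeneous")
                beta = float(fit.beta[0])
                se = float(fit.se(robust=False)[0])
                p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan
                conv = fit.converged
            except (ConvergenceError, SingularityError, ValueError):
                beta, se, p, conv = np.nan, np.nan, np.nan, False
            rows.append({"locus": locus, "beta": beta, "se": se, "p": p,
                         "converged": conv})
        df = pd.DataFrame(rows)
        order = np.argsort(np.where(np.isnan(df["p"]), np.inf,
                                    df["p"]), kind="stable")
        df = df.iloc[order].reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        per_trait[occ] = df
        top = df.head(top_n)
        chosen.update(top["locus"])
        for _, r in top.iterrows():
            prov_rows.append({"locus": r["locus"], "trait": occ,
                              "rank": int(r["rank"]), "p": r["p"]})
    union = [l for l in G.locus_ids if l in chosen]
    return per_trait, union, pd.DataFrame(prov_rows)


def multivariate_filter(candidates, G: GenotypeMatrix, P: PhenotypePanel,
                        Z: CovariateTable | None = None, family=None,
                        structure: str = "exchangeable",
                        effect_structure: str = "heterogeneous",
                        p_threshold: float = 1e-4) -> ScreeningResult:
    """Joint-test filter: keep candidates with GEE joint Wald p < threshold.

    The per-candidate fit uses a heterogeneous genotype effect (one
    coefficient per trait) by default; per-trait p-values come from robust
    SEs and the joint p from the sandwich Wald statistic.  An empty survivor
    set triggers a warning and falls back to the full candidate list.
    """
    if Z is None:
        Z = CovariateTable.intercept_only(P.subject_ids)
    if structure == "exchangeable" and P.n_occasions == 1:
        structure = "independence"
    candidates = list(candidates)
    unknown = [c for c in candidates if c not in set(G.locus_ids)]
    if unknown:
        raise KeyError(f"candidates not in genotype matrix: {unknown}")
    col = {l: j for j, l in enumerate(G.locus_ids)}
    rows = []
    t = P.n_occasions
    for locus in candidates:
        jl = col[locus]
        keep = _locus_subjects(G, jl)
        g = G.dosages[keep, jl]
        row = {"locus": locus}
        try:
            fit = fit_marginal_model(P.restrict(keep), Z.restrict(keep),
                                     family=family, structure=structure,
                                     genotype=g,
                                     effect_structure=effect_structure)
            se = fit.se(robust=True)[: fit.n_beta]
            for j in range(fit.n_beta):
                b = float(fit.beta[j])
                z = b / se[j] if se[j] > 0 else np.nan
                suffix = j + 1 if effect_structure == "heterogeneous" else ""
                row[f"beta{suffix}"] = b
                row[f"p{suffix}"] = float(2 * stats.norm.sf(abs(z)))
            wt = wald_test_genetic_effect(fit)
            row["joint_p"] = wt.p_value
            row["converged"] = fit.converged
        except (ConvergenceError, SingularityError, ValueError):
            for j in range(t if effect_structure == "heterogeneous" else 1):
                suffix = j + 1 if effect_structure == "heterogeneous" else ""
                row[f"beta{suffix}"] = np.nan
                row[f"p{suffix}"] = np.nan
            row["joint_p"] = np.nan
            row["converged"] = False
        rows.append(row)
    table = pd.DataFrame(rows)
    table["selected"] = table["joint_p"] < p_threshold
    selected = table.loc[table["selected"], "locus"].tolist()
    fell_back = False
    if not selected:
        warnings.warn("no candidate passed the multivariate filter; "
                      "continuing with the full candidate list", stacklevel=2)
        selected = candidates
        fell_back = True
    return ScreeningResult(table, selected, p_threshold, fell_back)


def screen(G: GenotypeMatrix, P: PhenotypePanel,
           Z: CovariateTable | None = None, family=None,
           top_n: int = 50, p_threshold: float = 1e-4,
           structure: str = "exchangeable") -> ScreeningResult:
    """Full two-stage screen: per-trait top-N union, then joint-p filter."""
    _, union, _ = marginal_screen(G, P, Z, family=family, top_n=top_n)
    return multivariate_filter(union, G, P, Z, family=family,
                               structure=structure, p_threshold=p_threshold)
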