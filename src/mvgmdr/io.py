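"""Tabular I/O for genotypes, phenotypes and covariates, plus marker QC.

Genotypes are additive minor-allele dosages in {0, 1, 2} with an explicit
missingness mask.  Two on-disk dialects are supported: PLINK ``.raw``
(space-delimited, additive recoding, six leading pedigree columns) and plain
TSV (one subject-id column followed by one column per SNP).  Phenotypes and
covariates are wide TSV tables; repeated measures or multiple traits appear
as one column per occasion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "."}


class ParseError(ValueError):
    """Raised when an input table violates the format contract."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Subjects x loci additive minor-allele dosages.

    ``dosages`` is float with ``nan`` at missing entries; ``missing_mask``
    mirrors the nan pattern.  Every non-missing dosage is 0, 1 or 2.
    """

    subject_ids: np.ndarray
    locus_ids: np.ndarray
    dosages: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.dosages.shape
        if self.missing_mask.shape != (n, p):
            raise ValidationError("dosages and missing_mask dimensions differ")
        if len(self.subject_ids) != n or len(self.locus_ids) != p:
            raise ValidationError("id vectors do not match dosage dimensions")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids")
        if len(set(self.locus_ids)) != p:
            raise ValidationError("duplicate locus ids")
        vals = self.dosages[~self.missing_mask]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"non-{{0,1,2}} dosage value {bad!r}")
        self.dosages = np.where(self.missing_mask, np.nan, self.dosages)

    @classmethod
    def from_dosages(cls, subject_ids, locus_ids, dosages) -> "GenotypeMatrix":
        """Build from a float matrix using ``nan`` as the missing code."""
        dosages = np.asarray(dosages, dtype=float)
        return cls(subject_ids, locus_ids, dosages, np.isnan(dosages))

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def locus_index(self, locus_ids: Sequence) -> np.ndarray:
        idx = pd.Index(self.locus_ids).get_indexer(list(locus_ids))
        if (idx < 0).any():
            missing = [l for l, i in zip(locus_ids, idx) if i < 0]
            raise KeyError(f"unknown loci: {missing}")
        return idx

    def restrict(self, subject_idx=None, locus_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if li.dtype == bool:
            li = np.flatnonzero(li)
        return GenotypeMatrix(
            self.subject_ids[si], self.locus_ids[li],
            self.dosages[np.ix_(si, li)], self.missing_mask[np.ix_(si, li)],
        )


@dataclass
class PhenotypePanel:
    """Subjects x occasions outcome matrix y_i with family tag.

    ``occasion_ids`` are trait names or time points (length t >= 1).  For the
    binomial family every non-missing outcome is 0/1.
    """

    subject_ids: np.ndarray
    occasion_ids: np.ndarray
    y: np.ndarray
    family: str
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.occasion_ids = np.asarray(self.occasion_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.y.shape:
            raise ValidationError("y and missing_mask dimensions differ")
        if self.family not in ("binomial", "gaussian"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.y.shape[1] < 1:
            raise ValidationError("need at least one occasion")
        if len(set(self.subject_ids)) != self.y.shape[0]:
            raise ValidationError("duplicate subject ids")
        if self.family == "binomial":
            vals = self.y[~self.missing_mask]
            if vals.size and not np.isin(vals, (0.0, 1.0)).all():
                bad = vals[~np.isin(vals, (0.0, 1.0))][0]
                raise ValidationError(
                    f"binomial outcome contains non-binary value {bad!r}")
        self.y = np.where(self.missing_mask, np.nan, self.y)

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def occasion(self, j) -> "PhenotypePanel":
        """Single-occasion (univariate) view, by index or occasion id."""
        if not isinstance(j, (int, np.integer)):
            j = int(np.flatnonzero(self.occasion_ids == j)[0])
        return PhenotypePanel(
            self.subject_ids, self.occasion_ids[[j]],
            self.y[:, [j]], self.family, self.missing_mask[:, [j]],
        )

    def restrict(self, subject_idx) -> "PhenotypePanel":
        si = np.asarray(subject_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        return PhenotypePanel(
            self.subject_ids[si], self.occasion_ids, self.y[si],
            self.family, self.missing_mask[si],
        )


@dataclass
class CovariateTable:
    """Subjects x covariates design block Z (optionally with unit column)."""

    subject_ids: np.ndarray
    names: np.ndarray
    values: np.ndarray
    has_intercept: bool = True

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.names = np.asarray(self.names, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if len(self.names) != self.values.shape[1]:
            raise ValidationError("covariate names do not match value columns")
        if self.has_intercept:
            if "intercept" not in self.names:
                raise ValidationError("has_intercept set but no intercept column")
            col = self.values[:, list(self.names).index("intercept")]
            if not np.all(col == 1.0):
                raise ValidationError("intercept column must be all ones")

    @classmethod
    def intercept_only(cls, subject_ids) -> "CovariateTable":
        n = len(subject_ids)
        return cls(subject_ids, ["intercept"], np.ones((n, 1)), True)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def restrict(self, subject_idx) -> "CovariateTable":
        si = np.asarray(subject_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        return CovariateTable(self.subject_ids[si], self.names,
                              self.values[si], self.has_intercept)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_dosage_frame(df: pd.DataFrame, subject_ids, snp_cols) -> GenotypeMatrix:
    n = len(df)
    dosages = np.empty((n, len(snp_cols)))
    for j, col in enumerate(snp_cols):
        raw = df[col].astype(str).str.strip()
        is_missing = raw.isin(_MISSING_TOKENS)
        num = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = (~is_missing) & num.isna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"unparseable dosage {raw.iloc[i]!r} at subject "
                f"{subject_ids[i]!r}, locus {col!r}")
        vals = num.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i = int(np.flatnonzero(~ok)[0])
            raise ParseError(
                f"dosage {vals[i]!r} not in {{0,1,2,NA}} at subject "
                f"{subject_ids[i]!r}, locus {col!r}")
        dosages[:, j] = vals
    if len(set(subject_ids)) != n:
        dup = pd.Series(subject_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ParseError(f"duplicate subject id {dup!r}")
    return GenotypeMatrix.from_dosages(subject_ids, list(snp_cols), dosages)


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype table in ``plink_raw`` or ``tsv`` dialect.

    Missing dosages may be coded NA, blank or ``.``; anything else outside
    {0,1,2} raises :class:`ParseError` naming the offending row and column.
    """
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        if tuple(df.columns[:6]) != PLINK_META:
            raise ParseError(
                f"plink_raw header must start with {' '.join(PLINK_META)}")
        subject_ids = df["IID"].tolist()
        snp_cols = list(df.columns[6:])
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise ParseError("tsv genotype file needs a subject column and at "
                             "least one SNP column")
        subject_ids = df.iloc[:, 0].tolist()
        snp_cols = list(df.columns[1:])
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    return _parse_dosage_frame(df, subject_ids, snp_cols)


def write_genotypes(G: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write a genotype table in the same dialects ``read_genotypes`` accepts."""
    def fmt(v):
        return "NA" if np.isnan(v) else str(int(v))

    body = pd.DataFrame(
        [[fmt(v) for v in row] for row in G.dosages],
        columns=list(G.locus_ids),
    )
    if dialect == "plink_raw":
        meta = pd.DataFrame({
            "FID": G.subject_ids, "IID": G.subject_ids,
            "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
        })
        pd.concat([meta, body], axis=1).to_csv(path, sep=" ", index=False)
    elif dialect == "tsv":
        body.insert(0, "subject", G.subject_ids)
        body.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_phenotypes(path, family: str, occasion_columns=None,
                    subject_col=None) -> PhenotypePanel:
    """Read a wide phenotype table; one column per occasion/trait."""
    df = pd.read_csv(path, sep="\t")
    if subject_col is None:
        subject_col = df.columns[0]
    if occasion_columns is None:
        occasion_columns = [c for c in df.columns if c != subject_col]
    missing = [c for c in occasion_columns if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype columns not found: {missing}")
    y = df[list(occasion_columns)].to_numpy(dtype=float)
    return PhenotypePanel(df[subject_col].astype(str).tolist(),
                          list(occasion_columns), y, family, np.isnan(y))


def read_covariates(path, columns=None, subject_col=None,
                    add_intercept: bool = True) -> CovariateTable:
    """Read a covariate TSV; prepends a unit column unless told otherwise."""
    df = pd.read_csv(path, sep="\t")
    if subject_col is None:
        subject_col = df.columns[0]
    if columns is None:
        columns = [c for c in df.columns if c != subject_col]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"covariate columns not found: {missing}")
    vals = df[list(columns)].to_numpy(dtype=float)
    names = list(columns)
    if add_intercept:
        vals = np.column_stack([np.ones(len(df)), vals])
        names = ["intercept"] + names
    return CovariateTable(df[subject_col].astype(str).tolist(), names, vals,
                          add_intercept)


def write_phenotypes(P: PhenotypePanel, path) -> None:
    df = pd.DataFrame(P.y, columns=list(P.occasion_ids))
    df.insert(0, "subject", P.subject_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.10g")


def write_covariates(Z: CovariateTable, path) -> None:
    keep = [i for i, nm in enumerate(Z.names) if nm != "intercept"]
    df = pd.DataFrame(Z.values[:, keep], columns=[Z.names[i] for i in keep])
    df.insert(0, "subject", Z.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# QC and alignment
# ---------------------------------------------------------------------------

def _qc_keep(dosages, mask, maf_min, miss_max):
    miss_frac = mask.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        f = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    # nan MAF (all missing) fails the MAF criterion
    return (miss_frac <= miss_max) & (maf > maf_min) & ~np.isnan(maf)


def apply_qc_filters(G: GenotypeMatrix, maf_min: float = 0.01,
                     miss_max: float = 0.005, strata=None) -> GenotypeMatrix:
    """Drop loci with missing fraction > ``miss_max`` or MAF <= ``maf_min``.

    MAF is min(f, 1-f) with f = mean(non-missing dosage)/2.  With ``strata``
    (per-subject labels) a locus must pass in every stratum, mirroring QC
    applied separately per recruitment area; default is pooled.
    """
    if not (0 <= maf_min <= 1 and 0 <= miss_max <= 1):
        raise ValueError("maf_min and miss_max must be fractions in [0,1]")
    if strata is None:
        keep = _qc_keep(G.dosages, G.missing_mask, maf_min, miss_max)
    else:
        strata = np.asarray(strata)
        keep = np.ones(G.n_loci, dtype=bool)
        for s in np.unique(strata):
            sel = strata == s
            keep &= _qc_keep(G.dosages[sel], G.missing_mask[sel],
                             maf_min, miss_max)
    return G.restrict(locus_idx=keep)


def orient_minor(G: GenotypeMatrix) -> GenotypeMatrix:
    """Flip columns so dosages count the minor allele (freq <= 0.5)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(G.dosages, axis=0) / 2.0
    flip = f > 0.5
    dosages = G.dosages.copy()
    dosages[:, flip] = 2.0 - dosages[:, flip]
    return GenotypeMatrix(G.subject_ids, G.locus_ids, dosages, G.missing_mask)


def align(G: GenotypeMatrix, P: PhenotypePanel, Z: CovariateTable | None = None,
          complete_case: bool = True):
    """Join the three tables on subject id, preserving per-subject alignment.

    Restricts to the id intersection (in genotype order), drops subjects with
    any missing covariate, and — under the default complete-case rule — drops
    subjects missing any phenotype occasion.  Set ``complete_case=False`` to
    keep subjects with partial occasions (the GEE handles unequal cluster
    sizes).
    """
    if Z is None:
        Z = CovariateTable.intercept_only(G.subject_ids)
    ids = [i for i in G.subject_ids
           if i in set(P.subject_ids) and i in set(Z.subject_ids)]
    gi = pd.Index(G.subject_ids).get_indexer(ids)
    pi = pd.Index(P.subject_ids).get_indexer(ids)
    zi = pd.Index(Z.subject_ids).get_indexer(ids)
    G2, P2, Z2 = G.restrict(gi), P.restrict(pi), Z.restrict(zi)
    keep = ~np.isnan(Z2.values).any(axis=1)
    if complete_case:
        keep &= ~P2.missing_mask.any(axis=1)
    else:
        keep &= ~P2.missing_mask.all(axis=1)
    return G2.restrict(keep), P2.restrict(keep), Z2.restrict(keep)
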