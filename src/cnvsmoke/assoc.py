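"""Covariate-adjusted linear association scan over polymorphic CNV components.

Each component is tested by ordinary least squares of a quantitative smoking
phenotype on CNV dosage (number of deleted copies: diploid 0, hemizygous 1,
homozygous 2) plus covariates (age, sex and — for admixed cohorts — the
average European-ancestry admixture score).  The scan reports per-component
effect sizes, two-sided t-test p-values and the genomic inflation factor
lambda (median association chi-square over its theoretical null median).

The scan's per-component fits use a Frisch-Waugh-Lovell residualization
(project phenotype and dosage off the covariate design once, then fit the
simple regression on residuals), which is algebraically exact OLS and fast
enough to be re-run thousands of times inside the permutation loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cnvsmoke.cnvcall import CNVComponent

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult", "ScanSummary", "MonomorphicError",
    "fit_linear_assoc", "run_scan", "carrier_contrast", "genomic_lambda",
    "encode_covariates", "scan_statistics",
]

# Median of the chi-square distribution with 1 df.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


class MonomorphicError(ValueError):
    """Raised when the dosage is constant in the analysis subset."""


@dataclass
class AssociationResult:
    """Regression output for one CNV component and one phenotype."""

    component_id: str
    phenotype: str
    beta: float
    se: float
    t_stat: float
    p_two_sided: float
    n: int
    covariates: list[str] = field(default_factory=list)

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_two_sided))


@dataclass
class ScanSummary:
    """Genome-wide scan: per-component results plus inflation factor."""

    results: list[AssociationResult]
    phenotype: str
    lambda_gc: float

    @property
    def m_components(self) -> int:
        return len(self.results)

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r.p_two_sided for r in self.results])

    @property
    def component_ids(self) -> list[str]:
        return [r.component_id for r in self.results]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "component_id": r.component_id, "phenotype": r.phenotype,
            "beta": r.beta, "se": r.se, "t": r.t_stat, "p": r.p_two_sided,
            "neg_log10_p": r.neg_log10_p, "n": r.n,
        } for r in self.results]
        return pd.DataFrame(rows)


def encode_covariates(covariates) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate matrix + names from a DataFrame/array/None.

    A ``sex`` column with M/F strings becomes a male indicator; booleans
    become 0/1; other columns must be numeric.
    """
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        cols = []
        names = []
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or str(col.dtype) == "category":
                vals = col.astype(str).str.upper()
                uniq = set(vals.unique())
                if uniq <= {"M", "F"}:
                    cols.append((vals == "M").to_numpy(float))
                    names.append("sex_male")
                    continue
                raise ValueError(f"cannot encode non-numeric covariate {name!r}")
            cols.append(col.to_numpy(float))
            names.append(str(name))
        return np.column_stack(cols) if cols else np.empty((len(covariates), 0)), names
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        offenders = [names[j] for j in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; collinear columns: {offenders}")


def fit_linear_assoc(phenotype, dosage, covariates=None,
                     component_id: str = "component",
                     phenotype_name: str = "phenotype") -> AssociationResult:
    """OLS of phenotype on CNV dosage plus covariates.

    ``dosage`` is the number of deleted copies per subject.  The two-sided
    p-value comes from the t distribution with n - k - 1 residual degrees
    of freedom.  Constant dosage raises :class:`MonomorphicError`;
    collinear covariates raise a ValueError naming the columns.
    """
    y = np.asarray(phenotype, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if y.shape != d.shape or y.ndim != 1:
        raise ValueError("phenotype and dosage must be 1-D of equal length")
    if np.ptp(d) == 0:
        raise MonomorphicError("monomorphic component")
    C, cov_names = encode_covariates(covariates)
    if C.size and C.shape[0] != y.size:
        raise ValueError(
            f"covariate table has {C.shape[0]} rows for {y.size} subjects")
    n = y.size
    X = np.column_stack([np.ones(n), d] + ([C] if C.size else []))
    names = ["intercept", "dosage"] + cov_names
    _check_full_rank(X, names)

    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for the requested model")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta_hat[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(
        component_id=component_id, phenotype=phenotype_name,
        beta=float(beta_hat[1]), se=se, t_stat=t, p_two_sided=max(p, 1e-300),
        n=n, covariates=cov_names)


def scan_statistics(y: np.ndarray, dosage_matrix: np.ndarray,
                    covariates=None) -> dict[str, np.ndarray]:
    """Vectorized per-component OLS via Frisch-Waugh-Lovell residualization.

    Exact OLS for each column of ``dosage_matrix`` regressed with the same
    covariate block.  Monomorphic columns get NaN statistics (callers decide
    whether to skip or raise).
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(dosage_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != y.size:
        raise ValueError("dosage matrix must be subjects x components")
    C, _ = encode_covariates(covariates)
    n = y.size
    F = np.column_stack([np.ones(n)] + ([C] if C.size else []))
    Q, _ = np.linalg.qr(F)
    y_t = y - Q @ (Q.T @ y)
    D_t = D - Q @ (Q.T @ D)
    s = np.einsum("ij,ij->j", D_t, D_t)
    mono = s <= 1e-12 * n
    s_safe = np.where(mono, 1.0, s)
    b = (D_t.T @ y_t) / s_safe
    yy = float(y_t @ y_t)
    rss = yy - b * b * s_safe
    df = n - F.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough observations for the requested model")
    se = np.sqrt(np.maximum(rss, 0.0) / df / s_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 1e-300, 1.0)
    for arr in (b, se, t, p):
        arr[mono] = np.nan
    return {"beta": b, "se": se, "t": t, "p": p, "df": df,
            "monomorphic": mono, "n": n}


def _dosage_matrix(components) -> tuple[np.ndarray, list[str]]:
    """Deleted-copies dosage matrix + ids from components or a table."""
    if isinstance(components, pd.DataFrame):
        return components.to_numpy(float), [str(c) for c in components.columns]
    if isinstance(components, np.ndarray):
        D = np.asarray(components, dtype=float)
        return D, [f"c{j}" for j in range(D.shape[1])]
    comps = list(components)
    if not comps:
        raise ValueError("no components to scan")
    if not all(isinstance(c, CNVComponent) for c in comps):
        raise TypeError("components must be CNVComponent, DataFrame or ndarray")
    D = np.column_stack([c.deleted_copies for c in comps]).astype(float)
    return D, [c.component_id for c in comps]


def run_scan(phenotype, components, covariates=None,
             phenotype_name: str = "phenotype") -> ScanSummary:
    """Association scan of one phenotype over all polymorphic components.

    Components monomorphic in the analysis subset are skipped with a logged
    warning; M (the number of tests) counts only tested components.
    """
    y = np.asarray(phenotype, dtype=float)
    D, ids = _dosage_matrix(components)
    if D.shape[0] != y.size:
        raise ValueError(
            f"phenotype length {y.size} != dosage rows {D.shape[0]}")
    C, cov_names = encode_covariates(covariates)
    if C.size and C.shape[0] != y.size:
        raise ValueError("phenotype/covariate length mismatch")
    st = scan_statistics(y, D, covariates)
    results = []
    for j, cid in enumerate(ids):
        if st["monomorphic"][j]:
            logger.warning("skipping monomorphic component %s", cid)
            continue
        results.append(AssociationResult(
            component_id=cid, phenotype=phenotype_name,
            beta=float(st["beta"][j]), se=float(st["se"][j]),
            t_stat=float(st["t"][j]), p_two_sided=float(st["p"][j]),
            n=int(st["n"]), covariates=cov_names))
    if not results:
        raise ValueError("all components are monomorphic; nothing to scan")
    lam = genomic_lambda(np.array([r.p_two_sided for r in results]))
    return ScanSummary(results=results, phenotype=phenotype_name, lambda_gc=lam)


def carrier_contrast(phenotype_raw, carrier_flags):
    """Welch two-sample contrast of carriers vs. the rest of the cohort.

    Returns a dict with group means, 95% confidence intervals, the Welch t
    statistic and its two-sided p-value, on whatever scale the phenotype is
    supplied (raw pack-years by default in this package's pipeline).
    """
    y = np.asarray(phenotype_raw, dtype=float)
    flags = np.asarray(carrier_flags, dtype=bool)
    if y.shape != flags.shape:
        raise ValueError("phenotype and carrier flags must align")
    a, b = y[flags], y[~flags]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 members")
    t, p = stats.ttest_ind(a, b, equal_var=False)

    def ci95(x):
        m = float(np.mean(x))
        sem = float(np.std(x, ddof=1) / np.sqrt(x.size))
        h = float(stats.t.ppf(0.975, x.size - 1)) * sem
        return (m - h, m + h)

    return {
        "mean_carriers": float(np.mean(a)), "mean_others": float(np.mean(b)),
        "ci_carriers": ci95(a), "ci_others": ci95(b),
        "n_carriers": int(a.size), "n_others": int(b.size),
        "welch_t": float(t), "p": float(p),
    }


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor from a vector of scan p-values.

    The observed p-values are converted to 1-df chi-square statistics; the
    ratio of their median to the theoretical null median (~0.4549) is the
    inflation factor; ~1 indicates no systematic confounding.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)
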