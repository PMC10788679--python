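"""Variance-component decomposition of imputation quality metrics.

The standard model-based quality metric reported by Minimac-style imputation
software is ``Rsq = Var(y) / (p(1-p))`` (haploid) where ``y`` are the imputed
allelic dosages and ``p`` is the alternative allele frequency (AAF) of the
imputed dataset.  The "true" accuracy is the squared Pearson correlation
between imputed dosage and true genotype (``EmpRsq``, a.k.a. dosage r2).

Regressing the dosage on the true allele, ``y = b0 + x * beta_imp + e``,
splits the total sum of squares into a regression part and a residual part,
which splits Rsq exactly into

    Rsq = EmpRsq * Rsq  +  MARE            (MARE = (1 - EmpRsq) * Rsq)
    Rsq = beta_imp**2   +  MARE            (when AAF of x equals AAF of y)

with ``beta_imp = sqrt(EmpRsq * Rsq)``.  MARE (MAF-Adjusted-Residual-Error)
is elevated when confidently wrong dosages inflate Rsq; beta_imp measures how
well the dosage groups separate by true genotype.  All variances here use the
population convention (divisor n) so the identities hold exactly.

Diploid data are handled by the rescaled binomial denominator,
``Rsq = Var(DS) / (2 p (1-p))``, with EmpRsq still the squared correlation of
DS against the 0/1/2 genotype dose.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_OK",
    "FLAG_MONO_TRUE",
    "FLAG_MONO_IMPUTED",
    "FLAG_NEG_SLOPE",
    "PLOIDY_DOSE",
    "MetricRecord",
    "compute_rsq",
    "compute_emprsq",
    "compute_mare",
    "compute_beta_imp",
    "decompose",
    "decompose_matrix",
    "records_to_frame",
    "theoretical_surfaces",
]

FLAG_OK = "ok"
FLAG_MONO_TRUE = "monomorphic_true"
FLAG_MONO_IMPUTED = "monomorphic_imputed"
FLAG_NEG_SLOPE = "negative_slope"

#: maximum per-haplotype (haploid) or per-individual (diploid) allele dose
PLOIDY_DOSE = {"haploid": 1, "diploid": 2}


def _as_vector(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 entries, got {arr.size}")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def _check_ploidy(ploidy: str) -> int:
    try:
        return PLOIDY_DOSE[ploidy]
    except KeyError:
        raise ValueError(f"ploidy must be 'haploid' or 'diploid', got {ploidy!r}") from None


def _check_dosages(y: np.ndarray, dose: int) -> None:
    if y.min() < 0 or y.max() > dose:
        raise ValueError(f"dosages must lie in [0, {dose}]")


def _check_alleles(x: np.ndarray, dose: int) -> None:
    if not np.all(x == np.round(x)):
        raise ValueError("true alleles/doses must be integer-valued")
    if x.min() < 0 or x.max() > dose:
        raise ValueError(f"true doses must lie in {{0..{dose}}}")


def compute_rsq(
    y: Sequence[float],
    ploidy: str = "haploid",
    p_override: float | None = None,
) -> float:
    """Model-based quality metric: Var(y) over the binomial variance p(1-p).

    ``p`` defaults to the AAF of the imputed dosages, ``mean(y) / dose``.
    Returns NaN when the imputed AAF is 0 or 1 (monomorphic imputed), where
    the metric is undefined.
    """
    dose = _check_ploidy(ploidy)
    arr = _as_vector(y, "y")
    _check_dosages(arr, dose)
    p = float(arr.mean() / dose) if p_override is None else float(p_override)
    if not 0.0 < p < 1.0:
        return float("nan")
    return float(arr.var()) / (dose * p * (1.0 - p))


def compute_emprsq(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between true dose and imputed dosage.

    This is the dosage-r2 style "empirical" accuracy, equal to the ratio of
    regression to total sum of squares of the simple linear regression of
    ``y`` on ``x``.  NaN if either vector has zero variance.  The squared
    correlation ignores the sign of the slope; negative-slope handling lives
    in :func:`decompose`.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    var_x = xv.var()
    var_y = yv.var()
    if var_x == 0.0 or var_y == 0.0:
        return float("nan")
    cov = float(np.mean((xv - xv.mean()) * (yv - yv.mean())))
    # rounding can push a perfect correlation epsilon above 1
    return min(cov * cov / (var_x * var_y), 1.0)


def _check_pair(rsq: float, emprsq: float) -> None:
    if not rsq >= 0.0:
        raise ValueError(f"rsq must be >= 0, got {rsq}")
    if not 0.0 <= emprsq <= 1.0:
        raise ValueError(f"emprsq must be in [0, 1], got {emprsq}")


def compute_mare(rsq: float, emprsq: float) -> float:
    """Residual variance component of Rsq: ``(1 - EmpRsq) * Rsq``."""
    _check_pair(rsq, emprsq)
    return (1.0 - emprsq) * rsq


def compute_beta_imp(rsq: float, emprsq: float) -> float:
    """Regression-slope component of Rsq: ``sqrt(EmpRsq * Rsq)``.

    Only the nonnegative branch is defined; a negatively correlated pair is
    flagged (not valued) by :func:`decompose`.
    """
    _check_pair(rsq, emprsq)
    return math.sqrt(emprsq * rsq)


@dataclasses.dataclass(frozen=True)
class MetricRecord:
    """Per-variant quality metrics and their decomposition.

    Missing (undefined) metrics are NaN with an explanatory flag; ``slope``
    is the raw regression coefficient Cov(x,y)/Var(x), a diagnostic that is
    not part of the canonical decomposition.
    """

    variant_key: str
    p: float
    rsq: float
    emprsq: float
    mare: float
    beta_imp: float
    slope: float
    n_haplotypes: int
    flags: tuple[str, ...] = (FLAG_OK,)

    @property
    def maf(self) -> float:
        return min(self.p, 1.0 - self.p)

    @property
    def ok(self) -> bool:
        return self.flags == (FLAG_OK,)


def decompose(
    x: Sequence[float],
    y: Sequence[float],
    ploidy: str = "haploid",
    variant_key: str = "-",
    p_override: float | None = None,
) -> MetricRecord:
    """Decompose one variant's Rsq into MARE and beta_imp against truth.

    Parameters
    ----------
    x
        True alleles (haploid, {0,1}) or genotype doses (diploid, {0,1,2}).
    y
        Imputed dosages, same length, in [0,1] (haploid) or [0,2] (diploid).
    p_override
        Use this AAF in the Rsq denominator instead of the imputed-dosage AAF
        (sensitivity checks against the truth AAF).
    """
    dose = _check_ploidy(ploidy)
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    _check_alleles(xv, dose)
    _check_dosages(yv, dose)

    n = xv.size
    p = float(yv.mean() / dose) if p_override is None else float(p_override)
    var_x = xv.var()
    var_y = yv.var()
    cov = float(np.mean((xv - xv.mean()) * (yv - yv.mean())))

    flags: list[str] = []
    if var_x == 0.0:
        flags.append(FLAG_MONO_TRUE)
    if var_y == 0.0 or not 0.0 < p < 1.0:
        flags.append(FLAG_MONO_IMPUTED)

    rsq = var_y / (dose * p * (1.0 - p)) if 0.0 < p < 1.0 else float("nan")
    slope = cov / var_x if var_x > 0.0 else float("nan")
    if var_x > 0.0 and var_y > 0.0:
        emprsq = min(cov * cov / (var_x * var_y), 1.0)
    else:
        emprsq = float("nan")

    if math.isnan(rsq) or math.isnan(emprsq):
        mare = float("nan")
        beta = float("nan")
    else:
        mare = compute_mare(rsq, emprsq)
        if slope < 0.0:
            flags.append(FLAG_NEG_SLOPE)
            beta = float("nan")
        else:
            beta = compute_beta_imp(rsq, emprsq)

    return MetricRecord(
        variant_key=variant_key,
        p=p,
        rsq=rsq,
        emprsq=emprsq,
        mare=mare,
        beta_imp=beta,
        slope=slope,
        n_haplotypes=n,
        flags=tuple(flags) if flags else (FLAG_OK,),
    )


def decompose_matrix(
    truth: np.ndarray,
    dosages: np.ndarray,
    variant_keys: Sequence[str] | None = None,
    ploidy: str = "haploid",
) -> list[MetricRecord]:
    """Row-wise :func:`decompose` for a markers x samples pair of matrices."""
    truth = np.asarray(truth, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    if truth.shape != dosages.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {dosages.shape}")
    if variant_keys is None:
        variant_keys = [str(i) for i in range(truth.shape[0])]
    return [
        decompose(truth[m], dosages[m], ploidy=ploidy, variant_key=str(variant_keys[m]))
        for m in range(truth.shape[0])
    ]


def records_to_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Tabulate records; one row per variant, flags comma-joined."""
    rows = [
        {
            "variant_key": r.variant_key,
            "p": r.p,
            "maf": r.maf,
            "rsq": r.rsq,
            "emprsq": r.emprsq,
            "mare": r.mare,
            "beta_imp": r.beta_imp,
            "slope": r.slope,
            "n": r.n_haplotypes,
            "flags": ",".join(r.flags),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def theoretical_surfaces(
    rsq_grid: Sequence[float], emprsq_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """MARE and beta_imp surfaces over an (Rsq, EmpRsq) grid.

    Returns ``(mare, beta_imp)`` arrays of shape ``(len(rsq_grid),
    len(emprsq_grid))``; used for isoline diagnostics on (dosage r2, Rsq)
    scatter plots.
    """
    rsq = np.asarray(rsq_grid, dtype=float)
    emp = np.asarray(emprsq_grid, dtype=float)
    if rsq.ndim != 1 or emp.ndim != 1:
        raise ValueError("grids must be one-dimensional")
    if (rsq < 0).any():
        raise ValueError("rsq grid must be nonnegative")
    if (emp < 0).any() or (emp > 1).any():
        raise ValueError("emprsq grid must lie in [0, 1]")
    R = rsq[:, None]
    E = emp[None, :]
    mare = (1.0 - E) * R
    beta = np.sqrt(E * R)
    return mare, beta
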