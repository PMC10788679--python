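"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the
metric oracle does an explicit least-squares sum-of-squares decomposition,
and the HMM oracle enumerates every hidden-state path.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from imputeqc.hmm import HaplotypePanel


def ols_decomposition(x, y):
    """Sum-of-squares decomposition of the regression of y on x.

    Fits y = b0 + b1*x by ordinary least squares and returns the quality
    metrics from the SS identities: rsq = (SS_tot/n)/(p(1-p)) with p the
    dosage mean, emprsq = SS_reg/SS_tot, mare = (SS_res/n)/(p(1-p)),
    beta_imp = sqrt(emprsq*rsq).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    A = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((y - fitted) ** 2)
    ss_reg = ss_tot - ss_res
    p = y.mean()
    denom = p * (1 - p)
    return {
        "rsq": (ss_tot / n) / denom,
        "emprsq": ss_reg / ss_tot,
        "mare": (ss_res / n) / denom,
        "beta_imp": float(np.sqrt(max(ss_reg, 0.0) / ss_tot * (ss_tot / n) / denom)),
        "slope": coef[1],
    }


def enumerate_posterior(alleles, theta, eps, target, typed):
    """Exact copying-state posterior by summing over all H^M hidden paths."""
    alleles = np.asarray(alleles)
    M, H = alleles.shape
    probs = np.zeros((M, H))
    total = 0.0
    for path in itertools.product(range(H), repeat=M):
        p = 1.0 / H
        for m in range(M):
            if m > 0:
                th = theta[m - 1]
                p *= (1 - th) + th / H if path[m] == path[m - 1] else th / H
            if typed[m] and target[m] >= 0:
                p *= 1 - eps[m] if alleles[m, path[m]] == target[m] else eps[m]
        total += p
        for m in range(M):
            probs[m, path[m]] += p
    return probs / total


def toy_panel(alleles, chrom="1"):
    """HaplotypePanel from a raw allele matrix with synthetic metadata."""
    alleles = np.asarray(alleles, dtype=np.int8)
    M = alleles.shape[0]
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 100 * (1 + np.arange(M)),
            "id": [f"v{i}" for i in range(M)],
            "ref": "A",
            "alt": "G",
        }
    )
    return HaplotypePanel(alleles=alleles, markers=markers)


@pytest.fixture
def two_hap_panel():
    """The two-haplotype, two-marker worked instance."""
    return toy_panel([[0, 1], [0, 1]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240113)
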