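"""Metric decomposition: worked examples, identities, and the OLS oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imputeqc.metrics import (
    FLAG_MONO_IMPUTED,
    FLAG_MONO_TRUE,
    FLAG_NEG_SLOPE,
    compute_beta_imp,
    compute_emprsq,
    compute_mare,
    compute_rsq,
    decompose,
    records_to_frame,
    theoretical_surfaces,
)

from conftest import ols_decomposition

X4 = [0, 0, 1, 1]
Y4 = [0.1, 0.2, 0.8, 0.9]


class TestRsq:
    @pytest.mark.parametrize(
        "y, expected",
        [
            ([0, 0, 1, 1], 1.0),            # Var(x) = p(1-p) exactly
            ([0.5, 0.5, 0.5, 0.5], 0.0),    # zero variance
            (Y4, 0.5),                      # Var = 0.125, p(1-p) = 0.25
        ],
    )
    def test_haploid_examples(self, y, expected):
        assert compute_rsq(y) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_imputed_is_nan(self):
        assert math.isnan(compute_rsq([0.0, 0.0, 0.0]))
        assert math.isnan(compute_rsq([1.0, 1.0, 1.0]))

    def test_diploid_denominator_doubles(self):
        y = [0.2, 0.4, 1.6, 1.8]
        p = np.mean(y) / 2
        expected = np.var(y) / (2 * p * (1 - p))
        assert compute_rsq(y, ploidy="diploid") == pytest.approx(expected, rel=1e-12)

    def test_p_override_changes_denominator(self):
        direct = compute_rsq(Y4)
        overridden = compute_rsq(Y4, p_override=0.4)
        assert overridden == pytest.approx(np.var(Y4) / (0.4 * 0.6), rel=1e-12)
        assert overridden != direct


class TestEmpRsq:
    def test_worked_example(self):
        assert compute_emprsq(X4, Y4) == pytest.approx(0.98, abs=1e-12)

    def test_perfect_correlation(self):
        assert compute_emprsq(X4, X4) == pytest.approx(1.0, abs=1e-12)

    def test_negative_slope_still_one(self):
        y = [0.9, 0.9, 0.1, 0.1]  # y = 0.9 - 0.8 x
        assert compute_emprsq(X4, y) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert math.isnan(compute_emprsq([0, 0, 0, 0], Y4))
        assert math.isnan(compute_emprsq(X4, [0.5] * 4))


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (compute_mare, (0.8, 0.75), 0.2),
        (compute_mare, (0.37, 1.0), 0.0),
        (compute_mare, (0.5, 0.98), 0.01),
        (compute_beta_imp, (0.5, 0.5), 0.5),
        (compute_beta_imp, (0.5, 0.98), 0.7),
        (compute_beta_imp, (1.0, 1.0), 1.0),
    ],
)
def test_mare_beta_arithmetic(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("fn", [compute_mare, compute_beta_imp])
def test_mare_beta_validation(fn):
    with pytest.raises(ValueError):
        fn(-0.1, 0.5)
    with pytest.raises(ValueError):
        fn(0.5, 1.2)


class TestDecompose:
    def test_worked_example_against_ols_oracle(self):
        oracle = ols_decomposition(X4, Y4)
        rec = decompose(X4, Y4)
        assert rec.rsq == pytest.approx(oracle["rsq"], abs=1e-12)
        assert rec.emprsq == pytest.approx(oracle["emprsq"], abs=1e-12)
        assert rec.mare == pytest.approx(oracle["mare"], abs=1e-12)
        assert rec.beta_imp == pytest.approx(oracle["beta_imp"], abs=1e-12)
        assert (rec.rsq, rec.emprsq, rec.mare, rec.beta_imp) == pytest.approx(
            (0.5, 0.98, 0.01, 0.7), abs=1e-12
        )
        assert rec.slope == pytest.approx(oracle["slope"], abs=1e-12)

    def test_perfect_imputation(self):
        rec = decompose([0, 1, 1, 0], [0, 1, 1, 0])
        assert (rec.rsq, rec.emprsq, rec.mare, rec.beta_imp) == pytest.approx(
            (1, 1, 0, 1), abs=1e-12
        )
        assert rec.ok

    def test_constant_dosage_flags_monomorphic_imputed(self):
        rec = decompose([0, 0, 1, 1], [0.5, 0.5, 0.5, 0.5])
        assert rec.rsq == 0.0
        assert math.isnan(rec.emprsq)
        assert FLAG_MONO_IMPUTED in rec.flags

    def test_monomorphic_truth_flagged(self):
        rec = decompose([1, 1, 1, 1], Y4)
        assert FLAG_MONO_TRUE in rec.flags
        assert math.isnan(rec.emprsq)

    def test_negative_slope_beta_missing(self):
        rec = decompose(X4, [0.9, 0.9, 0.1, 0.1])
        assert FLAG_NEG_SLOPE in rec.flags
        assert math.isnan(rec.beta_imp)
        assert rec.emprsq == pytest.approx(1.0)
        assert rec.slope < 0

    def test_oracle_equivalence_random_vectors(self, rng):
        """decompose matches the independent OLS SS decomposition."""
        for _ in range(1000):
            n = rng.integers(4, 40)
            x = rng.integers(0, 2, size=n)
            if x.min() == x.max():
                continue
            y = np.clip(x * rng.uniform(0.2, 1.0) + rng.normal(0, 0.2, n), 0, 1)
            rec = decompose(x, y)
            if not rec.ok:
                continue
            oracle = ols_decomposition(x, y)
            assert rec.rsq == pytest.approx(oracle["rsq"], abs=1e-9)
            assert rec.emprsq == pytest.approx(oracle["emprsq"], abs=1e-9)
            assert rec.mare == pytest.approx(oracle["mare"], abs=1e-9)
            assert rec.beta_imp == pytest.approx(oracle["beta_imp"], abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 1), st.floats(0.0, 1.0)), min_size=3, max_size=30
    )
)
def test_identities_hold_for_any_pair(data):
    """Rsq = EmpRsq*Rsq + MARE always; Rsq = beta^2 + MARE when AAFs agree."""
    x = np.array([d[0] for d in data])
    y = np.array([d[1] for d in data])
    rec = decompose(x, y)
    if not rec.ok:
        return
    assert rec.rsq == pytest.approx(rec.emprsq * rec.rsq + rec.mare, abs=1e-12)
    if abs(x.mean() - y.mean()) < 1e-12:
        assert rec.rsq == pytest.approx(rec.beta_imp**2 + rec.mare, abs=1e-9)


def test_identity_mismatch_factor_when_aafs_differ(rng):
    """The raw OLS slope recovers Rsq only after the Var(x)/p(1-p) factor;
    beta_imp (sqrt(EmpRsq*Rsq)) closes the identity exactly by construction."""
    x = rng.integers(0, 2, size=200)
    y = np.clip(x * 0.8 + rng.normal(0.1, 0.1, 200), 0, 1)
    rec = decompose(x, y)
    p = y.mean()
    # slope^2 * Var(x)/Var(y) = EmpRsq, so the slope route needs the
    # frequency factor while the Eq-style beta closes the identity exactly
    assert rec.slope**2 * x.var() / y.var() == pytest.approx(rec.emprsq, rel=1e-9)
    assert rec.slope**2 * x.var() / (p * (1 - p)) + rec.mare == (
        pytest.approx(rec.rsq, rel=1e-9)
    )
    assert rec.beta_imp**2 + rec.mare == pytest.approx(rec.rsq, rel=1e-9)


def test_ranges(rng):
    for _ in range(200):
        n = int(rng.integers(4, 50))
        x = rng.integers(0, 2, size=n)
        y = rng.uniform(0, 1, size=n)
        rec = decompose(x, y)
        if not rec.ok:
            continue
        assert 0 <= rec.emprsq <= 1
        assert 0 <= rec.mare <= rec.rsq + 1e-12
        assert 0 <= rec.beta_imp <= math.sqrt(rec.rsq) + 1e-12


def test_calibrated_posteriors_close_the_gap(rng):
    """With y the true posterior allele probability, Rsq converges to EmpRsq."""
    n = 10_000
    q = rng.beta(0.8, 1.6, size=n)
    x = (rng.random(n) < q).astype(int)
    rec = decompose(x, q)
    assert abs(rec.rsq - rec.emprsq) < 0.05


class TestSurfaces:
    def test_diagonal_and_edges(self):
        v = np.array([0.0, 0.25, 0.5, 1.0])
        mare, beta = theoretical_surfaces(v, v)
        diag_m = np.diag(mare)
        diag_b = np.diag(beta)
        assert diag_m == pytest.approx(v * (1 - v), abs=1e-12)
        assert diag_b == pytest.approx(v, abs=1e-12)
        assert mare[0] == pytest.approx(np.zeros(4), abs=1e-15)  # rsq = 0 row
        assert beta[0] == pytest.approx(np.zeros(4), abs=1e-15)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            theoretical_surfaces([-0.1], [0.5])
        with pytest.raises(ValueError):
            theoretical_surfaces([0.5], [1.5])


def test_records_frame_columns(rng):
    recs = [decompose(X4, Y4, variant_key="1:100:A:G")]
    df = records_to_frame(recs)
    assert list(df["variant_key"]) == ["1:100:A:G"]
    assert df.loc[0, "maf"] == pytest.approx(0.5)
    assert df.loc[0, "flags"] == "ok"
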