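"""Haplotype-copying HMM: enumeration oracle, limits, and contracts."""

import numpy as np
import pytest

from imputeqc.hmm import (
    THETA_CEIL,
    THETA_FLOOR,
    DosageSet,
    HMMParams,
    forward_backward,
    impute,
    loo_dosage,
    scale_theta,
)

from conftest import enumerate_posterior, toy_panel


def params_for(panel, theta, eps):
    return HMMParams(
        theta=np.full(panel.n_markers - 1, theta),
        epsilon=np.full(panel.n_markers, eps),
    )


class TestWorkedExample:
    """Two haplotypes (0,0) and (1,1); allele 1 observed at the first
    marker; theta=0.1, eps=0.01: the untyped second marker splits
    0.941/0.059 between the matching and mismatching template."""

    def test_posterior(self, two_hap_panel):
        params = params_for(two_hap_panel, 0.1, 0.01)
        mask = np.array([True, False])
        post = forward_backward([1, -1], two_hap_panel, params, mask)
        assert post[1] == pytest.approx([0.059, 0.941], abs=1e-12)
        oracle = enumerate_posterior(
            two_hap_panel.alleles, params.theta, params.epsilon, [1, -1], mask
        )
        assert post == pytest.approx(oracle, abs=1e-12)

    def test_imputed_dosage(self, two_hap_panel):
        params = params_for(two_hap_panel, 0.1, 0.01)
        mask = np.array([True, False])
        ds = impute([1, -1], two_hap_panel, params, mask)
        assert ds.hds[1, 0] == pytest.approx(0.941, abs=1e-12)

    def test_loo_matches_masked_impute(self, two_hap_panel):
        """LOO at the second marker equals imputing with it hidden."""
        params = params_for(two_hap_panel, 0.1, 0.01)
        both = np.array([True, True])
        loo = loo_dosage([1, 1], two_hap_panel, params, both)
        assert loo[1] == pytest.approx(0.941, abs=1e-9)
        hidden = impute([1, -1], two_hap_panel, params, np.array([True, False]))
        assert loo[1] == pytest.approx(hidden.hds[1, 0], abs=1e-12)


def test_enumeration_oracle_random_instances(rng):
    """Forward-backward equals exhaustive path enumeration (H<=4, M<=5)."""
    for _ in range(200):
        H = int(rng.integers(1, 5))
        M = int(rng.integers(2, 6))
        panel = toy_panel(rng.integers(0, 2, size=(M, H)))
        theta = rng.uniform(0.01, 0.9, size=M - 1)
        eps = rng.uniform(0.001, 0.3, size=M)
        params = HMMParams(theta=theta, epsilon=eps)
        mask = rng.random(M) < 0.7
        mask[int(rng.integers(0, M))] = True  # at least one typed
        target = rng.integers(0, 2, size=M)
        post = forward_backward(target, panel, params, mask)
        oracle = enumerate_posterior(panel.alleles, theta, eps, target, mask)
        np.testing.assert_allclose(post, oracle, atol=1e-9)
        assert post.sum(axis=1) == pytest.approx(np.ones(M), abs=1e-9)


def test_single_haplotype_panel_posterior_is_one(rng):
    panel = toy_panel(rng.integers(0, 2, size=(6, 1)))
    params = params_for(panel, 0.3, 0.05)
    mask = np.ones(6, dtype=bool)
    post = forward_backward(rng.integers(0, 2, size=6), panel, params, mask)
    np.testing.assert_allclose(post, np.ones((6, 1)))
    ds = impute(panel.alleles[:, 0], panel, params, mask)
    # dosage leans to that haplotype's alleles for any eps < 0.5
    assert np.all((ds.hds[:, 0] > 0.5) == (panel.alleles[:, 0] > 0))


def test_theta_to_zero_concentrates_on_best_match(rng):
    """No-switch limit: posterior mass collapses onto the one matching
    haplotype at every marker."""
    M, H = 12, 5
    alleles = rng.integers(0, 2, size=(M, H))
    target = alleles[:, 2].copy()
    # make column 2 the unique exact match
    for h in range(H):
        if h != 2 and np.array_equal(alleles[:, h], target):
            alleles[0, h] = 1 - alleles[0, h]
    panel = toy_panel(alleles)
    params = params_for(panel, 1e-12, 0.01)
    post = forward_backward(target, panel, params, np.ones(M, dtype=bool))
    assert np.all(post[:, 2] >= 1 - 1e-6)


def test_theta_to_one_forgets_everything(rng):
    """Memoryless limit: an untyped marker bracketed by theta~1 intervals
    reverts to the panel allele frequency."""
    M, H = 5, 8
    alleles = rng.integers(0, 2, size=(M, H))
    panel = toy_panel(alleles)
    params = params_for(panel, 1 - 1e-12, 0.01)
    mask = np.array([True, True, False, True, True])
    ds = impute(alleles[:, 0], panel, params, mask)
    panel_aaf = alleles[2].mean()
    assert ds.hds[2, 0] == pytest.approx(panel_aaf, abs=1e-6)


def test_loo_single_typed_marker_is_prior_dosage(rng):
    M, H = 4, 6
    alleles = rng.integers(0, 2, size=(M, H))
    panel = toy_panel(alleles)
    params = params_for(panel, 0.2, 0.01)
    mask = np.array([False, True, False, False])
    loo = loo_dosage(alleles[:, 0], panel, params, mask)
    # with its only observation removed, the posterior is the uniform prior
    assert loo[1] == pytest.approx(alleles[1].mean(), abs=1e-12)


def test_loo_recovers_panel_member(rng):
    """A target that IS a panel haplotype gets its own alleles back from
    leave-one-out dosages when theta and eps are small."""
    M, H = 60, 30
    alleles = rng.integers(0, 2, size=(M, H))
    panel = toy_panel(alleles)
    params = params_for(panel, 0.005, 0.001)
    mask = np.ones(M, dtype=bool)
    target = alleles[:, 7]
    loo = loo_dosage(target, panel, params, mask)
    assert np.mean((loo > 0.5) == (target > 0)) > 0.95


def test_batch_matches_single_target(rng):
    M, H, T = 10, 6, 4
    panel = toy_panel(rng.integers(0, 2, size=(M, H)))
    params = params_for(panel, 0.1, 0.01)
    mask = rng.random(M) < 0.5
    mask[0] = True
    targets = rng.integers(0, 2, size=(M, T))
    batch = impute(targets, panel, params, mask).hds
    for t in range(T):
        single = impute(targets[:, t], panel, params, mask).hds[:, 0]
        np.testing.assert_allclose(batch[:, t], single, atol=1e-12)


def test_haplotype_relabeling_leaves_dosages_unchanged(rng):
    M, H = 15, 10
    alleles = rng.integers(0, 2, size=(M, H))
    panel = toy_panel(alleles)
    perm = rng.permutation(H)
    shuffled = toy_panel(alleles[:, perm])
    params = params_for(panel, 0.05, 0.01)
    mask = np.ones(M, dtype=bool)
    mask[::3] = False
    mask[0] = mask[-1] = True
    target = rng.integers(0, 2, size=M)
    a = impute(target, panel, params, mask).hds
    b = impute(target, shuffled, params, mask).hds
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_missing_target_allele_treated_as_untyped(two_hap_panel):
    params = params_for(two_hap_panel, 0.1, 0.01)
    mask = np.array([True, True])
    with_missing = impute([1, -1], two_hap_panel, params, mask).hds
    untyped = impute([1, -1], two_hap_panel, params, np.array([True, False])).hds
    np.testing.assert_allclose(with_missing, untyped, atol=1e-12)


def test_no_underflow_on_long_regions(rng):
    M, H = 5000, 20
    panel = toy_panel(rng.integers(0, 2, size=(M, H)))
    params = params_for(panel, 0.001, 0.001)
    mask = np.ones(M, dtype=bool)
    ds = impute(panel.alleles[:, 0], panel, params, mask)
    assert np.isfinite(ds.hds).all()
    assert 0 <= ds.hds.min() and ds.hds.max() <= 1


class TestScaleTheta:
    def test_identity_fold(self):
        p = HMMParams(theta=np.array([0.02, 0.3]), epsilon=np.full(3, 1e-3))
        q = scale_theta(p, 1.0)
        np.testing.assert_allclose(q.theta, p.theta)
        np.testing.assert_allclose(q.epsilon, p.epsilon)

    def test_clamping_at_ceiling(self):
        p = HMMParams(theta=np.array([0.02]), epsilon=np.full(2, 1e-3))
        q = scale_theta(p, 100.0)
        assert q.theta[0] == THETA_CEIL

    def test_halving(self):
        p = HMMParams(theta=np.array([0.02]), epsilon=np.full(2, 1e-3))
        assert scale_theta(p, 0.5).theta[0] == pytest.approx(0.01)

    def test_floor_and_provenance(self):
        p = HMMParams(theta=np.array([1e-9]), epsilon=np.full(2, 1e-3))
        q = scale_theta(p, 1e-6)
        assert q.theta[0] == THETA_FLOOR
        assert q.provenance == "manual"

    def test_nonpositive_fold_rejected(self):
        p = HMMParams(theta=np.array([0.02]), epsilon=np.full(2, 1e-3))
        with pytest.raises(ValueError):
            scale_theta(p, 0.0)


class TestValidation:
    def test_mask_without_typed_markers(self, two_hap_panel):
        params = params_for(two_hap_panel, 0.1, 0.01)
        with pytest.raises(ValueError, match="typed"):
            impute([1, 1], two_hap_panel, params, np.array([False, False]))

    def test_dimension_mismatch(self, two_hap_panel):
        params = HMMParams(theta=np.array([0.1, 0.1]), epsilon=np.full(3, 0.01))
        with pytest.raises(ValueError):
            impute([1, 1], two_hap_panel, params, np.array([True, False]))

    def test_oversize_panel_rejected(self, rng):
        panel = toy_panel(rng.integers(0, 2, size=(2, 2)))
        panel.alleles = np.zeros((2, 1001), dtype=np.int8)  # bypass ctor check
        params = HMMParams(theta=np.array([0.1]), epsilon=np.full(2, 0.01))
        with pytest.raises(ValueError, match="single-region"):
            impute([1, 1], panel, params, np.array([True, True]))

    def test_ds_pairs_hds_columns(self):
        hds = np.array([[0.941, 0.120], [0.0, 1.0]])
        ds = DosageSet(hds=hds)
        np.testing.assert_allclose(ds.ds[:, 0], [1.061, 1.0])
        with pytest.raises(ValueError, match="pair"):
            DosageSet(hds=np.zeros((2, 3))).ds
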