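"""Signatures (Wilcoxon signed-Z) and NES/PES enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from scipy.special import ndtri

import screg
from screg.enrichment import RankSumEngine, ges_normal_scores


# ---------------------------------------------------------------------------
# Wilcoxon signed-Z
# ---------------------------------------------------------------------------

def test_complete_separation():
    z, rb = screg.wilcoxon_signed_z([10, 11, 12], [1, 2, 3])
    assert rb == 1.0
    assert z > 0


def test_identical_groups_score_zero():
    z, rb = screg.wilcoxon_signed_z([1, 2, 3], [3, 1, 2])
    assert z == 0.0 and rb == 0.0


def test_all_tied_degenerate_warns():
    with pytest.warns(UserWarning, match="tied"):
        z, rb = screg.wilcoxon_signed_z([5, 5], [5, 5, 5])
    assert z == 0.0 and rb == 0.0


def _enumeration_p(group, rest):
    """Exact two-sided rank-sum p by direct enumeration (test oracle)."""
    pooled = np.concatenate([group, rest])
    ranks = rankdata(pooled)
    n1 = len(group)
    mu = n1 * len(rest) / 2.0
    base = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - base
    us = [ranks[list(s)].sum() - base
          for s in itertools.combinations(range(len(pooled)), n1)]
    us = np.array(us)
    return np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)


@pytest.mark.parametrize("group,rest", [
    ([2.0, 5.0, 7.5, 1.1, 9.0], [3.3, 4.4, 0.5, 6.6, 8.8]),
    ([1, 1, 2, 3, 4], [2, 2, 3, 5, 6]),       # ties across groups
    ([10, 12, 13], [1, 2, 3, 4, 5]),           # unbalanced, separated
])
def test_exact_p_matches_enumeration_oracle(group, rest):
    from scipy.stats import norm
    z, rb = screg.wilcoxon_signed_z(group, rest)
    p_impl = 2 * norm.sf(abs(z)) if z != 0 else 1.0
    assert p_impl == pytest.approx(_enumeration_p(group, rest), abs=1e-9)


def test_sign_follows_median_difference():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = rng.normal(2, 1, 30)
        b = rng.normal(-2, 1, 25)
        z, rb = screg.wilcoxon_signed_z(a, b)
        assert np.sign(z) == np.sign(np.median(a) - np.median(b))
        assert np.sign(rb) == np.sign(z)


def test_engine_matches_scalar_on_normal_path():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 25))
    X[:, :5] = np.round(X[:, :5])  # force ties in some genes
    mask = rng.random(40) < 0.4
    engine = RankSumEngine(X)
    zs = engine.signed_z(mask)
    for j in range(25):
        z_ref, _ = screg.wilcoxon_signed_z(X[mask, j], X[~mask, j])
        assert zs[j] == pytest.approx(z_ref, abs=1e-12)


# ---------------------------------------------------------------------------
# cluster / cell signatures
# ---------------------------------------------------------------------------

def test_cluster_signature_marks_exclusive_gene():
    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (60, 10))
    labels = np.array([0] * 30 + [1] * 30)
    X[labels == 0, 3] += 10  # gene 3 expressed only in cluster 0
    sigs = screg.cluster_signatures(X, labels, [f"g{i}" for i in range(10)])
    assert sigs[0].idxmax() == "g3"
    assert sigs.loc["g3", 1] < 0


def test_cluster_signature_null_calibration():
    # permuted labels: per-gene scores approximately standard normal
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 2000))
    labels = rng.permutation(np.array([0] * 50 + [1] * 50))
    sigs = screg.cluster_signatures(X, labels, [f"g{i}" for i in range(2000)])
    z = sigs[0].to_numpy()
    assert abs(z.mean()) < 0.05
    assert 0.9 < z.var() < 1.1


def test_singleton_cluster_warns():
    X = np.random.default_rng(4).normal(size=(5, 4))
    with pytest.warns(UserWarning, match="singleton"):
        screg.cluster_signatures(X, np.array([0, 1, 1, 1, 1]),
                                 [f"g{i}" for i in range(4)])


def test_scaled_ges_contracts():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 12))
    X[:, 0] = 1.0  # zero-variance gene dropped
    with pytest.warns(UserWarning, match="zero-variance"):
        ges = screg.scaled_expression_ges(X, [f"g{i}" for i in range(12)],
                                          [f"c{i}" for i in range(50)])
    assert "g0" not in ges.index
    np.testing.assert_allclose(ges.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(ges.std(axis=1, ddof=0), 1.0, atol=1e-9)
    with pytest.raises(ValueError):
        screg.scaled_expression_ges(X[:1], [f"g{i}" for i in range(12)], ["c0"])


def test_scaled_ges_value_is_standardized_expression():
    X = np.array([[0.0], [2.0], [4.0]])
    ges = screg.scaled_expression_ges(X, ["g0"], ["a", "b", "c"])
    sd = X[:, 0].std()
    assert ges.loc["g0", "c"] == pytest.approx((4 - 2) / sd)


# ---------------------------------------------------------------------------
# NES / PES
# ---------------------------------------------------------------------------

def _toy_ges(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])


def test_regulon_at_top_ranks_attains_extremal_nes():
    ges = _toy_ges()
    top = list(ges.sort_values(ascending=False).index[:20])
    reg = screg.Regulon("TF", top, np.ones(20), np.full(20, 1 / 20))
    res = screg.regulon_nes(ges, reg)
    q = np.sort(ges_normal_scores(ges).to_numpy())[::-1][:20]
    assert res.nes == pytest.approx(q.sum() / np.sqrt(20), abs=1e-9)
    assert res.pes == pytest.approx(1.0, abs=1e-12)


def test_mode_flip_negates_nes():
    ges = _toy_ges(seed=1)
    rng = np.random.default_rng(2)
    targets = list(rng.choice(ges.index, 15, replace=False))
    modes = rng.choice([1.0, -1.0], 15)
    w = rng.random(15)
    a = screg.regulon_nes(ges, screg.Regulon("TF", targets, modes, w))
    b = screg.regulon_nes(ges, screg.Regulon("TF", targets, -modes, w))
    assert a.nes == pytest.approx(-b.nes, abs=1e-12)
    assert a.pes == pytest.approx(-b.pes, abs=1e-12)


def test_nes_invariant_to_monotone_ges_transform():
    ges = _toy_ges(seed=3)
    reg = screg.Regulon("TF", list(ges.index[:25]), np.ones(25),
                        np.full(25, 0.04))
    a = screg.regulon_nes(ges, reg).nes
    b = screg.regulon_nes(np.exp(ges * 3) + 7, reg).nes
    assert a == pytest.approx(b, abs=1e-12)


def test_nes_split_half_additivity():
    ges = _toy_ges(seed=4)
    targets = list(ges.index[10:40])
    modes = np.ones(30)
    w = np.full(30, 1 / 30)
    full = screg.regulon_nes(ges, screg.Regulon("TF", targets, modes, w)).nes
    q = ges_normal_scores(ges)
    half_sums = [
        sum(w[i] * modes[i] * q[targets[i]] for i in idx)
        for idx in (range(15), range(15, 30))]
    assert full == pytest.approx(sum(half_sums) / np.sqrt((w ** 2).sum()),
                                 abs=1e-9)


def test_set_enrichment_pes_extremes():
    ges = _toy_ges(seed=5)
    ordered = ges.sort_values(ascending=False).index
    top = screg.set_enrichment(ges, list(ordered[:10]), set_id="up")
    bottom = screg.set_enrichment(ges, list(ordered[-10:]), set_id="down")
    assert top.pes == pytest.approx(1.0, abs=1e-12)
    assert bottom.pes == pytest.approx(-1.0, abs=1e-12)


def test_set_enrichment_requires_overlap():
    with pytest.raises(ValueError, match="no members"):
        screg.set_enrichment(_toy_ges(), ["absent1", "absent2"], set_id="x")


def test_random_set_pes_symmetric():
    ges = _toy_ges(n=2000, seed=6)
    q = ges_normal_scores(ges).to_numpy()
    rng = np.random.default_rng(7)
    idx = rng.integers(0, 2000, (10_000, 30))
    nes = q[idx].sum(axis=1) / np.sqrt(30)
    nes_max = np.sort(q)[::-1][:30].sum() / np.sqrt(30)
    pes = nes / nes_max
    assert abs(np.median(pes)) < 0.02
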