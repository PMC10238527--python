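"""MI estimation, permutation null, DPI pruning and network consolidation."""

import itertools

import numpy as np
import pytest

import screg
from screg.network import fit_mi_null, _bin_ids


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def test_mi_near_zero_for_shuffled_pairs():
    rng = np.random.default_rng(0)
    x = rng.normal(size=10_000)
    y = rng.permutation(x)
    assert screg.mutual_information(x, y, bins=10) < 0.01


def test_mi_identity_equals_log_bins_before_correction():
    x = np.random.default_rng(1).permutation(1000).astype(float)
    mi = screg.mutual_information(x, x, bins=10, corrected=False)
    assert mi == pytest.approx(np.log(10), abs=1e-12)


def test_mi_matches_analytic_value_on_known_joint():
    # sample a printed 3x3 joint law and compare the plug-in estimate with
    # the analytic sum p log(p / (p_row p_col))
    P = np.array([[0.20, 0.10, 0.05],
                  [0.05, 0.15, 0.10],
                  [0.08, 0.07, 0.20]])
    analytic = 0.0
    for i in range(3):
        for j in range(3):
            analytic += P[i, j] * np.log(P[i, j] / (P[i].sum() * P[:, j].sum()))
    rng = np.random.default_rng(2)
    flat = rng.choice(9, size=100_000, p=P.ravel())
    x, y = np.divmod(flat, 3)
    # average-rank ties put each discrete level into a single bin, so the
    # empirical joint law is evaluated exactly
    mi = screg.mutual_information(x.astype(float), y.astype(float), bins=3)
    assert mi == pytest.approx(analytic, abs=0.005)


def test_mi_symmetry():
    rng = np.random.default_rng(3)
    x = rng.normal(size=500)
    y = x + rng.normal(size=500)
    assert screg.mutual_information(x, y) == pytest.approx(
        screg.mutual_information(y, x), abs=1e-12)


def test_mi_constant_vector_warns_zero():
    with pytest.warns(UserWarning, match="constant"):
        assert screg.mutual_information(np.ones(100), np.arange(100.0)) == 0.0


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def null_fit():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(300, 50))
    return screg.null_mi_threshold(X, n_perm=2000, bins=6, seed=0)


def test_cutoff_at_alpha_one_is_minimum(null_fit):
    assert null_fit.cutoff(1.0) <= null_fit.null_sorted.min() + 1e-12


def test_pvalue_monotone_nonincreasing(null_fit):
    grid = np.linspace(0, null_fit.null_sorted.max() * 3, 200)
    p = null_fit.pvalue(grid)
    assert (np.diff(p) <= 1e-12).all()


def test_extrapolated_cutoff_beyond_sample(null_fit):
    assert null_fit.cutoff(1e-8) > null_fit.null_sorted.max()
    assert null_fit.pvalue(null_fit.cutoff(1e-6)) == pytest.approx(1e-6, rel=0.01)


def test_degenerate_null_errors():
    with pytest.raises(ValueError, match="degenerate"):
        fit_mi_null(np.zeros(1000))


# ---------------------------------------------------------------------------
# DPI
# ---------------------------------------------------------------------------

def test_dpi_removes_weakest_triangle_edge():
    edges = [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.2)]
    kept = screg.dpi_prune(edges, tolerance=0.0)
    assert sorted((a, b) for a, b, _ in kept) == [("a", "b"), ("b", "c")]


def test_dpi_leaves_open_chain_untouched():
    edges = [("a", "b", 0.9), ("b", "c", 0.1)]
    assert len(screg.dpi_prune(edges)) == 2


def _oracle_dpi(edges, tolerance):
    """Independent re-statement of the pruning rule via explicit dict scans."""
    mi = {tuple(sorted((a, b))): m for a, b, m in edges}
    nodes = sorted({n for a, b, _ in edges for n in (a, b)})
    alive = dict(mi)
    for a, b, c in itertools.combinations(nodes, 3):
        tri = [tuple(sorted(e)) for e in ((a, b), (a, c), (b, c))]
        if not all(t in alive for t in tri):
            continue
        ranked = sorted(tri, key=lambda t: (mi[t], t))
        if mi[ranked[0]] < (1 - tolerance) * min(mi[ranked[1]], mi[ranked[2]]):
            del alive[ranked[0]]
    return set(alive)


@pytest.mark.parametrize("tolerance", [0.0, 0.15])
def test_dpi_matches_bruteforce_oracle(tolerance):
    rng = np.random.default_rng(7)
    for _ in range(30):
        nodes = [f"n{i}" for i in range(10)]
        edges = []
        for i, j in itertools.combinations(range(10), 2):
            if rng.random() < 0.4:
                edges.append((nodes[i], nodes[j], float(rng.random())))
        kept = {tuple(sorted((a, b))) for a, b, _ in
                screg.dpi_prune(edges, tolerance=tolerance)}
        assert kept == _oracle_dpi(edges, tolerance)
        assert kept <= {tuple(sorted((a, b))) for a, b, _ in edges}


def test_dpi_output_has_no_violating_triangle():
    rng = np.random.default_rng(8)
    for _ in range(10):
        edges = [(f"n{i}", f"n{j}", float(rng.random()))
                 for i, j in itertools.combinations(range(8), 2)
                 if rng.random() < 0.6]
        kept = screg.dpi_prune(edges, tolerance=0.0)
        mi = {tuple(sorted((a, b))): m for a, b, m in kept}
        nodes = sorted({n for a, b, _ in kept for n in (a, b)})
        for a, b, c in itertools.combinations(nodes, 3):
            tri = [tuple(sorted(e)) for e in ((a, b), (a, c), (b, c))]
            if all(t in mi for t in tri):
                vals = sorted(mi[t] for t in tri)
                assert vals[0] >= vals[1]  # weakest not strictly below the others


# ---------------------------------------------------------------------------
# bootstrap consolidation + regulon assembly on a small planted system
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_metacells():
    rng = np.random.default_rng(11)
    n, n_targets = 120, 8
    act = rng.normal(0, 1, n)
    cols = {"R1": np.exp(act + rng.normal(0, 0.3, n))}
    for t in range(n_targets):
        mode = 1 if t % 2 == 0 else -1
        cols[f"T{t}"] = np.exp(mode * act + rng.normal(0, 0.3, n))
    for f in range(20):
        cols[f"F{f}"] = np.exp(rng.normal(0, 1, n))
    genes = sorted(cols)
    M = np.column_stack([cols[g] for g in genes]) * 1000
    M = M / M.sum(axis=1, keepdims=True) * 1e6
    return screg.MetacellMatrix(matrix=M, genes=genes, is_cpm=True)


def test_bootstrap_consolidation_recovers_planted_edges(planted_metacells):
    edges = screg.bootstrap_consolidate(
        planted_metacells, {"TF": ["R1"]}, n_boot=20, alpha=1e-3,
        n_perm=1000, bins=6, seed=0)
    called = set(edges["target"])
    true = {f"T{t}" for t in range(8)}
    assert len(called & true) >= 6          # strong planted deps found
    assert len(called - true) <= 2          # few spurious targets
    full = edges[edges["support"] == 20]
    assert set(full["target"]) <= called


def test_bootstrap_deterministic(planted_metacells):
    kw = dict(n_boot=10, alpha=1e-3, n_perm=1000, bins=6, seed=3)
    e1 = screg.bootstrap_consolidate(planted_metacells, {"TF": ["R1"]}, **kw)
    e2 = screg.bootstrap_consolidate(planted_metacells, {"TF": ["R1"]}, **kw)
    assert e1.equals(e2)


def test_assemble_regulons_modes_weights(planted_metacells):
    edges = screg.bootstrap_consolidate(
        planted_metacells, {"TF": ["R1"]}, n_boot=20, alpha=1e-3,
        n_perm=1000, bins=6, seed=0)
    regs = screg.assemble_regulons(edges, planted_metacells, min_targets=3)
    assert len(regs) == 1
    reg = regs[0]
    assert reg.weights.sum() == pytest.approx(1.0, abs=1e-9)
    for t, m in zip(reg.targets, reg.modes):
        if t.startswith("T"):
            true_mode = 1 if int(t[1:]) % 2 == 0 else -1
            assert np.sign(m) == true_mode


def test_assemble_min_targets_boundary(planted_metacells):
    edges = screg.bootstrap_consolidate(
        planted_metacells, {"TF": ["R1"]}, n_boot=10, alpha=1e-3,
        n_perm=1000, bins=6, seed=0)
    with pytest.warns(UserWarning, match="min_targets"):
        assert screg.assemble_regulons(edges, planted_metacells,
                                       min_targets=10_000) == []


def test_nboot_guard(planted_metacells):
    with pytest.raises(ValueError, match="n_boot"):
        screg.bootstrap_consolidate(planted_metacells, {"TF": ["R1"]}, n_boot=1)


def test_bin_ids_equal_frequency():
    ids = _bin_ids(np.random.default_rng(0).permutation(100).astype(float), 5)
    assert (np.bincount(ids, minlength=5) == 20).all()
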