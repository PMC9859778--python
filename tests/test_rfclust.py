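import numpy as np
import pytest

from gmsubtype import (average_linkage, gini_importance,
                       proximity_to_dissimilarity, rf_proximity, select_k,
                       stability_assessment, supervised_discrimination)
from gmsubtype.rfclust import LinkageTree, ProximityMatrix
from reference_oracles import brute_force_average_linkage


def _blobs(n_per, p, gap, seed=0):
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for i, n in enumerate(n_per):
        parts.append(rng.normal(i * gap, 1.0, (n, p)))
        labels += [i + 1] * n
    return np.vstack(parts), np.array(labels)


# ---------------------------------------------------------------------------
# proximity

def test_proximity_contract():
    X, _ = _blobs((12, 12), 6, 4.0)
    prox = rf_proximity(X, n_trees=200, seed=0, forest_repeats=1)
    v = prox.values
    assert np.allclose(v, v.T)
    assert np.allclose(np.diag(v), 1.0)
    assert v.min() >= 0.0 and v.max() <= 1.0


def test_two_blobs_within_exceeds_between():
    X, labels = _blobs((20, 20), 10, 5.0, seed=1)
    prox = rf_proximity(X, n_trees=500, seed=1, forest_repeats=1).values
    a, b = labels == 1, labels == 2
    within = (prox[np.ix_(a, a)].sum() - 20) / (20 * 19)
    between = prox[np.ix_(a, b)].mean()
    assert within > between


def test_duplicated_rows_have_top_proximity():
    """A duplicated subject pair is each other's nearest neighbour in
    proximity for nearly every forest seed."""
    rng = np.random.default_rng(4)
    X = rng.normal(0, 1, (20, 5))
    X[7] = X[3]  # exact duplicate
    hits = 0
    for seed in range(20):
        prox = rf_proximity(X, n_trees=200, seed=seed, forest_repeats=1).values
        others = np.delete(prox[3], [3, 7])
        if prox[3, 7] >= others.max():
            hits += 1
    assert hits >= 19


def test_proximity_input_validation():
    X = np.zeros((10, 4))
    with pytest.raises(ValueError, match="constant"):
        rf_proximity(X, n_trees=100, seed=0)
    X = np.random.default_rng(0).normal(0, 1, (10, 4))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        rf_proximity(X, n_trees=100, seed=0)
    with pytest.raises(ValueError, match="n_trees"):
        rf_proximity(np.random.default_rng(0).normal(0, 1, (10, 4)),
                     n_trees=50, seed=0)


def test_dissimilarity_closed_forms():
    P = np.array([[1.0, 0.75, 0.0], [0.75, 1.0, 1.0], [0.0, 1.0, 1.0]])
    prox = ProximityMatrix(values=P, n_trees=100, seed=0)
    d = proximity_to_dissimilarity(prox)
    assert d[0, 1] == pytest.approx(0.5)      # sqrt(1 - 0.75)
    assert d[0, 2] == pytest.approx(1.0)      # proximity 0 -> distance 1
    assert d[1, 2] == pytest.approx(0.0)      # proximity 1 -> distance 0
    assert np.allclose(np.diag(d), 0.0)
    lin = proximity_to_dissimilarity(prox, transform="linear")
    assert lin[0, 1] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# average linkage

def test_forced_merge_order():
    """d(1,2)=1 and d(3,4)=1.5 with all cross-distances >= 4 force the
    first merge at height 1 and the second at 1.5."""
    D = np.full((4, 4), 5.0)
    np.fill_diagonal(D, 0.0)
    D[0, 1] = D[1, 0] = 1.0
    D[2, 3] = D[3, 2] = 1.5
    tree = average_linkage(D)
    assert tree.heights[0] == pytest.approx(1.0)
    assert tree.heights[1] == pytest.approx(1.5)
    assert sorted(tree.merges[0, :2].astype(int).tolist()) == [0, 1]
    assert sorted(tree.merges[1, :2].astype(int).tolist()) == [2, 3]


@pytest.mark.parametrize("n", [5, 8, 12])
def test_matches_brute_force_oracle(n):
    rng = np.random.default_rng(n)
    for _ in range(25):
        A = rng.random((n, n))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = average_linkage(D)
        assert np.allclose(np.sort(tree.heights),
                           np.sort(brute_force_average_linkage(D)), atol=1e-10)


def test_ultrametric_fixed_point():
    """Cophenetic distances of an ultrametric input reproduce it exactly."""
    # 2-level ultrametric on 4 leaves
    D = np.array([[0, 1, 3, 3],
                  [1, 0, 3, 3],
                  [3, 3, 0, 2],
                  [3, 3, 2, 0]], dtype=float)
    tree = average_linkage(D)
    assert np.allclose(tree.cophenetic(), D)


def test_linkage_input_validation():
    D = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        average_linkage(D)
    D = np.array([[0.0, -1.0], [-1.0, 0.0]])
    with pytest.raises(ValueError, match="non-negative"):
        average_linkage(D)


def test_newick_export_parses():
    X, _ = _blobs((5, 5), 4, 6.0, seed=2)
    prox = rf_proximity(X, n_trees=200, seed=0, forest_repeats=1)
    tree = average_linkage(proximity_to_dissimilarity(prox))
    newick = tree.to_newick([f"s{i}" for i in range(10)])
    import io
    from Bio import Phylo
    parsed = Phylo.read(io.StringIO(newick), "newick")
    assert len(parsed.get_terminals()) == 10


# ---------------------------------------------------------------------------
# K selection

def test_ch_closed_form_oracle():
    """CH on {0,0.1,0.2, 10,10.1,10.2} at K=2 equals the hand-computed
    15000 (SSB=150, SSW=0.04, K=2, n=6)."""
    X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
    D = np.abs(X - X.T)
    tree = average_linkage(D)
    sol = select_k(tree, X, k_range=(2, 3, 4, 5))
    assert sol.ch_by_k[2] == pytest.approx(15000.0, rel=1e-9)
    assert sol.chosen_k == 2


def test_three_blob_pipeline_recovery():
    """Three well-separated blobs: chosen K = 3 and perfect agreement
    with the planted labels."""
    from sklearn.metrics import adjusted_rand_score
    X, labels = _blobs((20, 20, 20), 10, 6.0, seed=3)
    prox = rf_proximity(X, n_trees=500, seed=3, forest_repeats=2)
    tree = average_linkage(proximity_to_dissimilarity(prox))
    sol = select_k(tree, X)
    assert sol.chosen_k == 3
    assert adjusted_rand_score(labels, sol.labels) == 1.0


def test_k_range_validation():
    X, _ = _blobs((4, 4), 3, 5.0)
    prox = rf_proximity(X, n_trees=100, seed=0, forest_repeats=1)
    tree = average_linkage(proximity_to_dissimilarity(prox))
    with pytest.raises(ValueError, match="exceed"):
        select_k(tree, X, k_range=range(2, 9))


def test_ch_invariant_to_rotation_and_relabeling():
    rng = np.random.default_rng(6)
    X, _ = _blobs((15, 15, 15), 8, 5.0, seed=6)
    prox = rf_proximity(X, n_trees=300, seed=6, forest_repeats=1)
    tree = average_linkage(proximity_to_dissimilarity(prox))
    sol = select_k(tree, X, k_range=(2, 3, 4))
    Q, _ = np.linalg.qr(rng.normal(0, 1, (8, 8)))
    sol_rot = select_k(tree, X @ Q, k_range=(2, 3, 4))
    for k in (2, 3, 4):
        assert sol.ch_by_k[k] == pytest.approx(sol_rot.ch_by_k[k], rel=1e-9)


# ---------------------------------------------------------------------------
# importance & discrimination

def test_planted_signal_roi_ranks_first():
    """One ROI carrying the full cluster separation ranks first for
    nearly every forest seed; 95 others are pure noise."""
    rng = np.random.default_rng(12)
    labels = np.repeat([1, 2, 3], 30)
    hits = 0
    for seed in range(20):
        X = rng.normal(0, 1, (90, 96))
        X[:, 40] = np.repeat([0.0, 6.0, 12.0], 30) + rng.normal(0, 0.5, 90)
        ranking = gini_importance(X, labels, n_trees=300, seed=seed)
        if ranking.ranking[0] == "f40":
            hits += 1
    assert hits >= 19


def test_importance_contract_and_row_order_invariance():
    rng = np.random.default_rng(5)
    X, labels = _blobs((15, 15), 10, 3.0, seed=5)
    r1 = gini_importance(X, labels, n_trees=200, seed=0)
    assert (r1.scores >= 0).all() and r1.scores.sum() > 0
    assert sorted(r1.ranking) == sorted(r1.scores.index)
    perm = rng.permutation(len(labels))
    r2 = gini_importance(X[perm], labels[perm], n_trees=200, seed=0)
    assert r1.ranking == r2.ranking
    assert np.allclose(r1.scores.to_numpy(), r2.scores.to_numpy())


def test_single_cluster_labels_rejected():
    X, _ = _blobs((10, 10), 5, 3.0)
    with pytest.raises(ValueError, match="2 clusters"):
        gini_importance(X, np.ones(20), n_trees=200, seed=0)


def test_discrimination_recovers_planted_separations():
    """ROI A low in clusters 1 and 2 separates {1,2} from {3}; ROI B low
    in cluster 1 only separates {1} from the others."""
    rng = np.random.default_rng(17)
    labels = np.repeat([1, 2, 3], 40)
    X = rng.normal(0, 1, (120, 4))
    X[labels != 3, 0] -= 5.0   # A: low in 1 & 2
    X[labels == 1, 1] -= 5.0   # B: low in 1 only
    import pandas as pd
    Xdf = pd.DataFrame(X, columns=["A", "B", "n1", "n2"])
    summ = supervised_discrimination(Xdf, labels, n_trees=300, seed=0)
    assert summ.separations["A"] == ((1, 2), (3,))
    low_b, high_b = summ.separations["B"]
    assert 1 in low_b and 2 in high_b
    assert summ.oob_accuracy >= 0.95


def test_shuffled_labels_give_chance_accuracy():
    rng = np.random.default_rng(23)
    X, labels = _blobs((30, 30, 30), 8, 6.0, seed=23)
    shuffled = rng.permutation(labels)
    summ = supervised_discrimination(X, shuffled, n_trees=300, seed=1)
    majority = 1 / 3
    se = np.sqrt(majority * (1 - majority) / len(labels))
    assert abs(summ.oob_accuracy - majority) <= 3 * se


# ---------------------------------------------------------------------------
# stability

def test_self_repeat_difference_is_zero():
    X, _ = _blobs((12, 12), 6, 5.0, seed=9)
    main = rf_proximity(X, n_trees=200, seed=10, forest_repeats=1)
    rep = rf_proximity(X, n_trees=200, seed=10, forest_repeats=1)
    assert np.array_equal(main.values, rep.values)
    iu = np.triu_indices(24, 1)
    assert np.abs(main.values[iu] - rep.values[iu]).mean() == 0.0


def test_separated_data_more_stable_than_noise():
    """Structure stabilizes the proximity matrix: repeat-to-repeat
    differences relative to the typical proximity level are larger for
    pure-noise data than for well-separated blobs.  (The absolute mean
    difference is not comparable across the two cases because the
    noise matrix sits at a much lower proximity level overall.)"""
    X_sep, _ = _blobs((20, 20), 8, 6.0, seed=14)
    X_noise = np.random.default_rng(14).normal(0, 1, (40, 8))
    iu = np.triu_indices(40, 1)
    main_sep = rf_proximity(X_sep, n_trees=500, seed=0, forest_repeats=1)
    main_noise = rf_proximity(X_noise, n_trees=500, seed=0, forest_repeats=1)
    rep_sep = stability_assessment(X_sep, main_sep, n_repeats=5, base_seed=0)
    rep_noise = stability_assessment(X_noise, main_noise, n_repeats=5,
                                     base_seed=0)
    assert (rep_noise.differences > 0).all()
    rel_sep = rep_sep.mean / main_sep.values[iu].mean()
    rel_noise = rep_noise.mean / main_noise.values[iu].mean()
    assert rel_noise > rel_sep


def test_stability_validation():
    X, _ = _blobs((10, 10), 5, 4.0)
    main = rf_proximity(X, n_trees=100, seed=0, forest_repeats=1)
    with pytest.raises(ValueError, match="n_repeats"):
        stability_assessment(X, main, n_repeats=0, base_seed=0)
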