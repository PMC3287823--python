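import numpy as np
import pytest

import raremark as rm
from raremark.trees import TreeSpec, fit_tree, run_ensemble


def exhaustive_best_root_split(X, y):
    """Brute-force Gini-gain search over every feature and midpoint
    threshold; returns (best_gain, set of argmax features)."""
    def gini(v):
        if len(v) == 0:
            return 0.0
        p = v.mean()
        return 1 - p * p - (1 - p) * (1 - p)

    n = len(y)
    parent = gini(y)
    best, argmax = -1.0, set()
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for t in (vals[:-1] + vals[1:]) / 2:
            left = y[X[:, j] <= t]
            right = y[X[:, j] > t]
            gain = parent - (len(left) * gini(left) + len(right) * gini(right)) / n
            if gain > best + 1e-12:
                best, argmax = gain, {j}
            elif abs(gain - best) <= 1e-12:
                argmax.add(j)
    return best, argmax


def test_pure_phenotype_gives_zero_splits():
    X = np.random.default_rng(0).normal(size=(40, 3))
    tree = fit_tree(X, np.zeros(40))
    assert tree.n_splits == 0


def test_root_split_matches_exhaustive_gini_search():
    rng = np.random.default_rng(1)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 80
        y = rng.binomial(1, 0.5, n)
        X = rng.normal(size=(n, 8))
        X[:, 3] += 1.5 * y  # informative feature
        tree = fit_tree(X, y, TreeSpec(), seed=seed)
        assert tree.n_splits >= 1
        root_feature = int(tree.clf.tree_.feature[0])
        _, argmax = exhaustive_best_root_split(X, y)
        assert root_feature in argmax


def test_perfect_binary_marker_takes_the_root():
    rng = np.random.default_rng(2)
    n = 80
    y = np.r_[np.ones(40), np.zeros(40)].astype(int)
    X = rng.normal(size=(n, 6))
    X[:, 2] = y  # perfect separator
    tree = fit_tree(X, y, TreeSpec(), seed=0)
    assert int(tree.clf.tree_.feature[0]) == 2
    assert tree.n_splits == 1  # children are pure


def test_node_below_min_size_is_not_split():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(19, 4))
    y = rng.binomial(1, 0.5, 19)
    tree = fit_tree(X, y, TreeSpec(min_node_to_split=20, min_leaf=7))
    assert tree.n_splits == 0


def test_trees_are_deterministic_and_sizes_are_structural():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(200, 10))
    y = rng.binomial(1, 0.5, 200)
    t1 = fit_tree(X, y, seed=5)
    t2 = fit_tree(X, y, seed=5)
    np.testing.assert_array_equal(t1.clf.tree_.feature, t2.clf.tree_.feature)
    np.testing.assert_array_equal(t1.clf.tree_.threshold, t2.clf.tree_.threshold)
    # s_i equals the number of internal nodes
    assert t1.n_splits == int((t1.clf.tree_.feature >= 0).sum())


def test_every_split_clears_the_complexity_gate():
    """Each internal node's population-weighted impurity decrease is at
    least complexity_penalty x root impurity."""
    rng = np.random.default_rng(6)
    n = 300
    y = rng.binomial(1, 0.5, n)
    X = rng.normal(size=(n, 8))
    X[:, 0] += 0.8 * y
    spec = TreeSpec(complexity_penalty=0.01)
    tree = fit_tree(X, y, spec, seed=0)
    t = tree.clf.tree_
    p = y.mean()
    root_gini = 1 - p * p - (1 - p) * (1 - p)
    for node in range(t.node_count):
        if t.feature[node] < 0:
            continue
        left, right = t.children_left[node], t.children_right[node]
        w = t.weighted_n_node_samples
        decrease = (
            w[node] * t.impurity[node]
            - w[left] * t.impurity[left]
            - w[right] * t.impurity[right]
        ) / n
        assert decrease >= spec.complexity_penalty * root_gini - 1e-12


def _binary_marker_set(columns, subject_ids):
    markers = [
        rm.CompositeMarker(f"m{j}", f"g{j}", (f"v{j}",), np.array([1.0]), col)
        for j, col in enumerate(columns)
    ]
    return rm.MarkerSet(subject_ids, markers)


def test_usage_counts_distinct_per_tree_convention():
    """Replicates engineered so each evaluation tree splits once on a known
    marker: usage counts reflect one count per tree, S sums tree sizes."""
    rng = np.random.default_rng(7)
    n = 60
    m0 = (rng.uniform(size=n) < 0.5).astype(float)
    m1 = (rng.uniform(size=n) < 0.5).astype(float)
    subject_ids = [f"s{i}" for i in range(n)]
    markers = _binary_marker_set([m0, m1], subject_ids)
    # construction replicate 0 is noise; reps 1-2 equal marker0, rep 3 marker1
    values = np.column_stack([
        rng.binomial(1, 0.5, n), m0, m0, m1,
    ]).astype(np.int8)
    phen = rm.PhenotypeReplicates(subject_ids, values)
    usage = run_ensemble(markers, None, phen, construction_replicate_index=0)
    assert list(usage.counts) == [2, 1]
    assert usage.S == int(usage.tree_sizes.sum())
    assert usage.mean_markers_per_tree == pytest.approx(1.0)
    # with single-split trees both conventions agree
    assert list(usage.split_counts) == [2, 1]


def test_covariate_splits_never_attributed_to_markers(qc_cohort, built_markers):
    _, _, cov, phen, _, _, _ = qc_cohort
    markers, _ = built_markers
    usage = run_ensemble(markers, cov, phen, 0, seed=1)
    assert usage.split_counts.sum() + usage.n_covariate_splits == usage.S
    assert (usage.counts <= usage.split_counts).all()
    assert (usage.counts <= len(usage.tree_sizes)).all()


def test_null_usage_counts_consistent_with_binomial_split_null():
    """Under phenotype independence with *identically distributed* binary
    markers — the symmetric case the equal-selection null describes — the
    per-marker split counts pass a multinomial goodness-of-fit at the 1%
    level in at least 90% of seeds. (Markers with heterogeneous value
    distributions are systematically over-dispersed relative to this null;
    see the family-wise error checks for the practical consequence.)"""
    from scipy.stats import chisquare

    passes = 0
    n_seeds = 12
    M, n = 50, 300
    for seed in range(n_seeds):
        ss = np.random.SeedSequence(seed + 100).generate_state(2) % (2**31)
        rng = np.random.default_rng(int(ss[1]))
        cfg = rm.CohortConfig(
            n_subjects=n, n_populations=2, n_variants=10, n_genes=1,
            n_chromosomes=1, n_replicates=60, seed=int(ss[0]),
        )
        _, _, cov, phen, _ = rm.generate_cohort(cfg)
        vals = (rng.uniform(size=(n, M)) < 0.2).astype(float)
        markers = rm.MarkerSet(
            [f"S{i:04d}" for i in range(n)],
            [rm.CompositeMarker(f"m{j}", f"g{j}", (f"v{j}",),
                                np.array([1.0]), vals[:, j])
             for j in range(M)],
        )
        usage = run_ensemble(markers, cov, phen, 0, seed=int(ss[0]))
        assert usage.split_counts.sum() >= 100
        _, p = chisquare(usage.split_counts)
        passes += p >= 0.01
    assert passes >= 0.9 * n_seeds - 1


def test_ensemble_requires_two_replicates(built_markers, qc_cohort):
    markers, _ = built_markers
    _, _, cov, phen, _, _, _ = qc_cohort
    one_rep = rm.PhenotypeReplicates(phen.subject_ids, phen.values[:, :1])
    with pytest.raises(rm.ValidationError):
        run_ensemble(markers, cov, one_rep, 0)
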