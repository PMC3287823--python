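"""Classification-tree association analyses across phenotype replicates.

One CART tree (Gini impurity, greedy binary splits) is fitted per phenotype
replicate on the composite markers plus covariates; the replicate used for
marker construction is excluded. The evidence statistic for a marker is how
often it is chosen as a splitting variable across the ensemble. Two
counting conventions are kept:

* ``counts`` (default): a marker is counted once per tree it splits in;
* ``split_counts``: every split on the marker counts, even within one tree.

``S`` is always the raw total number of splits over all trees (the sum of
per-tree sizes ``s_i``), covariate splits included; covariate splits never
count toward any marker.

Trees are grown with rpart-like gates: a node needs ``min_node_to_split``
subjects to be split, leaves keep at least ``min_leaf``, and a split must
improve population-weighted Gini impurity by at least
``complexity_penalty`` times the root impurity (a pre-pruning analogue of
the cost-complexity parameter). Fitting is delegated to scikit-learn's
DecisionTreeClassifier; trees are deterministic given inputs, spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .io import CovariateTable, MarkerSet, PhenotypeReplicates, ValidationError


@dataclass
class TreeSpec:
    """rpart-flavored growth controls."""

    min_node_to_split: int = 20
    min_leaf: int = 7
    complexity_penalty: float = 0.01
    max_depth: int = 30

    def __post_init__(self) -> None:
        if self.complexity_penalty < 0:
            raise ValidationError("complexity_penalty must be >= 0")
        if self.min_leaf > self.min_node_to_split // 2:
            raise ValidationError("need min_leaf <= min_node_to_split/2")


@dataclass
class FittedTree:
    """A fitted CART tree plus bookkeeping over its splits."""

    clf: DecisionTreeClassifier | None
    n_features: int

    @property
    def split_features(self) -> np.ndarray:
        """Feature index of every internal node (one entry per split)."""
        if self.clf is None:
            return np.array([], dtype=int)
        feat = self.clf.tree_.feature
        return feat[feat >= 0]

    @property
    def n_splits(self) -> int:
        """Tree size s_i: the number of internal nodes."""
        return int(len(self.split_features))


def _gini(y: np.ndarray) -> float:
    p = np.mean(y)
    return float(1.0 - p * p - (1.0 - p) * (1.0 - p))


def fit_tree(
    features: np.ndarray,
    phenotype: np.ndarray,
    spec: TreeSpec | None = None,
    seed: int = 0,
) -> FittedTree:
    """Grow one classification tree; a constant phenotype yields a stump."""
    spec = spec or TreeSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(phenotype)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and phenotype are misaligned")
    if len(np.unique(y)) < 2:
        return FittedTree(clf=None, n_features=X.shape[1])
    clf = DecisionTreeClassifier(
        criterion="gini",
        min_samples_split=spec.min_node_to_split,
        min_samples_leaf=spec.min_leaf,
        max_depth=spec.max_depth,
        min_impurity_decrease=spec.complexity_penalty * _gini(y),
        random_state=seed,
    )
    clf.fit(X, y)
    return FittedTree(clf=clf, n_features=X.shape[1])


@dataclass
class UsageCounts:
    """Marker-usage tallies across the tree ensemble."""

    marker_ids: list[str]
    counts: np.ndarray          # distinct-per-tree convention
    split_counts: np.ndarray    # per-split convention
    tree_sizes: np.ndarray      # s_i per evaluation replicate
    n_covariate_splits: int
    S: int = field(init=False)

    def __post_init__(self) -> None:
        self.S = int(self.tree_sizes.sum())

    @property
    def M(self) -> int:
        return len(self.marker_ids)

    @property
    def mean_markers_per_tree(self) -> float:
        n_trees = len(self.tree_sizes)
        return float(self.counts.sum() / n_trees) if n_trees else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "count": self.counts,
                "split_count": self.split_counts,
            }
        )


def run_ensemble(
    markers: MarkerSet,
    covariates: CovariateTable | None,
    replicates: PhenotypeReplicates,
    construction_replicate_index: int = 0,
    spec: TreeSpec | None = None,
    seed: int = 0,
) -> UsageCounts:
    """Fit one tree per evaluation replicate and tally marker usage.

    The construction replicate is excluded; with R replicates in total the
    ensemble holds R - 1 trees. Markers occupy the leading feature columns,
    covariates the trailing ones (their splits are recorded in
    ``n_covariate_splits`` but never attributed to markers).
    """
    if replicates.n_replicates < 2:
        raise ValidationError("tree ensemble needs >= 1 evaluation replicate")
    if not (0 <= construction_replicate_index < replicates.n_replicates):
        raise ValidationError("construction replicate index out of range")
    Xm = markers.value_matrix()
    M = Xm.shape[1]
    blocks = [Xm]
    if covariates is not None:
        Z, _ = covariates.design_matrix()
        blocks.append(Z)
    X = np.column_stack(blocks) if blocks else Xm

    counts = np.zeros(M, dtype=int)
    split_counts = np.zeros(M, dtype=int)
    sizes = []
    n_cov_splits = 0
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.generate_state(replicates.n_replicates) % (2**31)
    for r in range(replicates.n_replicates):
        if r == construction_replicate_index:
            continue
        tree = fit_tree(X, replicates.values[:, r], spec, seed=int(tree_seeds[r]))
        feats = tree.split_features
        sizes.append(tree.n_splits)
        marker_feats = feats[feats < M]
        n_cov_splits += int((feats >= M).sum())
        np.add.at(split_counts, marker_feats, 1)
        for f in np.unique(marker_feats):
            counts[f] += 1
    return UsageCounts(
        marker_ids=list(markers.marker_ids),
        counts=counts,
        split_counts=split_counts,
        tree_sizes=np.asarray(sizes, dtype=int),
        n_covariate_splits=n_cov_splits,
    )
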