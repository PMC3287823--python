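"""Significance calls for marker-usage counts.

Under the null of no marker-phenotype association (conditional on the
covariates), each of the M exchangeable markers is equally likely to be the
variable chosen at any split, so a given marker's total occurrence count
across an ensemble with S splits is Binomial(S, 1/M), with split choices
treated as independent. With a Bonferroni-corrected family-wise level
``alpha`` the per-marker level is ``alpha/M`` and the critical count is the
(1 - alpha/M) quantile of Bin(S, 1/M) — the smallest integer q whose CDF
reaches 1 - alpha/M. A marker whose count *meets or exceeds* the critical
value is declared genome-wide significant.

The quantile convention matters: the stricter "smallest k whose upper tail
is below alpha/M" rule gives a threshold one higher at typical sizes; the
inverse-CDF rule used here is the one under which an ensemble of 199 trees
averaging 11.37 markers each (S = 2263) with M = 493 yields the critical
count 14.

The binomial null leans on exchangeability, which real marker sets violate;
a permutation alternative (randomly permuting affection status and
refitting the tree) is provided for single-replicate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io import CovariateTable, MarkerSet, ValidationError
from .trees import TreeSpec, UsageCounts, fit_tree


@dataclass
class SignificanceConfig:
    alpha: float = 0.05
    method: str = "binomial"  # "binomial" | "permutation"
    n_permutations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.method not in ("binomial", "permutation"):
            raise ValidationError(f"unknown method {self.method!r}")


def binomial_critical_value(S: int, M: int, alpha: float = 0.05) -> int:
    """(1 - alpha/M) quantile of Binomial(S, 1/M).

    The smallest integer q with CDF(q) >= 1 - alpha/M; 0 when S = 0.
    """
    if S < 0 or M < 1:
        raise ValidationError("need S >= 0 and M >= 1")
    if S == 0:
        return 0
    return int(binom.ppf(1.0 - alpha / M, S, 1.0 / M))


@dataclass
class SignificanceResult:
    marker_ids: list[str]
    counts: np.ndarray
    critical_value: int
    S: int
    M: int
    alpha: float
    method: str
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.counts >= self.critical_value

    @property
    def per_marker_level(self) -> float:
        """Bonferroni per-marker significance level alpha / M."""
        return self.alpha / self.M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "count": self.counts,
                "critical_value": self.critical_value,
                "significant": self.significant,
                "method": self.method,
            }
        )


def call_significant(
    usage: UsageCounts, config: SignificanceConfig | None = None
) -> SignificanceResult:
    """Flag markers whose usage count meets or exceeds the binomial critical
    value. An empty ensemble (S = 0) flags nothing: the threshold is floored
    at one occurrence."""
    config = config or SignificanceConfig()
    q = binomial_critical_value(usage.S, usage.M, config.alpha) if usage.M else 0
    return SignificanceResult(
        marker_ids=list(usage.marker_ids),
        counts=usage.counts.copy(),
        critical_value=max(q, 1),
        S=usage.S,
        M=usage.M,
        alpha=config.alpha,
        method="binomial",
    )


@dataclass
class PermutationResult:
    marker_ids: list[str]
    observed_counts: np.ndarray
    critical_value: int
    pvalues: np.ndarray
    null_max_counts: np.ndarray
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.observed_counts >= self.critical_value


def permutation_null(
    markers: MarkerSet,
    covariates: CovariateTable | None,
    phenotype: np.ndarray,
    spec: TreeSpec | None = None,
    config: SignificanceConfig | None = None,
) -> PermutationResult:
    """Permutation-based significance for a single-replicate tree analysis.

    Affection status is randomly permuted ``n_permutations`` times (each
    permutation preserves the case/control totals exactly); the tree is
    refitted on each permuted phenotype and the maximum per-marker split
    count is recorded, giving a max-statistic null that controls the
    family-wise error rate. The empirical critical value is the ceiling of
    the (1 - alpha) quantile of that null; per-marker p-values are max-T
    adjusted with the add-one convention.
    """
    config = config or SignificanceConfig()
    if config.n_permutations < 1:
        raise ValidationError("need n_permutations >= 1")
    y = np.asarray(phenotype)
    Xm = markers.value_matrix()
    M = Xm.shape[1]
    blocks = [Xm]
    if covariates is not None:
        Z, _ = covariates.design_matrix()
        blocks.append(Z)
    X = np.column_stack(blocks)

    def marker_split_counts(yy: np.ndarray, tree_seed: int) -> np.ndarray:
        tree = fit_tree(X, yy, spec, seed=tree_seed)
        feats = tree.split_features
        out = np.zeros(M, dtype=int)
        np.add.at(out, feats[feats < M], 1)
        return out

    rng = np.random.default_rng(config.seed)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_permutations + 1) % (2**31)
    observed = marker_split_counts(y, int(seeds[0]))

    null_max = np.empty(config.n_permutations, dtype=int)
    exceed = np.zeros(M, dtype=int)
    for b in range(config.n_permutations):
        y_perm = rng.permutation(y)
        cnt = marker_split_counts(y_perm, int(seeds[b + 1]))
        null_max[b] = cnt.max() if M else 0
        exceed += null_max[b] >= observed
    crit = int(np.ceil(np.quantile(null_max, 1.0 - config.alpha)))
    pvals = (1.0 + exceed) / (config.n_permutations + 1.0)
    return PermutationResult(
        marker_ids=list(markers.marker_ids),
        observed_counts=observed,
        critical_value=max(crit, 1),
        pvalues=pvals,
        null_max_counts=null_max,
        alpha=config.alpha,
    )
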