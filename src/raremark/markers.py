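"""Composite-marker construction: per-group selection of carrier dummies.

For every variant group a 0/1 carrier dummy is coded per variant (1 iff the
subject carries at least one minor allele — dominant coding, which is what
"presence or absence" of a rare variant means). An L1-penalized logistic
model with unpenalized covariates is fitted on one designated construction
phenotype replicate; the AIC-best path point picks a subset of dummies, and
their fitted linear combination becomes the group's composite marker:

    v_j = sum_k beta_k d_jk .

Because individual dummies are rare but the combination pools carriers, the
marker is usually non-rare; it is kept only if its value is nonzero in at
least ``prevalence_min`` of the subjects (default 5%), which guarantees the
downstream tree analysis never sees a rare predictor.

``value_mode="union"`` replaces the weighted combination with the 0/1 union
of selected carriers, for sensitivity analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grouping import GroupAssignment
from .io import (
    MISSING,
    CompositeMarker,
    CovariateTable,
    GenotypeMatrix,
    MarkerSet,
    ValidationError,
    VariantTable,
)
from .lasso import LassoFit, PathSpec, fit_lasso_logistic, select_by_aic

logger = logging.getLogger(__name__)


def make_dummies(calls: np.ndarray) -> np.ndarray:
    """Carrier (dominant) coding: 1 iff call in {1, 2}; missing counts as 0."""
    calls = np.asarray(calls)
    return ((calls == 1) | (calls == 2)).astype(float)


def build_composite_markers(
    groups: list[GroupAssignment],
    genotypes: GenotypeMatrix,
    variants: VariantTable,
    covariates: CovariateTable | None,
    phenotype: np.ndarray,
    prevalence_min: float = 0.05,
    path_spec: PathSpec | None = None,
    value_mode: str = "weighted",
) -> tuple[MarkerSet, pd.DataFrame]:
    """Run the per-group selection and collect surviving markers.

    ``phenotype`` is the construction replicate's 0/1 vector. Returns the
    marker set plus a per-group diagnostics table (selected penalty, model
    size, log-likelihood, AIC, prevalence, keep decision).
    """
    if value_mode not in ("weighted", "union"):
        raise ValidationError(f"unknown value_mode {value_mode!r}")
    y = np.asarray(phenotype)
    if y.shape[0] != genotypes.n_subjects:
        raise ValidationError("phenotype length does not match subjects")
    col_of = {v: j for j, v in enumerate(variants.variant_ids)}
    Z = None
    if covariates is not None:
        Z, _ = covariates.design_matrix()

    markers: list[CompositeMarker] = []
    rows = []
    for grp in groups:
        try:
            cols = [col_of[v] for v in grp.variant_ids]
        except KeyError as e:
            raise ValidationError(f"group {grp.group_id}: unknown variant {e}")
        D_full = make_dummies(genotypes.calls[:, cols])
        varying = D_full.std(axis=0) > 0
        if not varying.any():
            logger.info("group %s: all dummies monomorphic; skipped", grp.group_id)
            rows.append((grp.group_id, np.nan, 0, np.nan, np.nan, 0, np.nan, False))
            continue
        D = D_full[:, varying]
        vids = [v for v, keep in zip(grp.variant_ids, varying) if keep]

        fit = fit_lasso_logistic(D, Z, y, path_spec)
        lam, _, w = select_by_aic(fit)
        sel = w != 0
        i = fit.selected
        if not sel.any():
            rows.append(
                (grp.group_id, lam, int(fit.n_nonzero[i]), fit.loglik[i],
                 fit.aic[i], 0, np.nan, False)
            )
            continue
        weights = w[sel]
        members = tuple(v for v, s in zip(vids, sel) if s)
        if value_mode == "weighted":
            values = D[:, sel] @ weights
        else:
            values = D[:, sel].any(axis=1).astype(float)
        prevalence = float(np.mean(values != 0))
        kept = prevalence >= prevalence_min
        rows.append(
            (grp.group_id, lam, int(fit.n_nonzero[i]), fit.loglik[i],
             fit.aic[i], int(sel.sum()), prevalence, kept)
        )
        if kept:
            markers.append(
                CompositeMarker(
                    marker_id=f"mk:{grp.group_id}",
                    group_id=grp.group_id,
                    variant_ids=members,
                    weights=weights,
                    values=values,
                )
            )

    diagnostics = pd.DataFrame(
        rows,
        columns=["group_id", "lambda", "k", "loglik", "aic",
                 "n_selected", "prevalence", "kept"],
    )
    logger.info(
        "marker construction: %d/%d groups yielded a non-rare marker",
        len(markers), len(groups),
    )
    return MarkerSet(genotypes.subject_ids, markers), diagnostics
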