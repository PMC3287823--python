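"""Variant QC: exclude common variants and Hardy-Weinberg failures.

Rare-variant collapsing operates on the rare tail of the MAF spectrum, so
the screen removes every variant with MAF above ``maf_max`` (default 0.05)
and every variant failing an exact Hardy-Weinberg test at ``hwe_alpha``
(default 1e-4). Boundary conventions are strict inequalities: MAF exactly
at the threshold is retained and an HWE p exactly at the threshold passes.

The HWE test is the exact conditional test: holding the subject total and
the minor-allele count fixed, the p-value sums the probabilities of every
heterozygote count whose conditional probability does not exceed that of
the observed count. The exact test is preferred over chi-square because
rare variants put most genotype classes at very low expected counts. It is
evaluated on the pooled sample; genotypes are fixed across phenotype
replicates, so QC is replicate-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, ValidationError, VariantTable, maf_from_calls

compute_maf = maf_from_calls


@dataclass
class QcThresholds:
    maf_max: float = 0.05
    hwe_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.maf_max <= 0.5):
            raise ValidationError("maf_max must be in (0, 0.5]")
        if not (0 < self.hwe_alpha < 1):
            raise ValidationError("hwe_alpha must be in (0, 1)")


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value from genotype counts.

    Conditions on the total number of subjects and minor alleles; the
    conditional probability of ``h`` heterozygotes is proportional to
    ``2**h / (n_aa! h! n_bb!)`` over heterozygote counts of the correct
    parity. Symmetric in the two homozygote classes; returns 1.0 for
    monomorphic variants.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValidationError("genotype counts must be nonnegative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValidationError("need at least one subject")
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    n_aa = (rare - hets) // 2
    n_bb = n - n_aa - hets
    logw = (
        hets * np.log(2.0)
        - gammaln(n_aa + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(n_bb + 1.0)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_het)[0][0]]
    # relative tolerance so equal-probability counts tie robustly in floats
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[col != MISSING]
    n2 = int((obs == 2).sum())
    n1 = int((obs == 1).sum())
    n0 = int((obs == 0).sum())
    return n0, n1, n2


def filter_variants(
    genotypes: GenotypeMatrix,
    variants: VariantTable,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, VariantTable, pd.DataFrame]:
    """Apply the MAF and HWE screens; returns filtered data plus a QC report.

    The report has one row per input variant with columns ``variant_id``,
    ``maf``, ``hwe_p``, ``kept`` and ``reason`` (empty when kept). An empty
    surviving set is a warning, not an error.
    """
    import logging

    log = logging.getLogger(__name__)
    thresholds = thresholds or QcThresholds()
    if genotypes.n_variants != len(variants):
        raise ValidationError("genotypes and variant table are misaligned")

    mafs = np.empty(genotypes.n_variants)
    hwe_p = np.empty(genotypes.n_variants)
    reasons = []
    for j in range(genotypes.n_variants):
        col = genotypes.calls[:, j]
        if (col == MISSING).all():
            mafs[j] = np.nan
            hwe_p[j] = np.nan
            reasons.append("all_missing")
            continue
        mafs[j] = maf_from_calls(col)[0]
        n0, n1, n2 = _genotype_counts(col)
        hwe_p[j] = hwe_exact_pvalue(n0, n1, n2)
        if mafs[j] > thresholds.maf_max:
            reasons.append("maf")
        elif hwe_p[j] < thresholds.hwe_alpha:
            reasons.append("hwe")
        else:
            reasons.append("")
    reasons = np.array(reasons, dtype=object)
    kept = reasons == ""
    report = pd.DataFrame(
        {
            "variant_id": variants.variant_ids,
            "maf": mafs,
            "hwe_p": hwe_p,
            "kept": kept,
            "reason": reasons,
        }
    )
    n_maf = int((reasons == "maf").sum())
    n_hwe = int((reasons == "hwe").sum())
    log.info(
        "QC: %d/%d variants kept (%d removed MAF>%g, %d removed HWE p<%g)",
        kept.sum(), len(kept), n_maf, thresholds.maf_max, n_hwe, thresholds.hwe_alpha,
    )
    if not kept.any():
        log.warning("QC removed every variant")
    idx = np.where(kept)[0]
    out_vt = variants.subset(idx)
    out_vt.df["maf"] = mafs[idx]
    return genotypes.subset_variants(idx), out_vt, report
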