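from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raremark as rm
from raremark.io import MISSING
from raremark.preprocess import compute_maf, hwe_exact_pvalue


def hwe_bruteforce(n0: int, n1: int, n2: int) -> float:
    """Exact-arithmetic enumeration of the conditional heterozygote
    distribution with fixed subject and allele totals."""
    n = n0 + n1 + n2
    rare = 2 * min(n0, n2) + n1
    if rare == 0:
        return 1.0
    denom = comb(2 * n, rare)
    probs = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        naa = (rare - h) // 2
        nbb = n - naa - h
        probs[h] = Fraction(comb(n, naa) * comb(n - naa, h) * 2**h, denom)
    assert sum(probs.values()) == 1
    obs = probs[n1]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.mark.parametrize(
    "calls, expected",
    [
        ([0, 0, 0, 0], 0.0),
        ([2, 2, 2, 2], 0.0),       # polarized: min(p, 1-p)
        ([0, 1, 0, 0, 2], 0.3),
    ],
)
def test_maf_direct_counts(calls, expected):
    assert compute_maf(np.array(calls))[0] == pytest.approx(expected)


def test_maf_all_missing_is_error():
    with pytest.raises(rm.ValidationError):
        compute_maf(np.full(4, MISSING))


def test_hwe_monomorphic_is_one():
    assert hwe_exact_pvalue(5, 0, 0) == 1.0
    assert hwe_exact_pvalue(0, 0, 5) == 1.0


def test_hwe_two_subjects_full_enumeration():
    # 2 subjects, 2 minor alleles: het counts {0, 2} with probs 1/3 and 2/3;
    # observing zero heterozygotes gives p = 1/3, while observing the modal
    # two-heterozygote outcome leaves no excluded outcome, so p = 1
    assert hwe_exact_pvalue(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)
    assert hwe_exact_pvalue(0, 2, 0) == pytest.approx(1.0, abs=1e-12)


def test_hwe_matches_bruteforce_small_totals():
    for n in range(1, 13):
        for n0 in range(n + 1):
            for n1 in range(n - n0 + 1):
                n2 = n - n0 - n1
                got = hwe_exact_pvalue(n0, n1, n2)
                want = hwe_bruteforce(n0, n1, n2)
                assert got == pytest.approx(want, abs=1e-12), (n0, n1, n2)


@given(
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hwe_symmetric_in_homozygotes(a, b, c):
    if a + b + c == 0:
        return
    assert hwe_exact_pvalue(a, b, c) == pytest.approx(
        hwe_exact_pvalue(c, b, a), abs=1e-12
    )


def test_hwe_exact_test_is_conservative_under_equilibrium():
    """Genotypes drawn at exact HWE proportions reject at most at the
    nominal level (exact conditional tests are conservative)."""
    rng = np.random.default_rng(17)
    n, reps, alpha = 120, 1500, 0.05
    geno = rng.binomial(2, 0.15, size=(reps, n))
    rejections = 0
    for row in geno:
        n2 = int((row == 2).sum()); n1 = int((row == 1).sum())
        if hwe_exact_pvalue(n - n1 - n2, n1, n2) < alpha:
            rejections += 1
    mc_err = 3 * np.sqrt(alpha * (1 - alpha) / reps)
    assert rejections / reps <= alpha + mc_err


def _table(mafs, hwe_cols):
    """Assemble a genotype matrix from explicit per-variant genotype counts."""
    cols = []
    for spec in hwe_cols:
        n0, n1, n2 = spec
        cols.append(np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2)]))
    calls = np.column_stack(cols).astype(np.int8)
    n_var = calls.shape[1]
    var = rm.VariantTable(pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n_var)],
        "chrom": "1", "pos": np.arange(1, n_var + 1), "gene": "",
        "maf": mafs,
    }))
    geno = rm.GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])], calls)
    return geno, var


def test_filter_boundary_conventions():
    """MAF strictly above 0.05 excluded; exactly 0.05 retained; HWE failures
    below the alpha threshold excluded."""
    # 100 subjects: maf 0.05 (10 het), maf 0.06 (12 het), HWE-failing (5 hom-minor, 0 het)
    geno, var = _table(
        [0.05, 0.06, 0.025],
        [(90, 10, 0), (88, 12, 0), (95, 0, 5)],
    )
    assert hwe_exact_pvalue(95, 0, 5) < 1e-4  # engineered HWE failure
    _, kept_var, report = rm.filter_variants(geno, var)
    assert list(report["kept"]) == [True, False, False]
    assert list(report["reason"]) == ["", "maf", "hwe"]
    assert list(kept_var.df["variant_id"]) == ["v0"]


def test_filter_monotone_in_maf_threshold(small_cohort):
    _, (geno, var, _, _, _) = small_cohort
    loose = rm.filter_variants(geno, var, rm.QcThresholds(maf_max=0.05))[1]
    tight = rm.filter_variants(geno, var, rm.QcThresholds(maf_max=0.02))[1]
    assert set(tight.df["variant_id"]) <= set(loose.df["variant_id"])


def test_filter_reports_counts_per_rule(small_cohort):
    _, (geno, var, _, _, _) = small_cohort
    _, var_f, report = rm.filter_variants(geno, var)
    assert len(report) == len(var)
    assert report["kept"].sum() == len(var_f)
    assert set(report.loc[~report["kept"], "reason"]) <= {"maf", "hwe", "all_missing"}
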