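import numpy as np
import pytest

import raremark as rm


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with a single causal gene, shared across tests."""
    cfg = rm.CohortConfig(
        n_subjects=300,
        n_populations=4,
        n_variants=400,
        n_genes=30,
        n_chromosomes=3,
        n_replicates=12,
        causal_genes={"G0010": 1.0},
        causal_maf_range=(0.01, 0.03),
        seed=7,
    )
    return cfg, rm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def qc_cohort(small_cohort):
    """The same cohort after QC filtering and grouping."""
    _, (geno, var, cov, phen, truth) = small_cohort
    geno_f, var_f, report = rm.filter_variants(geno, var)
    groups = rm.assign_groups(var_f)
    return geno_f, var_f, cov, phen, truth, groups, report


@pytest.fixture(scope="session")
def built_markers(qc_cohort):
    geno_f, var_f, cov, phen, truth, groups, _ = qc_cohort
    markers, diag = rm.build_composite_markers(
        groups, geno_f, var_f, cov, phen.values[:, 0]
    )
    return markers, diag


def random_marker_set(rng: np.random.Generator, n_subjects=8, n_markers=3):
    markers = []
    for m in range(n_markers):
        k = int(rng.integers(1, 4))
        w = rng.normal(size=k)
        w[0] = w[0] if w[0] != 0 else 1.0
        d = (rng.uniform(size=(n_subjects, k)) < 0.3).astype(float)
        markers.append(
            rm.CompositeMarker(
                marker_id=f"m{m}",
                group_id=f"g{m}",
                variant_ids=tuple(f"v{m}_{j}" for j in range(k)),
                weights=w,
                values=d @ w,
            )
        )
    return rm.MarkerSet([f"S{i}" for i in range(n_subjects)], markers)
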