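"""Synthetic cohort generator.

Emulates the structure of a multi-population, rare-variant-dominated
case/control resource: several hundred unrelated subjects drawn from a
handful of population groups, tens of thousands of SNPs with a strongly
rare-skewed MAF spectrum, four covariates (population, age, sex, smoking),
a small set of causal genes acting through rare-variant carriers, and R
phenotype replicates drawn on fixed genotypes.

The phenotype model is logistic on purpose — the downstream penalized
selection stage is logistic, so the generator and the method share a
liability scale:

    logit P(case_j) = b0 + a_pop(j) + b_age (age_j - 50) + b_sex sex_j
                      + b_smk smk_j + sum_g beta_g carrier_g(j)

where ``carrier_g(j)`` indicates that subject j carries at least one minor
allele at any variant of causal gene g. Genotypes are Binomial(2, MAF) per
variant with MAF drawn from a four-stratum spectrum; genes are contiguous
positional blocks; a configurable fraction of variants is intergenic.
Linkage disequilibrium is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    MISSING,
    CompositeMarker,
    CovariateTable,
    GenotypeMatrix,
    MarkerSet,
    PhenotypeReplicates,
    ValidationError,
    VariantTable,
)

# MAF strata: below 0.001, 0.001-0.01, 0.01-0.05, above 0.05. Default
# mixture weights follow the cumulative rare-variant percentages of the
# motivating cohort (38.5% < 0.001, 74.0% < 0.01, 87.2% < 0.05).
MAF_STRATA = ((1e-4, 1e-3), (1e-3, 1e-2), (1e-2, 5e-2), (5e-2, 0.5))
DEFAULT_SPECTRUM = (0.385, 0.355, 0.132, 0.128)


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the motivating data set's scale: 697 subjects in 17
    population groups, 24,487 variants, 200 phenotype replicates. Effect
    sizes are on the log-odds scale; ``causal_genes`` maps gene labels to
    per-carrier log-odds increments.
    """

    n_subjects: int = 697
    n_populations: int = 17
    n_variants: int = 24487
    n_genes: int = 3000
    n_chromosomes: int = 22
    maf_spectrum: tuple[float, float, float, float] = DEFAULT_SPECTRUM
    intergenic_rate: float = 0.2
    causal_genes: dict[str, float] = field(default_factory=dict)
    causal_maf_range: tuple[float, float] | None = None
    beta0: float = -1.2
    beta_age: float = 0.02
    beta_sex: float = 0.4
    beta_smoke: float = 0.4
    pop_intercept_sd: float = 0.3
    missing_rate: float = 0.0
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.maf_spectrum) - 1.0) > 1e-9:
            raise ValidationError("maf_spectrum weights must sum to 1")
        if self.n_replicates < 1:
            raise ValidationError("need n_replicates >= 1")
        if self.n_genes > self.n_variants:
            raise ValidationError("more genes than variants")


def gene_label(i: int) -> str:
    return f"G{i:04d}"


def _draw_mafs(n: int, spectrum: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """MAFs from the stratum mixture, log-uniform within each stratum."""
    strata = rng.choice(len(MAF_STRATA), size=n, p=np.asarray(spectrum))
    lo = np.array([MAF_STRATA[s][0] for s in strata])
    hi = np.array([MAF_STRATA[s][1] for s in strata])
    u = rng.uniform(size=n)
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def _layout_variants(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromosome, position and gene label per variant.

    Genes are contiguous blocks of variants; contiguous genes share a
    chromosome, so no gene and no positional neighborhood spans two
    chromosomes. A fraction of variants is relabeled intergenic.
    """
    gene_of_variant = (np.arange(cfg.n_variants) * cfg.n_genes) // cfg.n_variants
    chrom_of_gene = (np.arange(cfg.n_genes) * cfg.n_chromosomes) // cfg.n_genes
    chroms = chrom_of_gene[gene_of_variant] + 1
    genes = np.array([gene_label(g) for g in gene_of_variant], dtype=object)
    intergenic = rng.uniform(size=cfg.n_variants) < cfg.intergenic_rate
    genes[intergenic] = ""
    pos = np.empty(cfg.n_variants, dtype=int)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        gaps = rng.integers(100, 10_000, size=len(idx))
        pos[idx] = np.cumsum(gaps)
    return chroms.astype(str), pos, genes


def simulate_covariates(
    n_subjects: int, n_populations: int, rng: np.random.Generator
) -> CovariateTable:
    """Population labels (uneven sizes), age, sex and smoking status."""
    pop_w = rng.dirichlet(np.full(n_populations, 2.0))
    pop = rng.choice(n_populations, size=n_subjects, p=pop_w)
    age = np.clip(rng.normal(50, 12, size=n_subjects), 18, 90).round(1)
    sex = rng.integers(0, 2, size=n_subjects)
    smoke = (rng.uniform(size=n_subjects) < 0.25).astype(int)
    df = pd.DataFrame(
        {
            "population": [f"P{p:02d}" for p in pop],
            "age": age,
            "sex": sex,
            "smoking": smoke,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n_subjects)], name="subject_id"),
    )
    return CovariateTable(df)


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[GenotypeMatrix, VariantTable, CovariateTable, PhenotypeReplicates, dict]:
    """Draw one cohort; fully reproducible from ``cfg.seed``.

    Returns genotypes, the variant table, covariates, phenotype replicates
    and a ``truth`` dict listing causal genes, their member variant ids and
    the per-gene carrier prevalence realized in the sample.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, pos, genes = _layout_variants(cfg, rng)

    for g in cfg.causal_genes:
        if not (genes == g).any():
            raise ValidationError(
                f"causal gene {g!r} has no variants (check n_genes/intergenic_rate)"
            )

    mafs = _draw_mafs(cfg.n_variants, cfg.maf_spectrum, rng)
    if cfg.causal_maf_range is not None:
        lo, hi = cfg.causal_maf_range
        for g in cfg.causal_genes:
            idx = np.where(genes == g)[0]
            u = rng.uniform(size=len(idx))
            mafs[idx] = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))

    calls = rng.binomial(2, mafs[None, :], size=(cfg.n_subjects, cfg.n_variants))
    calls = calls.astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.uniform(size=calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    subject_ids = [f"S{i:04d}" for i in range(cfg.n_subjects)]
    covariates = simulate_covariates(cfg.n_subjects, cfg.n_populations, rng)

    pop_int = rng.normal(0.0, cfg.pop_intercept_sd, size=cfg.n_populations)
    pop_idx = np.array([int(p[1:]) for p in covariates.df["population"]])
    eta = (
        cfg.beta0
        + pop_int[pop_idx]
        + cfg.beta_age * (covariates.df["age"].to_numpy() - 50.0)
        + cfg.beta_sex * covariates.df["sex"].to_numpy()
        + cfg.beta_smoke * covariates.df["smoking"].to_numpy()
    )

    truth: dict = {"causal_genes": {}, "causal_variants": []}
    for g, beta in cfg.causal_genes.items():
        idx = np.where(genes == g)[0]
        carrier = (calls[:, idx] >= 1).any(axis=1).astype(float)
        eta = eta + beta * carrier
        vids = [f"V{j:06d}" for j in idx]
        truth["causal_genes"][g] = {
            "beta": beta,
            "variant_ids": vids,
            "carrier_prevalence": float(carrier.mean()),
        }
        truth["causal_variants"].extend(vids)

    p_case = expit(eta)
    pheno = rng.binomial(1, p_case[:, None], size=(cfg.n_subjects, cfg.n_replicates))
    # invariant: every replicate needs both classes; redraw degenerate columns
    for r in range(cfg.n_replicates):
        tries = 0
        while pheno[:, r].sum() in (0, cfg.n_subjects):
            pheno[:, r] = rng.binomial(1, p_case)
            tries += 1
            if tries > 100:
                raise ValidationError(
                    "could not draw a replicate with both cases and controls; "
                    "check beta0 / effect sizes"
                )

    genotypes = GenotypeMatrix(subject_ids, calls)
    variants = VariantTable(
        pd.DataFrame(
            {
                "variant_id": [f"V{j:06d}" for j in range(cfg.n_variants)],
                "chrom": chroms,
                "pos": pos,
                "gene": genes.astype(str),
                "maf": np.minimum(mafs, 1 - mafs),
            }
        )
    )
    phenotypes = PhenotypeReplicates(
        subject_ids, pheno.astype(np.int8), [f"rep{r}" for r in range(cfg.n_replicates)]
    )
    return genotypes, variants, covariates, phenotypes, truth


def simulate_null_markers(
    n_subjects: int,
    n_markers: int,
    rng: np.random.Generator | int,
    dummies_per_marker: tuple[int, int] = (2, 6),
    carrier_prob_range: tuple[float, float] = (0.01, 0.08),
) -> MarkerSet:
    """Exchangeable null composite markers, iid across markers.

    Each marker is a weighted sum of a few independent Bernoulli carrier
    dummies, mimicking the shape of a composite marker (sparse, non-rare)
    while being generated identically and independently of any phenotype —
    the exchangeability the binomial split-frequency null assumes.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    markers = []
    lo, hi = carrier_prob_range
    for m in range(n_markers):
        k = int(rng.integers(dummies_per_marker[0], dummies_per_marker[1] + 1))
        probs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))
        d = (rng.uniform(size=(n_subjects, k)) < probs).astype(float)
        w = rng.normal(0.8, 0.3, size=k) * rng.choice([-1.0, 1.0], size=k)
        markers.append(
            CompositeMarker(
                marker_id=f"nm{m:03d}",
                group_id=f"nullgrp{m:03d}",
                variant_ids=tuple(f"nm{m:03d}_v{j}" for j in range(k)),
                weights=w,
                values=d @ w,
            )
        )
    return MarkerSet(subject_ids, markers)


# ---------------------------------------------------------------------------
# file emission (formats core_io reads)
# ---------------------------------------------------------------------------


def write_cohort_files(
    outdir: str | Path,
    genotypes: GenotypeMatrix,
    variants: VariantTable,
    covariates: CovariateTable,
    phenotypes: PhenotypeReplicates,
) -> dict[str, Path]:
    """Write VCF + annotation TSV + covariate/phenotype CSVs under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "annotation": outdir / "annotation.tsv",
        "covariates": outdir / "covariates.csv",
        "phenotypes": outdir / "phenotypes.csv",
    }
    _write_vcf(genotypes, variants, paths["vcf"])
    variants.df[["variant_id", "chrom", "pos", "gene"]].to_csv(
        paths["annotation"], sep="\t", index=False
    )
    covariates.df.to_csv(paths["covariates"], index_label="subject_id")
    pd.DataFrame(
        phenotypes.values,
        index=pd.Index(phenotypes.subject_ids, name="subject_id"),
        columns=phenotypes.replicate_labels,
    ).to_csv(paths["phenotypes"])
    return paths


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(genotypes: GenotypeMatrix, variants: VariantTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        df = variants.df
        for j in range(len(df)):
            gts = "\t".join(_GT[int(c)] for c in genotypes.calls[:, j])
            fh.write(
                f"{df.chrom.iat[j]}\t{df.pos.iat[j]}\t{df.variant_id.iat[j]}"
                f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )
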