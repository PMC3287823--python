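"""Data model and readers/writers.

Core containers for the pipeline: a genotype matrix of minor-allele counts,
a per-variant annotation table, covariates, replicate case/control
phenotypes, and composite-marker sets. Readers accept VCF (via cyvcf2) or
PLINK-style ``.ped``/``.map`` text plus a variant-to-gene annotation TSV.

Conventions
-----------
* Genotype calls are minor-allele counts in {0, 1, 2}; missing is ``MISSING``
  (-1). Loaders polarize every site so the counted allele is the minor allele
  *in the loaded sample*.
* Positions are 1-based (VCF/bim convention).
* Marker sets are written as a versioned TSV with a JSON header line so the
  file is human-diffable and round-trips bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-genotype code used throughout.
MISSING = -1

MARKERSET_MAGIC = "#raremark_markerset"
MARKERSET_VERSION = 1


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending record."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x variants matrix of minor-allele counts.

    ``calls`` is an ``(N, P)`` integer array with entries in {0, 1, 2} or
    ``MISSING``. Row order matches ``subject_ids``.
    """

    subject_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D matrix")
        n = len(self.subject_ids)
        if n < 1:
            raise ValidationError("need at least one subject")
        if self.calls.shape[0] != n:
            raise ValidationError(
                f"calls has {self.calls.shape[0]} rows but {n} subject ids"
            )
        if len(set(self.subject_ids)) != n:
            raise ValidationError("subject_ids must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("genotype calls outside {0,1,2,missing}")

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.subject_ids, self.calls[:, idx])


VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "gene", "maf")


@dataclass
class VariantTable:
    """Per-variant annotation: id, chromosome, 1-based position, gene, MAF.

    Wraps a :class:`pandas.DataFrame` with columns ``variant_id``, ``chrom``,
    ``pos``, ``gene`` (empty string for intergenic) and ``maf``. Row order
    matches the genotype-matrix columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"variant table missing columns {missing}")
        df = self.df.loc[:, list(VARIANT_COLUMNS)].reset_index(drop=True)
        df["variant_id"] = df["variant_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["gene"] = df["gene"].fillna("").astype(str)
        df["pos"] = df["pos"].astype(int)
        df["maf"] = df["maf"].astype(float)
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValidationError(f"duplicate variant_id {dup!r}")
        if (df["pos"] < 1).any():
            raise ValidationError("positions must be >= 1 (1-based)")
        if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
            raise ValidationError("maf must lie in [0, 0.5] after polarization")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    def subset(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))


@dataclass
class CovariateTable:
    """Per-subject covariates: population (categorical), age, sex, smoking."""

    df: pd.DataFrame

    REQUIRED = ("population", "age", "sex", "smoking")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"covariate table missing columns {missing}")
        if self.df.index.duplicated().any():
            raise ValidationError("one row per subject_id required")
        df = self.df.copy()
        df["population"] = df["population"].astype(str)
        for col in ("sex", "smoking"):
            vals = set(df[col].unique())
            if not vals <= {0, 1}:
                raise ValidationError(f"{col} must be binary 0/1, got {vals}")
        self.df = df

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df.index.astype(str))

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Numeric design matrix (no intercept column).

        The categorical population is one-hot encoded with the largest
        population as the reference level; age, sex and smoking enter as-is.
        """
        pops = self.df["population"]
        ref = pops.value_counts().idxmax()
        levels = [p for p in sorted(pops.unique()) if p != ref]
        cols, names = [], []
        for lev in levels:
            cols.append((pops == lev).to_numpy(float))
            names.append(f"pop[{lev}]")
        for col in ("age", "sex", "smoking"):
            cols.append(self.df[col].to_numpy(float))
            names.append(col)
        return np.column_stack(cols), names

    def reorder(self, subject_ids: Sequence[str]) -> "CovariateTable":
        missing = [s for s in subject_ids if s not in self.df.index]
        if missing:
            raise ValidationError(f"covariates missing subjects {missing[:5]}")
        return CovariateTable(self.df.loc[list(subject_ids)])


@dataclass
class PhenotypeReplicates:
    """N x R matrix of case/control (1/0) indicators on fixed genotypes."""

    subject_ids: list[str]
    values: np.ndarray
    replicate_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValidationError("phenotype replicates must be 2-D")
        n, r = self.values.shape
        if r < 1:
            raise ValidationError("need at least one replicate")
        if n != len(self.subject_ids):
            raise ValidationError("row count does not match subject ids")
        if not self.replicate_labels:
            self.replicate_labels = [f"rep{i}" for i in range(r)]
        if len(self.replicate_labels) != r:
            raise ValidationError("replicate label count mismatch")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValidationError("phenotypes must be 0/1")
        counts = self.values.sum(axis=0)
        if (counts == 0).any() or (counts == n).any():
            j = int(np.where((counts == 0) | (counts == n))[0][0])
            raise ValidationError(
                f"replicate {self.replicate_labels[j]!r} lacks cases or controls"
            )

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


@dataclass
class CompositeMarker:
    """One composite marker: a weighted combination of carrier dummies.

    ``values[j] = sum_k weights[k] * d_jk`` where ``d_jk`` indicates that
    subject ``j`` carries at least one minor allele of member variant ``k``.
    """

    marker_id: str
    group_id: str
    variant_ids: tuple[str, ...]
    weights: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.variant_ids) != len(self.weights):
            raise ValidationError("weights must align with member variants")
        if len(self.weights) < 1 or not np.any(self.weights != 0):
            raise ValidationError("marker needs >= 1 member with nonzero weight")

    @property
    def prevalence(self) -> float:
        """Fraction of subjects with a nonzero marker value."""
        return float(np.mean(self.values != 0))


@dataclass
class MarkerSet:
    """An ordered collection of composite markers over one subject panel."""

    subject_ids: list[str]
    markers: list[CompositeMarker]

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValidationError("marker_ids must be unique")
        n = len(self.subject_ids)
        for m in self.markers:
            if len(m.values) != n:
                raise ValidationError(
                    f"marker {m.marker_id!r} has {len(m.values)} values, "
                    f"expected {n}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def value_matrix(self) -> np.ndarray:
        """N x M matrix of per-subject marker values."""
        if not self.markers:
            return np.empty((len(self.subject_ids), 0))
        return np.column_stack([m.values for m in self.markers])


# ---------------------------------------------------------------------------
# polarization / MAF helpers
# ---------------------------------------------------------------------------


def polarize(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns so the counted allele is the sample minor allele.

    Returns the polarized matrix and a boolean vector marking flipped
    columns. Idempotent: re-polarizing changes nothing. Ties (frequency
    exactly 0.5) are left as-is.
    """
    calls = np.asarray(calls, dtype=np.int8)
    obs = calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / np.where(n_alleles > 0, n_alleles, 1)
    flip = p > 0.5
    out = calls.copy()
    cols = np.where(flip)[0]
    for j in cols:
        m = obs[:, j]
        out[m, j] = 2 - out[m, j]
    return out, flip


def maf_from_calls(calls: np.ndarray) -> np.ndarray:
    """Per-variant minor allele frequency, min(p, 1-p) over non-missing calls.

    Raises :class:`ValidationError` for an all-missing variant.
    """
    calls = np.asarray(calls)
    if calls.ndim == 1:
        calls = calls[:, None]
    obs = calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    if (n_alleles == 0).any():
        j = int(np.where(n_alleles == 0)[0][0])
        raise ValidationError(f"variant column {j} has no observed genotypes")
    p = np.where(obs, calls, 0).sum(axis=0) / n_alleles
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# genotype loading
# ---------------------------------------------------------------------------


def _read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "gene"}
    if not required <= set(ann.columns):
        raise ParseError(
            f"annotation {path} must have columns variant_id and gene, "
            f"got {list(ann.columns)}"
        )
    ann["gene"] = ann["gene"].fillna("")
    if ann["variant_id"].duplicated().any():
        raise ParseError(f"annotation {path} has duplicate variant_id entries")
    return ann.set_index("variant_id")


def _gene_lookup(ann: pd.DataFrame, variant_ids: Sequence[str]) -> list[str]:
    genes = []
    n_missing = 0
    for vid in variant_ids:
        if vid in ann.index:
            genes.append(str(ann.loc[vid, "gene"]))
        else:
            genes.append("")
            n_missing += 1
    if n_missing:
        logger.warning(
            "%d variants absent from the annotation; gene set to empty",
            n_missing,
        )
    return genes


def _load_vcf(path: Path) -> tuple[list[str], np.ndarray, list[str], list[str], list[int]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, vids, chroms, poss = [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = {0: 0, 1: 1, 3: 2, 2: MISSING}
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            logger.warning(
                "skipping non-biallelic site %s:%d", var.CHROM, var.POS
            )
            continue
        gt = var.gt_types
        rows.append([remap[int(g)] for g in gt])
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        vids.append(vid)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    if not rows:
        raise ParseError(f"no biallelic SNP records in {path}")
    calls = np.asarray(rows, dtype=np.int8).T  # sites-major -> subjects-major
    return subjects, calls, vids, chroms, poss


def _load_ped_map(ped_path: Path) -> tuple[list[str], np.ndarray, list[str], list[str], list[int]]:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise ParseError(f"companion map file {map_path} not found")
    vids, chroms, poss = [], [], []
    for lineno, line in enumerate(map_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{map_path}:{lineno}: expected 4 fields")
        chroms.append(parts[0])
        vids.append(parts[1])
        poss.append(int(parts[3]))
    n_var = len(vids)
    subjects, rows = [], []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_var:
            raise ParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_var} fields, "
                f"got {len(parts)}"
            )
        subjects.append(parts[1])
        alleles = parts[6:]
        row = np.empty(n_var, dtype=np.int8)
        for j in range(n_var):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                row[j] = MISSING
            else:
                # allele "2" is the counted (alt/minor candidate) allele
                row[j] = (a == "2") + (b == "2")
        rows.append(row)
    if not rows:
        raise ParseError(f"{ped_path} contains no subjects")
    return subjects, np.vstack(rows), vids, chroms, poss


def load_genotypes(
    path: str | Path, annotation: str | Path
) -> tuple[GenotypeMatrix, VariantTable]:
    """Load genotypes from VCF or PLINK ``.ped``/``.map`` text.

    The annotation TSV (``variant_id``, ``gene``, optionally ``chrom``/``pos``)
    supplies gene labels; variants absent from it get an empty gene with a
    logged warning. Calls are polarized to minor-allele counts and MAF is
    computed from the loaded sample.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf" or path.name.endswith(".vcf.gz"):
        subjects, calls, vids, chroms, poss = _load_vcf(path)
    elif path.suffix.lower() == ".ped":
        subjects, calls, vids, chroms, poss = _load_ped_map(path)
    else:
        raise ParseError(f"unrecognized genotype format: {path}")
    calls, flipped = polarize(calls)
    if flipped.any():
        logger.info("polarized %d variants to minor-allele counts", flipped.sum())
    miss_rate = np.mean(calls == MISSING, axis=0)
    for j in np.where(miss_rate > 0.05)[0]:
        logger.warning(
            "variant %s missingness %.1f%% (>5%%)", vids[j], 100 * miss_rate[j]
        )
    ann = _read_annotation(annotation)
    genes = _gene_lookup(ann, vids)
    maf = maf_from_calls(calls)
    variants = VariantTable(
        pd.DataFrame(
            {
                "variant_id": vids,
                "chrom": chroms,
                "pos": poss,
                "gene": genes,
                "maf": maf,
            }
        )
    )
    return GenotypeMatrix(subjects, calls), variants


# ---------------------------------------------------------------------------
# phenotype / covariate loading
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def load_phenotypes(
    path: str | Path, subject_ids: Sequence[str] | None = None
) -> PhenotypeReplicates:
    """Load replicate phenotypes: ``subject_id`` column plus one 0/1 column
    per replicate. If ``subject_ids`` is given, rows are aligned to it and a
    mismatch is an error listing the offending ids."""
    df = _read_table(path)
    if "subject_id" not in df.columns:
        raise ParseError(f"{path}: expected a subject_id column")
    df = df.set_index(df["subject_id"].astype(str)).drop(columns="subject_id")
    if subject_ids is not None:
        missing = sorted(set(subject_ids) - set(df.index))
        extra = sorted(set(df.index) - set(subject_ids))
        if missing or extra:
            raise ValidationError(
                f"subject mismatch: missing={missing[:5]} extra={extra[:5]}"
            )
        df = df.loc[list(subject_ids)]
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = vals[~np.isin(vals, (0, 1))][0]
        raise ValidationError(f"non-binary phenotype value {bad!r}")
    return PhenotypeReplicates(
        list(df.index), vals.astype(np.int8), [str(c) for c in df.columns]
    )


def load_covariates(
    path: str | Path, subject_ids: Sequence[str] | None = None
) -> CovariateTable:
    df = _read_table(path)
    if "subject_id" not in df.columns:
        raise ParseError(f"{path}: expected a subject_id column")
    df = df.set_index(df["subject_id"].astype(str)).drop(columns="subject_id")
    table = CovariateTable(df)
    if subject_ids is not None:
        table = table.reorder(list(subject_ids))
    return table


# ---------------------------------------------------------------------------
# marker-set round trip
# ---------------------------------------------------------------------------


def write_marker_set(markers: MarkerSet, path: str | Path) -> None:
    """Write a marker set as a versioned TSV with a JSON header line.

    The header carries marker definitions (members and weights, full float
    precision); the body is one row per subject with per-marker values.
    ``read_marker_set(write_marker_set(m))`` is the identity, bit-exactly.
    """
    header = {
        "version": MARKERSET_VERSION,
        "markers": [
            {
                "marker_id": m.marker_id,
                "group_id": m.group_id,
                "variant_ids": list(m.variant_ids),
                "weights": [float(w) for w in m.weights],
            }
            for m in markers.markers
        ],
    }
    lines = [f"{MARKERSET_MAGIC}\t{json.dumps(header)}"]
    cols = ["subject_id"] + markers.marker_ids
    lines.append("\t".join(cols))
    vals = markers.value_matrix()
    for i, sid in enumerate(markers.subject_ids):
        row = [sid] + [repr(float(v)) for v in vals[i]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_marker_set(path: str | Path) -> MarkerSet:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith(MARKERSET_MAGIC + "\t"):
        raise ParseError(f"{path}: not a marker-set file")
    header = json.loads(text[0].split("\t", 1)[1])
    if header.get("version") != MARKERSET_VERSION:
        raise ParseError(
            f"{path}: unknown marker-set schema version {header.get('version')!r}"
        )
    defs = header["markers"]
    ids = [d["marker_id"] for d in defs]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate marker_id in header")
    body = text[1:]
    colnames = body[0].split("\t")
    if colnames[0] != "subject_id" or colnames[1:] != ids:
        raise ParseError(f"{path}: body columns do not match header markers")
    subject_ids, rows = [], []
    for line in body[1:]:
        if not line:
            continue
        parts = line.split("\t")
        subject_ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    vals = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(ids)))
    )
    markers = [
        CompositeMarker(
            marker_id=d["marker_id"],
            group_id=d["group_id"],
            variant_ids=tuple(d["variant_ids"]),
            weights=np.asarray(d["weights"], dtype=float),
            values=vals[:, k],
        )
        for k, d in enumerate(defs)
    ]
    return MarkerSet(subject_ids, markers)
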