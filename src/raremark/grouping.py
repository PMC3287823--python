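"""Partition QC-passing rare variants into collapsing groups.

Genes holding at least ``min_gene_size`` variants become gene groups —
collapsing within a functional unit. Everything left over (variants in
small genes plus intergenic variants) is pooled per chromosome, sorted by
position, and chunked into consecutive positional bins of ``bin_size``
variants; an undersized trailing bin (below half of ``bin_size``) is merged
into its left neighbor. The result is an exhaustive, disjoint partition of
the surviving variants, invariant to input row order.

Bins are sized by variant count rather than by base-pair windows so every
group presents a comparable number of candidate predictors to the
selection stage regardless of local variant density.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ValidationError, VariantTable


@dataclass
class GroupAssignment:
    group_id: str
    kind: str  # "gene" | "positional"
    chrom: str
    variant_ids: list[str]


def assign_groups(
    variants: VariantTable,
    min_gene_size: int = 5,
    bin_size: int = 20,
) -> list[GroupAssignment]:
    """Build the gene/positional partition of the variant table."""
    if min_gene_size < 1:
        raise ValidationError("min_gene_size must be >= 1")
    if bin_size < 2:
        raise ValidationError("bin_size must be >= 2")
    df = variants.df
    if (df["chrom"].str.strip() == "").any():
        bad = df.loc[df["chrom"].str.strip() == "", "variant_id"].iloc[0]
        raise ValidationError(f"variant {bad!r} has no chromosome")

    # canonical order: chromosome, position, id — makes output independent
    # of input row order
    df = df.sort_values(["chrom", "pos", "variant_id"], kind="mergesort")

    groups: list[GroupAssignment] = []
    leftovers = []
    for gene, sub in df[df["gene"] != ""].groupby("gene", sort=True):
        if len(sub) >= min_gene_size:
            chroms = sub["chrom"].unique()
            if len(chroms) > 1:
                raise ValidationError(
                    f"gene {gene!r} spans chromosomes {list(chroms)}"
                )
            groups.append(
                GroupAssignment(
                    group_id=f"gene:{gene}",
                    kind="gene",
                    chrom=str(chroms[0]),
                    variant_ids=list(sub["variant_id"]),
                )
            )
        else:
            leftovers.append(sub)
    leftovers.append(df[df["gene"] == ""])
    left = pd.concat(leftovers) if leftovers else df.iloc[:0]
    left = left.sort_values(["chrom", "pos", "variant_id"], kind="mergesort")

    for chrom, sub in left.groupby("chrom", sort=True):
        vids = list(sub["variant_id"])
        chunks = [vids[i : i + bin_size] for i in range(0, len(vids), bin_size)]
        if len(chunks) >= 2 and len(chunks[-1]) < bin_size / 2:
            tail = chunks.pop()
            chunks[-1] = chunks[-1] + tail
        for k, chunk in enumerate(chunks):
            groups.append(
                GroupAssignment(
                    group_id=f"pos:{chrom}:bin{k:03d}",
                    kind="positional",
                    chrom=str(chrom),
                    variant_ids=chunk,
                )
            )
    return groups


def groups_to_frame(groups: list[GroupAssignment]) -> pd.DataFrame:
    """Long-format table (group_id, kind, chrom, variant_id) for export."""
    rows = [
        (g.group_id, g.kind, g.chrom, v)
        for g in groups
        for v in g.variant_ids
    ]
    return pd.DataFrame(rows, columns=["group_id", "kind", "chrom", "variant_id"])
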