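"""Mitochondrial annotation of regulated sites.

Annotation tables are gene-keyed, MitoCarta-style: one row per gene with a
mitochondrial flag and a submitochondrial compartment (MOM, MIM, Matrix,
IMS, Membrane, unknown).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

SUBCOMPARTMENTS = ("MOM", "MIM", "Matrix", "IMS", "Membrane", "unknown")
NON_MITO = "non-mito"


def _normalize_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.copy()
    ann["gene"] = ann["gene"].str.upper()
    dup = ann[ann.duplicated("gene", keep=False)]
    if not dup.empty:
        conflicting = []
        for gene, grp in dup.groupby("gene"):
            if grp[["mitochondrial", "subcompartment"]].drop_duplicates().shape[0] > 1:
                conflicting.append(gene)
        if conflicting:
            raise ValueError(f"conflicting annotation rows for gene(s): {sorted(conflicting)}")
        ann = ann.drop_duplicates("gene")
    return ann.set_index("gene")


def annotate_sites(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_column: str = "gene",
    synonyms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join results to a mitochondrial annotation table by gene symbol.

    The join is case-insensitive; genes absent from the table are labeled
    non-mitochondrial.  ``synonyms`` optionally maps alternate symbols to
    canonical ones before the join (empty by default).  Re-annotating an
    already annotated frame is a no-op on the annotation columns.
    """
    ann = _normalize_annotation(annotation)
    out = results.copy()
    genes = out[gene_column].str.upper()
    if synonyms:
        syn = {k.upper(): v.upper() for k, v in synonyms.items()}
        genes = genes.map(lambda g: syn.get(g, g))
    mito = genes.isin(ann.index) & genes.map(
        lambda g: bool(ann["mitochondrial"].get(g, False))
    )
    sub = genes.map(
        lambda g: ann["subcompartment"].get(g, NON_MITO) if g in ann.index else NON_MITO
    )
    out["mitochondrial"] = mito
    out["subcompartment"] = sub.where(mito, NON_MITO)
    return out


def compartment_distribution(
    annotated: pd.DataFrame, direction: str | None = None
) -> pd.DataFrame:
    """Counts and fractions of sites per submitochondrial compartment.

    ``direction`` filters to ``"up"`` or ``"down"`` regulated sites first.
    Fractions are reported both over all input sites (mito + non-mito sums
    to 1) and over mitochondrial sites only.
    """
    df = annotated
    if direction is not None:
        df = df[df["direction"] == direction]
    if df.empty:
        raise ValueError("no sites left after filtering")
    counts = df["subcompartment"].value_counts()
    order = [c for c in (*SUBCOMPARTMENTS, NON_MITO) if c in counts.index]
    counts = counts.reindex(order)
    n = len(df)
    n_mito = int(df["mitochondrial"].sum())
    out = pd.DataFrame(
        {
            "subcompartment": counts.index,
            "count": counts.to_numpy(),
            "fraction_all": counts.to_numpy() / n,
        }
    )
    out["fraction_mito"] = [
        (c / n_mito if s != NON_MITO and n_mito else float("nan"))
        for s, c in zip(out["subcompartment"], out["count"])
    ]
    return out.reset_index(drop=True)
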