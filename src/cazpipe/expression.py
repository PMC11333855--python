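"""Relative-expression summaries of CAZymes, sulfatases and CGC members.

Transcript counts are aggregated per gut section and taxon class into
within-category fractions (no length normalization: the deliverable is the
relative share of each class within a category, which is insensitive to a
common per-gene scale).  Highly expressed clusters are selected as those
comprising the upper quantile of total substrate-assigned CGC expression
in any sample of a section.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cgc import GeneCluster
from .io import MagMeta, SampleMeta

CATEGORIES = ("CAZyme", "sulfatase", "CGC-CAZyme")


def relative_expression_by_class(
    expr: pd.DataFrame,
    calls: pd.DataFrame,
    sulfatase_calls: pd.DataFrame,
    clusters: list[GeneCluster],
    metas: list[MagMeta],
    samples: list[SampleMeta],
) -> pd.DataFrame:
    """Per-section, per-category class fractions of transcript counts.

    ``expr`` is long-format (gene_id, sample_id, count); gene ids double as
    protein ids.  Categories: CAZyme (all consensus calls), sulfatase, and
    CGC-CAZyme (CAZyme members of clusters — a subset of CAZyme).  Within
    each (section, category), class fractions sum to 1; a category with
    zero counts in a section is emitted as missing (NaN).
    """
    mag_class = {m.mag_id: m.class_label for m in metas}
    gene_mag: dict[str, str] = {}
    for row in calls.itertuples(index=False):
        gene_mag[row.protein_id] = row.mag_id
    for row in sulfatase_calls.itertuples(index=False):
        gene_mag[row.protein_id] = row.mag_id

    caz_genes = set(calls["protein_id"]) if len(calls) else set()
    sulf_genes = set(sulfatase_calls["protein_id"]) if len(sulfatase_calls) else set()
    cgc_genes = {
        m.gene_id for c in clusters for m in c.members if m.role == "CAZyme"
    } & caz_genes

    category_genes = {
        "CAZyme": caz_genes,
        "sulfatase": sulf_genes,
        "CGC-CAZyme": cgc_genes,
    }
    sample_section = {
        s.sample_id: s.section for s in samples if s.assay == "metatranscriptome"
    }
    expr = expr[expr["sample_id"].isin(sample_section)]
    sections = sorted(set(sample_section.values()))
    classes = sorted(set(mag_class.values()))

    rows = []
    for section in sections:
        sect_samples = {s for s, sec in sample_section.items() if sec == section}
        sect = expr[expr["sample_id"].isin(sect_samples)]
        for category, genes in category_genes.items():
            cat = sect[sect["gene_id"].isin(genes)]
            totals = {cls: 0.0 for cls in classes}
            for row in cat.itertuples(index=False):
                mag = gene_mag.get(row.gene_id)
                cls = mag_class.get(mag)
                if cls is not None:
                    totals[cls] += row.count
            grand = sum(totals.values())
            for cls in classes:
                rows.append(
                    {
                        "section": section,
                        "category": category,
                        "class": cls,
                        "count": totals[cls],
                        "fraction": totals[cls] / grand if grand > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["section", "category", "class", "count", "fraction"])


def top_cgc_by_expression(
    expr: pd.DataFrame,
    clusters: list[GeneCluster],
    samples: list[SampleMeta],
    section: str,
    quantile: float = 0.25,
) -> list[GeneCluster]:
    """Select substrate-assigned clusters in the upper expression quantile.

    Per sample of the section, cluster expression is the sum of member-gene
    counts, and its share is taken over all substrate-assigned clusters.
    The minimal prefix of clusters (sorted by descending share) whose
    cumulative share reaches ``quantile`` of the total is selected; a
    cluster is returned if selected in *any* sample of the section.  The
    returned clusters carry their maximal per-sample ``expression_share``.
    """
    assigned = [c for c in clusters if c.substrates]
    if not assigned:
        return []
    sample_ids = [
        s.sample_id
        for s in samples
        if s.section == section and s.assay == "metatranscriptome"
    ]
    if not sample_ids:
        return []
    gene_cluster: dict[str, str] = {}
    for c in assigned:
        for m in c.members:
            gene_cluster[m.gene_id] = c.cgc_id

    sub = expr[expr["sample_id"].isin(sample_ids)].copy()
    sub = sub[sub["gene_id"].isin(gene_cluster)]
    selected: dict[str, float] = {}
    for sid in sample_ids:
        s = sub[sub["sample_id"] == sid]
        totals: dict[str, float] = {c.cgc_id: 0.0 for c in assigned}
        for row in s.itertuples(index=False):
            totals[gene_cluster[row.gene_id]] += row.count
        grand = sum(totals.values())
        if grand <= 0:
            continue
        order = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        cum = 0.0
        for cid, cnt in order:
            if cnt <= 0:
                break
            share = cnt / grand
            if cid not in selected or share > selected[cid]:
                selected[cid] = share
            cum += share
            if cum >= quantile - 1e-12:
                break
    out = []
    for c in assigned:
        if c.cgc_id in selected:
            c.expression_share = selected[c.cgc_id]
            out.append(c)
    return out
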