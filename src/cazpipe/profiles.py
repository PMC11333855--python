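"""Per-MAG and per-class CAZyme statistics.

Density is CAZyme genes per 1000 predicted genes by default (per Mbp via
config), compared between taxonomic classes with a Wilcoxon rank-sum test.
Community composition is summarized as a Bray-Curtis dissimilarity matrix
over per-MAG family density vectors.  Genus relative abundances are
compared across gut sections with Kruskal-Wallis tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .catalog import SubstrateCatalog, collapse_subfamily, family_mechanism, DEGRADATIVE_MECHANISMS
from .config import PipelineConfig
from .io import MagMeta, SampleMeta


@dataclass
class MagProfile:
    mag_id: str
    class_label: str
    genus_label: str
    n_genes: int
    n_cazymes: int
    density: float
    family_counts: dict[str, int]


def cazyme_density(
    meta: MagMeta,
    calls: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> MagProfile:
    """Build one MAG's CAZyme profile from its consensus calls.

    ``calls`` must be restricted to this MAG (columns protein_id, family).
    """
    config = config or PipelineConfig()
    if meta.n_genes <= 0:
        raise ValueError(f"MAG {meta.mag_id}: n_genes must be > 0")
    fam_counts: dict[str, int] = {}
    for row in calls.itertuples(index=False):
        fam = collapse_subfamily(row.family)
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
    n_caz = sum(fam_counts.values())
    if config.density_unit == "per_1000_genes":
        density = 1000.0 * n_caz / meta.n_genes
    else:
        if meta.genome_size <= 0:
            raise ValueError(f"MAG {meta.mag_id}: genome_size must be > 0 for per-Mbp density")
        density = n_caz / (meta.genome_size / 1e6)
    return MagProfile(
        mag_id=meta.mag_id,
        class_label=meta.class_label,
        genus_label=meta.genus_label,
        n_genes=meta.n_genes,
        n_cazymes=n_caz,
        density=density,
        family_counts=fam_counts,
    )


def build_profiles(
    metas: list[MagMeta],
    calls: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> list[MagProfile]:
    by_mag = dict(tuple(calls.groupby("mag_id"))) if len(calls) else {}
    empty = calls.iloc[0:0]
    return [cazyme_density(m, by_mag.get(m.mag_id, empty), config) for m in metas]


def profiles_to_frame(profiles: list[MagProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mag_id": p.mag_id,
                "class": p.class_label,
                "genus": p.genus_label,
                "n_genes": p.n_genes,
                "n_cazymes": p.n_cazymes,
                "density": p.density,
            }
            for p in profiles
        ]
    )


def compare_density_classes(
    profiles: list[MagProfile], class_a: str, class_b: str
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of CAZyme density between two classes.

    Returns (rank-sum statistic W = sum of class-A ranks, two-sided p).
    Uses the exact null distribution at small untied sample sizes and the
    tie-corrected normal approximation otherwise.
    """
    a = [p.density for p in profiles if p.class_label == class_a]
    b = [p.density for p in profiles if p.class_label == class_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 MAGs for the rank-sum test")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    w = res.statistic + len(a) * (len(a) + 1) / 2.0  # U -> rank-sum of sample A
    return float(w), float(res.pvalue)


def bray_curtis_matrix(
    profiles: list[MagProfile], feature: str = "density"
) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity over per-MAG family vectors.

    ``feature``: "density" scales each family count by 1000/n_genes (a
    density composition); "counts" uses raw counts.  Pairs in which both
    vectors are all-zero are undefined and reported as NaN.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    fams = sorted({f for p in profiles for f in p.family_counts})
    mat = np.zeros((len(profiles), len(fams)))
    for i, p in enumerate(profiles):
        for j, f in enumerate(fams):
            c = p.family_counts.get(f, 0)
            mat[i, j] = 1000.0 * c / p.n_genes if feature == "density" else c
    ids = [p.mag_id for p in profiles]
    if mat.shape[1] == 0:
        d = np.full((len(ids), len(ids)), np.nan)
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=ids, columns=ids)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(mat, metric="braycurtis"))
    # pdist leaves 0/0 pairs as nan already; make the contract explicit
    zero = mat.sum(axis=1) == 0
    for i in np.where(zero)[0]:
        for j in np.where(zero)[0]:
            if i != j:
                d[i, j] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def genus_section_summary(
    abundance: pd.DataFrame,
    samples: list[SampleMeta],
    metas: list[MagMeta],
    level: str = "genus",
) -> pd.DataFrame:
    """Per-taxon per-section mean/SD relative abundance + Kruskal-Wallis p.

    ``abundance`` is samples x MAGs in percent.  Taxon abundance per sample
    is the sum over member MAGs.  The Kruskal-Wallis test (tie-corrected,
    chi-square approximation) compares a taxon's per-sample abundances
    across sections; a raw p is reported alongside a Benjamini-Hochberg
    adjusted column.  Sections with < 2 samples are excluded from the test.
    """
    from .io import RANKS

    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    rank_i = RANKS.index(level)
    sample_section = {s.sample_id: s.section for s in samples}
    mag_taxon = {m.mag_id: m.taxonomy[rank_i] for m in metas}

    taxa = sorted(set(mag_taxon.values()))
    sections = sorted({sample_section[s] for s in abundance.index})
    rows = []
    pvals: list[float | None] = []
    for taxon in taxa:
        mags = [m for m in abundance.columns if mag_taxon.get(m) == taxon]
        taxon_ab = abundance[mags].sum(axis=1)
        groups = {
            sec: taxon_ab[[s for s in abundance.index if sample_section[s] == sec]]
            for sec in sections
        }
        testable = [g.values for g in groups.values() if len(g) >= 2]
        if len(testable) >= 2:
            if np.ptp(np.concatenate(testable)) == 0:
                h, p = 0.0, 1.0  # identical values in every section
            else:
                h, p = stats.kruskal(*testable)
        else:
            h, p = np.nan, None
        pvals.append(p)
        for sec in sections:
            g = groups[sec]
            rows.append(
                {
                    "taxon": taxon,
                    "level": level,
                    "section": sec,
                    "mean_pct": float(g.mean()) if len(g) else np.nan,
                    "sd_pct": float(g.std(ddof=1)) if len(g) > 1 else np.nan,
                    "n_samples": len(g),
                    "kw_h": float(h) if h == h else np.nan,
                    "kw_p": p if p is not None else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    # BH adjustment across taxa (transparency column; raw p is primary)
    taxon_p = pd.Series(
        {t: p for t, p in zip(taxa, pvals) if p is not None}, dtype=float
    )
    if len(taxon_p):
        order = taxon_p.sort_values()
        m = len(order)
        adj = (order * m / np.arange(1, m + 1)).iloc[::-1].cummin().iloc[::-1].clip(upper=1.0)
        df["kw_p_bh"] = df["taxon"].map(adj).astype(float)
    else:
        df["kw_p_bh"] = np.nan
    return df


def pool_enzyme_counts(
    calls: pd.DataFrame,
    groups: dict[str, list[str]],
    metas: list[MagMeta],
    catalog: SubstrateCatalog,
) -> pd.DataFrame:
    """Pooled per-group, per-class, per-enzyme-label gene counts.

    Each accepted call contributes once, under its family's enzyme label;
    MAGs outside every group are pooled under "ungrouped".  Output also
    carries per-enzyme MAG counts and the HMW/LMW flag.
    """
    mag_group: dict[str, str] = {}
    for gid, members in groups.items():
        for m in members:
            mag_group[m] = gid
    mag_class = {m.mag_id: m.class_label for m in metas}

    acc: dict[tuple[str, str, str], dict] = {}
    for row in calls.itertuples(index=False):
        rule = catalog.classify_family(row.family)
        label = rule.enzyme_label or collapse_subfamily(row.family)
        gid = mag_group.get(row.mag_id, "ungrouped")
        cls = mag_class.get(row.mag_id, "unclassified")
        key = (gid, cls, label)
        slot = acc.setdefault(
            key,
            {
                "group": gid,
                "class": cls,
                "enzyme_label": label,
                "weight_class": rule.weight_class,
                "substrates": ",".join(sorted(rule.substrates)) or "-",
                "gene_count": 0,
                "mags": set(),
            },
        )
        slot["gene_count"] += 1
        slot["mags"].add(row.mag_id)

    rows = []
    for key in sorted(acc):
        slot = acc[key]
        slot["mag_count"] = len(slot.pop("mags"))
        rows.append(slot)
    cols = ["group", "class", "enzyme_label", "weight_class", "substrates",
            "gene_count", "mag_count"]
    return pd.DataFrame(rows, columns=cols)
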