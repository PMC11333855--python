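"""MAG co-abundance analysis.

Pairwise Pearson correlation of relative abundances across samples (the
data are compositional — closed to 100% — and correlations are computed on
the closed values, with no log-ratio transform, matching common practice in
gut-community co-abundance heatmaps).  Co-abundant groups are delineated by
average-linkage clustering on 1 - r restricted to significant positive
pairs, and labelled A*/B* by their section IV -> V abundance trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import SampleMeta


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclass
class CoabundGroup:
    group_id: str
    members: list[str]
    mean_within_r: float
    section_trend: str = "stable"  # IV-enriched | V-enriched | stable


@dataclass(frozen=True)
class FoldChange:
    mag_id: str
    mean_iv: float
    mean_v: float
    log10_fc: float


def correlate(abundance: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r and two-sided p over MAG abundance columns.

    Requires >= 3 samples.  Constant-abundance MAGs are excluded with a
    warning (r undefined).  |r| = 1 pairs get p = 0.
    """
    n = len(abundance)
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n}")
    constant = [c for c in abundance.columns if abundance[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"excluding {len(constant)} constant-abundance MAG(s): {constant[:5]}",
            stacklevel=2,
        )
        abundance = abundance.drop(columns=constant)
    cols = list(abundance.columns)
    x = abundance.values.astype(float)
    if x.shape[1] == 1:
        r = np.ones((1, 1))
    else:
        r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p via t = r * sqrt((n-2)/(1-r^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=n,
    )


def section_fold_change(
    abundance: pd.DataFrame,
    samples: list[SampleMeta],
    epsilon: float = 0.01,
) -> list[FoldChange]:
    """log10 fold change of mean abundance from section IV to V per MAG.

    Means are taken over samples of each section; ``epsilon`` (percentage
    points) guards against zero means.  MAGs absent from all samples of
    both sections are omitted.
    """
    sec = {s.sample_id: s.section for s in samples}
    iv = [s for s in abundance.index if sec.get(s) == "IV"]
    v = [s for s in abundance.index if sec.get(s) == "V"]
    if not iv or not v:
        raise ValueError("both sections IV and V must be present")
    out = []
    for mag in abundance.columns:
        m_iv = float(abundance.loc[iv, mag].mean())
        m_v = float(abundance.loc[v, mag].mean())
        if m_iv == 0.0 and m_v == 0.0:
            continue
        out.append(
            FoldChange(
                mag_id=mag,
                mean_iv=m_iv,
                mean_v=m_v,
                log10_fc=float(np.log10((m_v + epsilon) / (m_iv + epsilon))),
            )
        )
    return out


def delineate_groups(
    corr: CorrelationMatrix,
    alpha: float = 0.05,
    min_r: float = 0.3,
    min_size: int = 2,
    cut_height: float = 0.7,
    abundance: pd.DataFrame | None = None,
    samples: list[SampleMeta] | None = None,
) -> list[CoabundGroup]:
    """Delineate co-abundant MAG groups from the correlation matrix.

    Edges are significant positive pairs (p <= alpha, r >= min_r).  MAGs
    are clustered by average linkage on 1 - r and the tree cut at
    ``cut_height``; within each cut cluster, groups are the connected
    components of the edge graph with >= ``min_size`` members.  Output
    order is deterministic: by descending summed abundance when an
    abundance table is given, else by descending size then member ids.
    Groups are labelled A1.. / B1.. by section trend (A = IV-enriched).
    """
    mags = list(corr.r.columns)
    rm, pm = corr.r.values, corr.p.values
    edges = (pm <= alpha) & (rm >= min_r)
    np.fill_diagonal(edges, False)

    if len(mags) >= 3:
        dist = squareform(np.clip(1.0 - rm, 0.0, 2.0), checks=False)
        labels = fcluster(linkage(dist, method="average"), t=cut_height, criterion="distance")
    else:
        labels = np.ones(len(mags), dtype=int)

    # connected components of the edge graph within each cut cluster
    raw_groups: list[list[int]] = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        unseen = set(idx)
        while unseen:
            stack = [min(unseen)]
            unseen.discard(stack[0])
            comp = []
            while stack:
                i = stack.pop()
                comp.append(i)
                for j in idx:
                    if j in unseen and edges[i, j]:
                        unseen.discard(j)
                        stack.append(j)
            if len(comp) >= min_size:
                raw_groups.append(sorted(comp))

    fc_by_mag: dict[str, float] = {}
    if abundance is not None and samples is not None:
        for fc in section_fold_change(abundance, samples):
            fc_by_mag[fc.mag_id] = fc.log10_fc

    def sort_key(comp: list[int]):
        if abundance is not None:
            total = -float(abundance[[mags[i] for i in comp]].sum().sum())
        else:
            total = -len(comp)
        return (total, [mags[i] for i in comp])

    raw_groups.sort(key=sort_key)

    groups: list[CoabundGroup] = []
    counters = {"A": 0, "B": 0, "G": 0}
    for comp in raw_groups:
        members = [mags[i] for i in comp]
        sub_r = rm[np.ix_(comp, comp)]
        mean_r = float(sub_r[np.triu_indices(len(comp), k=1)].mean())
        if fc_by_mag:
            mean_fc = float(np.mean([fc_by_mag.get(m, 0.0) for m in members]))
            if mean_fc < -0.1:
                trend, letter = "IV-enriched", "A"
            elif mean_fc > 0.1:
                trend, letter = "V-enriched", "B"
            else:
                trend, letter = "stable", "B"
        else:
            trend, letter = "stable", "G"
        counters[letter] += 1
        groups.append(
            CoabundGroup(
                group_id=f"{letter}{counters[letter]}",
                members=members,
                mean_within_r=mean_r,
                section_trend=trend,
            )
        )
    return groups


def groups_to_frame(groups: list[CoabundGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "members": ",".join(g.members),
                "n_members": len(g.members),
                "mean_within_r": g.mean_within_r,
                "section_trend": g.section_trend,
            }
            for g in groups
        ],
        columns=["group_id", "members", "n_members", "mean_within_r", "section_trend"],
    )


def correlation_to_frame(corr: CorrelationMatrix) -> pd.DataFrame:
    """Long-format (mag_a, mag_b, r, p, n) upper-triangle listing."""
    mags = list(corr.r.columns)
    rows = []
    for i, a in enumerate(mags):
        for b in mags[i + 1:]:
            rows.append(
                {
                    "mag_a": a,
                    "mag_b": b,
                    "r": corr.r.loc[a, b],
                    "p": corr.p.loc[a, b],
                    "n": corr.n,
                }
            )
    return pd.DataFrame(rows, columns=["mag_a", "mag_b", "r", "p", "n"])


def group_capability_panel(
    groups: list[CoabundGroup],
    calls: pd.DataFrame,
    catalog,
) -> pd.DataFrame:
    """Per-group x substrate x weight-class gene counts and MAG fractions.

    Summarizes each co-abundant group's capacity for the HMW and LMW forms
    of each substrate from its members' accepted calls.
    """
    rows = []
    for g in groups:
        member_set = set(g.members)
        sub = calls[calls["mag_id"].isin(member_set)] if len(calls) else calls
        acc: dict[tuple[str, str], dict] = {}
        for row in sub.itertuples(index=False):
            rule = catalog.classify_family(row.family)
            if rule.weight_class not in ("HMW", "LMW"):
                continue
            for s in rule.substrates:
                if s == "sulfate_removal":
                    continue
                slot = acc.setdefault((s, rule.weight_class), {"genes": 0, "mags": set()})
                slot["genes"] += 1
                slot["mags"].add(row.mag_id)
        for (s, wc) in sorted(acc):
            slot = acc[(s, wc)]
            rows.append(
                {
                    "group_id": g.group_id,
                    "substrate": s,
                    "weight_class": wc,
                    "gene_count": slot["genes"],
                    "mag_fraction": len(slot["mags"]) / len(g.members),
                }
            )
    return pd.DataFrame(
        rows, columns=["group_id", "substrate", "weight_class", "gene_count", "mag_fraction"]
    )
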