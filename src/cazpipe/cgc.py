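"""CAZyme gene cluster (CGC) detection and substrate inference.

A CGC is a maximal run of signature genes (CAZyme, transporter TC,
transcription factor TF, signal-transduction protein STP) on one contig in
which consecutive signature genes are separated by at most ``cgc_max_gap``
non-signature genes, containing at least one CAZyme and at least one
non-CAZyme signature gene.  Degradative clusters carry >=2 degradative
CAZymes (GH/PL/CE; binding modules and transferases do not count).
Substrates are inferred from dedicated families and from colocalization of
ambiguous families with complementary activities on the same substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import (
    DEGRADATIVE_MECHANISMS,
    SubstrateCatalog,
    collapse_subfamily,
    family_mechanism,
)
from .config import PipelineConfig
from .io import GeneRecord, MagMeta

SIGNATURE_ROLES = frozenset({"CAZyme", "TC", "TF", "STP"})
ROLES = frozenset({"CAZyme", "TC", "TF", "STP", "other"})


@dataclass
class ClusterMember:
    gene_id: str
    role: str  # CAZyme | TC | TF | STP | other
    family: str | None = None  # consensus family for CAZyme members


@dataclass
class GeneCluster:
    """One detected CAZyme gene cluster (members ordered by start)."""

    cgc_id: str
    mag_id: str
    contig_id: str
    members: list[ClusterMember]
    degradative: bool = False
    n_degradative: int = 0
    substrates: dict[str, str] = field(default_factory=dict)  # substrate -> evidence
    expression_share: float | None = None

    @property
    def cazyme_families(self) -> list[str]:
        return [m.family for m in self.members if m.role == "CAZyme" and m.family]

    def validate(self, max_gap_roles: list[str] | None = None) -> None:
        roles = {m.role for m in self.members}
        if "CAZyme" not in roles:
            raise AssertionError(f"{self.cgc_id}: no CAZyme member")
        if not (roles & (SIGNATURE_ROLES - {"CAZyme"})):
            raise AssertionError(f"{self.cgc_id}: no non-CAZyme signature member")


def detect_cgcs(
    genes: list[GeneRecord],
    roles: dict[str, str],
    config: PipelineConfig | None = None,
) -> list[GeneCluster]:
    """Detect CGCs on (possibly multi-contig, multi-MAG) sorted gene lists.

    ``roles`` maps gene_id -> role; genes must be sorted by start within
    each contig.  Clusters never span contigs and are maximal under the
    gap rule.  The cluster span runs from its first to its last signature
    gene; intervening non-signature genes are included as members.
    """
    config = config or PipelineConfig()
    max_gap = config.cgc_max_gap

    by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault((g.mag_id, g.contig_id), []).append(g)

    clusters: list[GeneCluster] = []
    for (mag_id, contig_id), contig_genes in sorted(by_contig.items()):
        starts = [g.start for g in contig_genes]
        if starts != sorted(starts):
            raise ValueError(f"genes on {mag_id}/{contig_id} are not sorted by start")
        sig_idx = [
            i for i, g in enumerate(contig_genes)
            if roles.get(g.gene_id, "other") in SIGNATURE_ROLES
        ]
        # chain signature genes: consecutive ones <= max_gap apart
        chains: list[list[int]] = []
        for i in sig_idx:
            if chains and i - chains[-1][-1] - 1 <= max_gap:
                chains[-1].append(i)
            else:
                chains.append([i])
        for chain in chains:
            chain_roles = {roles.get(contig_genes[i].gene_id, "other") for i in chain}
            if "CAZyme" not in chain_roles:
                continue
            if not (chain_roles & (SIGNATURE_ROLES - {"CAZyme"})):
                continue
            lo, hi = chain[0], chain[-1]
            members = [
                ClusterMember(
                    gene_id=contig_genes[i].gene_id,
                    role=roles.get(contig_genes[i].gene_id, "other"),
                )
                for i in range(lo, hi + 1)
            ]
            clusters.append(
                GeneCluster(
                    cgc_id=f"CGC_{mag_id}_{contig_id}_{contig_genes[lo].start}",
                    mag_id=mag_id,
                    contig_id=contig_id,
                    members=members,
                )
            )
    return clusters


def flag_degradative(
    cluster: GeneCluster,
    families: dict[str, str],
    config: PipelineConfig | None = None,
) -> GeneCluster:
    """Attach consensus families and the degradative flag.

    ``families`` maps gene_id -> consensus family.  A member counts as
    degradative iff its family mechanism is GH, PL or CE.
    """
    config = config or PipelineConfig()
    n = 0
    for m in cluster.members:
        if m.role == "CAZyme":
            m.family = families.get(m.gene_id, m.family)
            fam = m.family
            if fam and family_mechanism(collapse_subfamily(fam)) in DEGRADATIVE_MECHANISMS:
                n += 1
    cluster.n_degradative = n
    cluster.degradative = n >= config.cgc_min_degradative
    return cluster


def infer_substrates(
    cluster: GeneCluster, catalog: SubstrateCatalog
) -> dict[str, str]:
    """Infer cluster substrates from dedicated families and colocalization.

    Dedicated families contribute their substrate directly.  An ambiguous
    family's candidate substrate is kept only when a *different* member
    family supports the same substrate (complementary colocalization).
    Clusters with no resolvable substrate return an empty mapping and are
    tallied as unclassified.
    """
    fams = sorted(set(collapse_subfamily(f) for f in cluster.cazyme_families))
    rules = [catalog.classify_family(f) for f in fams]

    evidence: dict[str, str] = {}
    for rule in rules:
        if rule.dedicated:
            (sub,) = tuple(rule.substrates)
            if sub != "sulfate_removal":
                evidence[sub] = "dedicated"

    # colocalization: substrate supported by >=2 distinct member families
    support: dict[str, set[str]] = {}
    for rule in rules:
        for sub in rule.substrates:
            if sub == "sulfate_removal":
                continue
            support.setdefault(sub, set()).add(rule.key)
    for rule in rules:
        if rule.dedicated or not rule.mapped:
            continue
        for sub in rule.substrates:
            if sub in evidence or sub == "sulfate_removal":
                continue
            if len(support.get(sub, ())) >= 2:
                evidence[sub] = "colocalization"

    cluster.substrates = evidence
    return evidence


def analyze_clusters(
    genes: list[GeneRecord],
    roles: dict[str, str],
    families: dict[str, str],
    catalog: SubstrateCatalog,
    config: PipelineConfig | None = None,
) -> list[GeneCluster]:
    """detect -> flag_degradative -> infer_substrates, validated."""
    config = config or PipelineConfig()
    clusters = detect_cgcs(genes, roles, config)
    for c in clusters:
        flag_degradative(c, families, config)
        if c.degradative:
            infer_substrates(c, catalog)
        c.validate()
    return clusters


def summarize_cgcs_by_taxon(
    clusters: list[GeneCluster],
    metas: list[MagMeta],
    level: str = "class",
) -> pd.DataFrame:
    """Per-taxon CGC totals, degradative and substrate-assigned totals.

    Mean/SD of substrate-assigned CGCs per MAG are computed over *all* MAGs
    of the taxon, including zero-CGC MAGs (population SD, ddof=1 when n>1).
    """
    from .io import RANKS

    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {list(RANKS)}")
    rank_i = RANKS.index(level)
    mag_taxon = {m.mag_id: m.taxonomy[rank_i] for m in metas}

    per_mag_total: dict[str, int] = {m.mag_id: 0 for m in metas}
    per_mag_degr: dict[str, int] = {m.mag_id: 0 for m in metas}
    per_mag_sub: dict[str, int] = {m.mag_id: 0 for m in metas}
    for c in clusters:
        if c.mag_id not in per_mag_total:
            raise KeyError(f"cluster {c.cgc_id} references unknown MAG {c.mag_id!r}")
        per_mag_total[c.mag_id] += 1
        if c.degradative:
            per_mag_degr[c.mag_id] += 1
            if c.substrates:
                per_mag_sub[c.mag_id] += 1

    rows = []
    for taxon in sorted(set(mag_taxon.values())):
        mags = [m for m, t in mag_taxon.items() if t == taxon]
        sub_counts = pd.Series([per_mag_sub[m] for m in mags], dtype=float)
        rows.append(
            {
                "taxon": taxon,
                "level": level,
                "n_mags": len(mags),
                "total_cgcs": sum(per_mag_total[m] for m in mags),
                "degradative_cgcs": sum(per_mag_degr[m] for m in mags),
                "substrate_assigned_cgcs": int(sub_counts.sum()),
                "mean_substrate_cgcs_per_mag": float(sub_counts.mean()),
                "sd_substrate_cgcs_per_mag": float(sub_counts.std(ddof=1))
                if len(mags) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    """Flatten clusters for the on-disk CGC TSV."""
    rows = []
    for c in sorted(clusters, key=lambda c: c.cgc_id):
        rows.append(
            {
                "cgc_id": c.cgc_id,
                "mag_id": c.mag_id,
                "contig_id": c.contig_id,
                "genes": ";".join(
                    f"{m.gene_id}|{m.role}|{m.family or '-'}" for m in c.members
                ),
                "n_degradative": c.n_degradative,
                "degradative": int(c.degradative),
                "substrates": ",".join(sorted(c.substrates)) or "-",
                "evidence": ",".join(
                    f"{s}:{e}" for s, e in sorted(c.substrates.items())
                )
                or "-",
            }
        )
    cols = ["cgc_id", "mag_id", "contig_id", "genes", "n_degradative",
            "degradative", "substrates", "evidence"]
    return pd.DataFrame(rows, columns=cols)
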