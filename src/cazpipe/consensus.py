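"""Consensus CAZyme annotation from multi-stream evidence.

A per-protein CAZyme call is accepted only when at least two independent
evidence streams (profile HMM, k-mer classifier, similarity search) agree
on the same family after collapsing subfamilies; the reported family is
taken from the highest-priority agreeing stream (HMMER, then eCAMI, then
DIAMOND).  EC-linked calls and sulfatase calls additionally pass coverage /
identity (and, for sulfatases, Pfam-domain) filters.  MAGs are retained by
MIMAG-style completeness/contamination thresholds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .catalog import collapse_subfamily, family_mechanism
from .config import PipelineConfig
from .io import AnnotationHit, MagMeta

SOURCE_PRIORITY = ("HMMER", "eCAMI", "DIAMOND")


@dataclass(frozen=True)
class CazymeCall:
    """Accepted consensus CAZyme call for one protein."""

    protein_id: str
    family: str
    mechanism: str
    ec: str | None
    supporting_sources: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.supporting_sources) < 2:
            raise ValueError(f"call for {self.protein_id}: needs >=2 supporting sources")
        if family_mechanism(self.family) != self.mechanism:
            raise ValueError(
                f"call for {self.protein_id}: mechanism {self.mechanism} does not "
                f"match family {self.family}"
            )


@dataclass(frozen=True)
class SulfataseCall:
    protein_id: str
    s1_family: str
    coverage: float
    identity: float


def filter_evalue(hits: list[AnnotationHit], config: PipelineConfig) -> list[AnnotationHit]:
    """Drop hits above the e-value cutoff (applied before any other rule)."""
    return [h for h in hits if h.evalue <= config.evalue_cutoff]


def merge_calls(hits: list[AnnotationHit]) -> CazymeCall | None:
    """Merge one protein's evidence into a consensus call, or nothing.

    Keeps the best-e-value hit per source, collapses subfamily labels,
    and accepts iff >=2 sources share a family.  When a source reports
    several families, any intersection counts as agreement.  The family
    reported comes from the highest-priority agreeing source.
    """
    if not hits:
        return None
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"merge_calls got hits for multiple proteins: {sorted(proteins)}")
    protein_id = hits[0].protein_id

    best: dict[str, AnnotationHit] = {}
    for h in hits:
        if h.source not in best or h.evalue < best[h.source].evalue:
            best[h.source] = h

    # family -> supporting sources, after subfamily collapse
    votes: dict[str, set[str]] = defaultdict(set)
    for source, h in best.items():
        for label in h.labels:
            votes[collapse_subfamily(label)].add(source)

    agreed = {fam: srcs for fam, srcs in votes.items() if len(srcs) >= 2}
    if not agreed:
        return None

    # choose family by priority of its best supporting source, then by the
    # supporting hit's e-value, then lexicographically (deterministic)
    def rank(fam: str) -> tuple:
        srcs = agreed[fam]
        prio = min(SOURCE_PRIORITY.index(s) for s in srcs)
        top = SOURCE_PRIORITY[prio]
        return (prio, best[top].evalue, fam)

    family = min(agreed, key=rank)
    mech = family_mechanism(family)
    if mech is None:
        return None  # non-CAZy label (e.g. a sulfatase subfamily) cannot form a CAZyme call
    sources = frozenset(agreed[family])
    ec = next(
        (best[s].ec for s in SOURCE_PRIORITY if s in sources and best[s].ec),
        None,
    )
    return CazymeCall(
        protein_id=protein_id,
        family=family,
        mechanism=mech,
        ec=ec,
        supporting_sources=sources,
    )


def accept_ec(hit: AnnotationHit, config: PipelineConfig) -> bool:
    """EC-linked CAZyme acceptance: coverage >= 40% and identity >= 30%."""
    if hit.ec is None:
        raise ValueError(f"hit for {hit.protein_id} carries no EC number")
    return hit.coverage >= config.ec_min_coverage and hit.identity >= config.ec_min_identity


def accept_sulfatase(hit: AnnotationHit, config: PipelineConfig) -> SulfataseCall | None:
    """Sulfatase acceptance: coverage >= 50%, identity >= 30%, PF00884 domain."""
    ok = (
        hit.coverage >= config.sulf_min_coverage
        and hit.identity >= config.sulf_min_identity
        and config.required_sulf_domain in hit.domains
    )
    if not ok:
        return None
    s1 = next(iter(hit.labels)) if len(hit.labels) == 1 else sorted(hit.labels)[0]
    return SulfataseCall(
        protein_id=hit.protein_id, s1_family=s1,
        coverage=hit.coverage, identity=hit.identity,
    )


def filter_mags(
    metas: list[MagMeta],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[MagMeta]:
    """Retain MAGs with completeness >= min and contamination < max.

    The contamination bound is strict ("less than"), the completeness bound
    inclusive, following MIMAG phrasing.
    """
    return [
        m
        for m in metas
        if m.completeness >= min_completeness and m.contamination < max_contamination
    ]


def annotate_proteins(
    hits: list[AnnotationHit],
    protein_to_mag: dict[str, str],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full per-protein acceptance stage over a hit table.

    Returns (cazyme_calls, sulfatase_calls) DataFrames.  CAZyme calls come
    from the >=2-stream consensus; an EC is attached only when its DIAMOND
    evidence passes the EC coverage/identity filter.  Sulfatase calls come
    from DIAMOND S1-subfamily hits passing the sulfatase filter.
    """
    hits = filter_evalue(hits, config)
    by_protein: dict[str, list[AnnotationHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)

    caz_rows, sulf_rows = [], []
    for pid in sorted(by_protein):
        phits = by_protein[pid]
        mag = protein_to_mag.get(pid)
        if mag is None:
            raise KeyError(f"hit references unknown protein {pid!r}")
        caz_hits = [h for h in phits if not any(l.startswith("S1_") for l in h.labels)]
        sulf_hits = [h for h in phits if any(l.startswith("S1_") for l in h.labels)]

        call = merge_calls(caz_hits)
        if call is not None:
            ec = call.ec
            if ec is not None:
                # EC evidence must itself pass the EC filter
                ec_ok = any(
                    h.ec == ec and accept_ec(h, config)
                    for h in caz_hits
                    if h.ec is not None
                )
                if not ec_ok:
                    ec = None
            caz_rows.append(
                {
                    "protein_id": pid,
                    "mag_id": mag,
                    "family": call.family,
                    "mechanism": call.mechanism,
                    "ec": ec or "-",
                    "sources": ",".join(sorted(call.supporting_sources)),
                }
            )
        for h in sulf_hits:
            sc = accept_sulfatase(h, config)
            if sc is not None:
                sulf_rows.append(
                    {
                        "protein_id": pid,
                        "mag_id": mag,
                        "s1_family": sc.s1_family,
                        "coverage": sc.coverage,
                        "identity": sc.identity,
                    }
                )
    caz_cols = ["protein_id", "mag_id", "family", "mechanism", "ec", "sources"]
    sulf_cols = ["protein_id", "mag_id", "s1_family", "coverage", "identity"]
    return (
        pd.DataFrame(caz_rows, columns=caz_cols),
        pd.DataFrame(sulf_rows, columns=sulf_cols),
    )
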