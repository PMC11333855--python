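"""Synthetic multi-MAG communities with planted ground truth.

Generates the full input bundle the pipeline consumes — gene tables,
three-stream annotation evidence, sulfatase similarity hits with domain
annotations, MAG metadata, closed relative-abundance tables with blocked
co-abundance structure across two hindgut sections, and transcript counts
— together with the planted truth (per-protein families, per-MAG
capability matrix, CGC memberships and substrates, co-abundance blocks).

Class substrate guilds default to the structure seen in seaweed-eating
herbivore hindguts: Bacteroidia with broad brown- plus red-algae capacity
(incl. sulfatases), Clostridia brown-algae-biased, Bacilli and
Gammaproteobacteria narrow, a sulfur-cycling class with none.  Everything
is deterministic per seed; all randomness in the package lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import PANELS, SubstrateCatalog, load_catalog
from .io import (
    AnnotationHit,
    GeneRecord,
    MagMeta,
    SampleMeta,
    write_abundance_table,
    write_annotation_hits,
    write_expression_table,
    write_gene_table,
    write_mag_metadata,
    write_sample_metadata,
)

DEFAULT_CLASS_SPLIT = {
    "Bacteroidia": 31,
    "Clostridia": 23,
    "Bacilli": 5,
    "Gammaproteobacteria": 4,
    "Verrucomicrobiae": 2,
    "Cyanobacteriia": 1,
    "Spirochaetia": 1,
    "Desulfobacteria": 1,
}

DEFAULT_CLASS_GUILDS = {
    "Bacteroidia": frozenset(
        {"alginate", "laminarin", "FCSP", "carrageenan", "agarose",
         "galactan", "starch", "sulfate_removal", "mannitol"}
    ),
    "Clostridia": frozenset(
        {"alginate", "laminarin", "FCSP", "galactan", "starch", "mannitol"}
    ),
    "Bacilli": frozenset({"alginate", "starch", "mannitol"}),
    "Gammaproteobacteria": frozenset({"alginate", "laminarin", "galactan", "starch"}),
    "Verrucomicrobiae": frozenset({"FCSP", "sulfate_removal", "mannitol"}),
    "Cyanobacteriia": frozenset({"starch"}),
    "Spirochaetia": frozenset({"galactan", "starch"}),
    "Desulfobacteria": frozenset(),
}

#: CAZyme genes per 1000 genes, by class (drives the density contrasts).
DEFAULT_CLASS_DENSITY = {
    "Bacteroidia": 60.0,
    "Clostridia": 35.0,
    "Bacilli": 20.0,
    "Gammaproteobacteria": 30.0,
    "Verrucomicrobiae": 15.0,
    "Cyanobacteriia": 8.0,
    "Spirochaetia": 10.0,
    "Desulfobacteria": 0.0,
}

#: Mean community relative abundance (%) per class before per-MAG variation.
DEFAULT_CLASS_ABUNDANCE = {
    "Bacteroidia": 50.0,
    "Clostridia": 30.0,
    "Bacilli": 8.0,
    "Gammaproteobacteria": 5.0,
    "Verrucomicrobiae": 3.0,
    "Cyanobacteriia": 1.5,
    "Spirochaetia": 1.5,
    "Desulfobacteria": 1.0,
}

#: Class-level expression multipliers per section (hindgut chamber V is
#: Bacteroidia/Clostridia-dominated).
DEFAULT_EXPR_MULT = {
    "IV": {"Bacteroidia": 1.5, "Clostridia": 2.0, "Bacilli": 1.0},
    "V": {"Bacteroidia": 3.0, "Clostridia": 2.0},
    "III": {"Bacilli": 2.0, "Clostridia": 1.0},
}
_EXPR_MULT_DEFAULT = 0.5

CLASS_TAXONOMY = {
    "Bacteroidia": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
                    "Rikenellaceae", "Alistipes"),
    "Clostridia": ("Bacteria", "Bacillota_A", "Clostridia", "Oscillospirales",
                   "Oscillospiraceae", "unclassified"),
    "Bacilli": ("Bacteria", "Bacillota", "Bacilli", "Erysipelotrichales",
                "Erysipelotrichaceae", "unclassified"),
    "Gammaproteobacteria": ("Bacteria", "Pseudomonadota", "Gammaproteobacteria",
                            "Enterobacterales", "Vibrionaceae", "Vibrio"),
    "Verrucomicrobiae": ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae",
                         "Verrucomicrobiales", "Akkermansiaceae", "Akkermansia"),
    "Cyanobacteriia": ("Bacteria", "Cyanobacteriota", "Cyanobacteriia",
                       "Chroococcales", "unclassified", "unclassified"),
    "Spirochaetia": ("Bacteria", "Spirochaetota", "Spirochaetia",
                     "Spirochaetales", "unclassified", "unclassified"),
    "Desulfobacteria": ("Bacteria", "Desulfobacterota", "Desulfobacteria",
                        "Desulfobacterales", "unclassified", "unclassified"),
}

MANNITOL_GENES_BY_CLASS = {
    "Bacteroidia": ("m2dh", "fructokinase"),
    "Verrucomicrobiae": ("m2dh", "fructokinase"),
    "Clostridia": ("m2dh", "fructokinase", "pts_mannitol", "m1pdh"),
    "Bacilli": ("pts_mannitol", "m1pdh"),
    "Gammaproteobacteria": ("pts_mannitol", "m1pdh"),
}

S1_BY_CLASS = {
    "Bacteroidia": ("S1_7", "S1_8", "S1_15", "S1_16", "S1_17", "S1_19", "S1_25"),
    "Verrucomicrobiae": ("S1_7", "S1_15", "S1_17", "S1_19"),
}

_FILLER_FAMILIES = ("CBM4", "CBM6", "CBM32", "CBM48", "GT2", "GT4",
                    "CE1", "CE6", "CE10", "AA3")

_GENES_PER_CONTIG = 100
_FEATURE_BUFFER = 4  # 'other' genes between features; > cgc_max_gap + 1


@dataclass
class Block:
    """Co-abundance block: members share a latent lognormal factor."""

    members: list[str]
    sd: float = 0.8
    section_boost: dict[str, float] = field(default_factory=dict)


@dataclass
class CommunityPlan:
    n_mags_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPLIT)
    )
    class_guilds: dict[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_GUILDS)
    )
    class_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DENSITY)
    )
    class_abundance: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ABUNDANCE)
    )
    genes_per_mag: int = 400
    n_fish: int = 4
    sections: tuple[str, ...] = ("IV", "V")
    cgc_rate: float = 2.0
    annotator_agreement: float = 1.0
    label_noise: float = 0.0
    completeness_range: tuple[float, float] = (75.0, 99.5)
    contamination_range: tuple[float, float] = (0.0, 6.4)
    coabund_blocks: list[Block] | None = None  # None -> default six-block layout
    residual_sd: float = 0.15
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("annotator_agreement", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.genes_per_mag < 50:
            raise ValueError("genes_per_mag must be >= 50")
        if self.cgc_rate * 10 > self.genes_per_mag:
            raise ValueError("infeasible plan: cgc_rate too high for genes_per_mag")

    @property
    def mag_ids(self) -> list[str]:
        return list(self.mag_class)

    @property
    def mag_class(self) -> dict[str, str]:
        out = {}
        i = 0
        for cls, n in self.n_mags_per_class.items():
            for _ in range(n):
                i += 1
                out[f"FM_{i:02d}"] = cls
        return out


@dataclass
class GroundTruth:
    protein_family: dict[str, str]   # planted CAZy family per CAZyme gene
    protein_s1: dict[str, str]       # planted S1 subfamily per sulfatase gene
    capability: pd.DataFrame         # MAG x panel boolean matrix
    cgcs: list[dict]                 # planted clusters: mag_id, gene_ids, substrate
    blocks: dict[str, list[str]]     # block label -> member MAGs
    mag_class: dict[str, str]
    pooled_counts: pd.DataFrame | None = None  # filled by tests/acceptance as needed


# ---------------------------------------------------------------------------
# feature composition

def _dedicated_families(catalog: SubstrateCatalog, substrate: str) -> list[str]:
    return sorted(
        r.key
        for r in catalog.rules
        if r.key_type == "family" and r.dedicated and r.substrates == {substrate}
    )


def _families_for(catalog: SubstrateCatalog, substrate: str, guild: frozenset) -> list[str]:
    """Families acting on ``substrate`` whose full substrate set fits the guild."""
    return sorted(
        r.key
        for r in catalog.rules
        if r.key_type == "family"
        and substrate in r.substrates
        and r.substrates <= guild
    )


def plant_cgc(
    substrate: str,
    catalog: SubstrateCatalog,
    guild: frozenset,
    rng: np.random.Generator,
) -> list[tuple[str, str | None, str | None]]:
    """Compose a CGC gene run: (role, family, product) member tuples.

    Contains >=2 degradative CAZymes from families dedicated to the
    substrate (so substrate inference recovers exactly the planted
    substrate), at least one transporter, optionally a regulator and an
    intervening non-signature gene (gap <= 2 preserved).
    """
    dedicated = _dedicated_families(catalog, substrate)
    if len(dedicated) < 2:
        raise ValueError(f"substrate {substrate!r} lacks two dedicated families")
    k = min(len(dedicated), int(rng.integers(2, 4)))
    fams = [str(f) for f in rng.choice(dedicated, size=k, replace=False)]
    ambiguous = sorted(
        r.key
        for r in catalog.rules
        if r.key_type == "family"
        and not r.dedicated
        and substrate in r.substrates
        and r.substrates <= guild
    )
    if ambiguous and rng.random() < 0.4:
        fams.append(str(rng.choice(ambiguous)))
    members: list[tuple[str, str | None, str | None]] = [
        ("CAZyme", f, None) for f in fams
    ]
    members.append(("TC", None, None))
    if rng.random() < 0.5:
        members.append(("TF", None, None))
    members = [members[i] for i in rng.permutation(len(members))]
    if rng.random() < 0.5:  # one intervening non-signature gene
        members.insert(int(rng.integers(1, len(members))), ("other", None, None))
    return members


# ---------------------------------------------------------------------------
# abundance model

def sample_abundances(
    mag_base: dict[str, float],
    blocks: list[Block],
    samples: list[SampleMeta],
    rng: np.random.Generator,
    residual_sd: float = 0.15,
) -> pd.DataFrame:
    """Closed relative-abundance table (rows sum to 100%).

    Per sample, each MAG's weight is its base mean, times a shared
    per-block lognormal factor (one draw per block per sample), times the
    block's section multiplier, times per-MAG lognormal residual noise.
    """
    seen: set[str] = set()
    for b in blocks:
        overlap = seen & set(b.members)
        if overlap:
            raise ValueError(f"block memberships overlap: {sorted(overlap)}")
        seen |= set(b.members)
        missing = set(b.members) - set(mag_base)
        if missing:
            raise ValueError(f"block references unknown MAGs: {sorted(missing)}")
    mags = list(mag_base)
    idx = {m: i for i, m in enumerate(mags)}
    rows = []
    for s in samples:
        w = np.array([mag_base[m] for m in mags], dtype=float)
        if residual_sd > 0:
            w *= np.exp(rng.normal(0.0, residual_sd, size=len(mags)))
        for b in blocks:
            factor = math.exp(rng.normal(0.0, b.sd)) if b.sd > 0 else 1.0
            factor *= b.section_boost.get(s.section, 1.0)
            for m in b.members:
                w[idx[m]] *= factor
        rows.append(100.0 * w / w.sum())
    return pd.DataFrame(rows, index=[s.sample_id for s in samples], columns=mags)


def default_blocks(plan: CommunityPlan) -> list[Block]:
    """Six-block layout over the plan's MAGs (A groups IV-enriched)."""
    by_class: dict[str, list[str]] = {}
    for mag, cls in plan.mag_class.items():
        by_class.setdefault(cls, []).append(mag)

    def take(cls: str, n: int) -> list[str]:
        pool = by_class.get(cls, [])
        out, by_class[cls] = pool[:n], pool[n:]
        return out

    blocks = [
        Block(take("Bacilli", 1) + take("Bacteroidia", 1), sd=0.8,
              section_boost={"IV": 2.5}),
        Block(take("Clostridia", 4), sd=0.8, section_boost={"IV": 2.5}),
        Block(take("Clostridia", 4) + take("Bacteroidia", 4), sd=0.8),
        Block(take("Bacteroidia", 8) + take("Verrucomicrobiae", 1), sd=0.8,
              section_boost={"V": 1.5}),
        Block(take("Bacteroidia", 3) + take("Clostridia", 1), sd=0.8,
              section_boost={"V": 2.5}),
        Block(take("Bacteroidia", 3) + take("Gammaproteobacteria", 2), sd=0.8,
              section_boost={"V": 2.0}),
    ]
    return [b for b in blocks if len(b.members) >= 2]


# ---------------------------------------------------------------------------
# main generator

def _emit_hits(
    gene_id: str,
    family: str,
    family_keys: list[str],
    fam_ec: dict[str, str],
    plan: CommunityPlan,
    rng: np.random.Generator,
) -> list[AnnotationHit]:
    """Three-stream evidence for one CAZyme gene, with annotator noise."""
    hits = []
    for source in ("HMMER", "eCAMI", "DIAMOND"):
        if rng.random() > plan.annotator_agreement:
            continue  # stream missed the protein
        label = family
        if plan.label_noise > 0 and rng.random() < plan.label_noise:
            others = [f for f in family_keys if f != family]
            label = str(others[int(rng.integers(len(others)))])
        ec = fam_ec.get(label) if source == "DIAMOND" else None
        hits.append(
            AnnotationHit(
                protein_id=gene_id,
                source=source,
                label=label,
                coverage=float(rng.uniform(0.6, 0.95)),
                identity=float(rng.uniform(0.4, 0.9)),
                evalue=float(10 ** rng.uniform(-60, -10)),
                ec=ec,
            )
        )
    return hits


def generate_community(
    plan: CommunityPlan,
    out_dir: str | Path | None = None,
    catalog: SubstrateCatalog | None = None,
) -> tuple[dict, GroundTruth]:
    """Generate a community bundle (optionally written to ``out_dir``).

    Returns ``(bundle, truth)``; bundle keys: genes, hits, roles,
    mag_metadata, samples, abundance, expression.  Deterministic per
    ``plan.rng_seed``; writing to disk is byte-identical across runs.
    """
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(plan.rng_seed)
    family_keys = sorted(r.key for r in catalog.rules if r.key_type == "family")
    fam_ec: dict[str, str] = {}
    for r in catalog.rules:
        if r.key_type == "family" and r.dedicated:
            for e in catalog.rules:
                if e.key_type == "ec" and e.enzyme_label == r.enzyme_label:
                    fam_ec[r.key] = e.key
                    break

    genes: list[GeneRecord] = []
    hits: list[AnnotationHit] = []
    roles: dict[str, str] = {}
    metas: list[MagMeta] = []
    truth_family: dict[str, str] = {}
    truth_s1: dict[str, str] = {}
    truth_cgcs: list[dict] = []
    mag_class = plan.mag_class
    capability = pd.DataFrame(False, index=plan.mag_ids, columns=list(PANELS))

    for mag in plan.mag_ids:
        cls = mag_class[mag]
        guild = plan.class_guilds.get(cls, frozenset())
        density = plan.class_density.get(cls, 10.0)
        G = plan.genes_per_mag
        n_caz_target = int(round(density * G / 1000.0))
        degradable = sorted(s for s in guild if s not in ("sulfate_removal", "mannitol"))

        # --- compose features (each: kind, substrate, member tuples)
        features: list[dict] = []
        if degradable and plan.cgc_rate > 0:
            for _ in range(int(rng.poisson(plan.cgc_rate))):
                sub = str(rng.choice(degradable))
                features.append(
                    {"kind": "cgc", "substrate": sub,
                     "items": plant_cgc(sub, catalog, guild, rng)}
                )
        n_cgc_caz = sum(
            1 for f in features for role, _, _ in f["items"] if role == "CAZyme"
        )
        cap_fams: list[str] = []
        for sub in degradable:
            pool = _families_for(catalog, sub, guild)
            if not pool:
                continue
            k = 2 if cls in ("Bacteroidia", "Clostridia") and len(pool) > 1 else 1
            cap_fams.extend(str(f) for f in rng.choice(pool, size=k, replace=False))
        for fam in cap_fams:
            features.append(
                {"kind": "cazyme", "substrate": None,
                 "items": [("CAZyme", fam, None)]}
            )
        if "sulfate_removal" in guild:
            s1_pool = S1_BY_CLASS.get(cls, ("S1_15",))
            for _ in range(int(rng.integers(2, 5))):
                features.append(
                    {"kind": "sulfatase", "substrate": None,
                     "items": [("sulfatase", str(rng.choice(s1_pool)), None)]}
                )
        if "mannitol" in guild:
            for sym in MANNITOL_GENES_BY_CLASS.get(cls, ()):
                features.append(
                    {"kind": "mannitol", "substrate": None,
                     "items": [("other", None, sym)]}
                )
        n_filler = max(0, n_caz_target - n_cgc_caz - len(cap_fams))
        filler_pool = sorted(
            {f for sub in degradable for f in _families_for(catalog, sub, guild)}
            | set(_FILLER_FAMILIES)
        )
        for _ in range(n_filler):
            features.append(
                {"kind": "cazyme", "substrate": None,
                 "items": [("CAZyme", str(rng.choice(filler_pool)), None)]}
            )
        features = [features[i] for i in rng.permutation(len(features))]

        # --- lay features onto a gene grid with buffer genes between them
        grid: list[tuple[str, str | None, str | None]] = [("other", None, None)] * G
        placements: list[tuple[dict, list[int]]] = []
        pos = 2
        for feat in features:
            L = len(feat["items"])
            if pos // _GENES_PER_CONTIG != (pos + L - 1) // _GENES_PER_CONTIG:
                pos = ((pos // _GENES_PER_CONTIG) + 1) * _GENES_PER_CONTIG + 2
            if pos + L > G:
                raise ValueError(f"infeasible plan: features overflow {G} genes in {mag}")
            for k, item in enumerate(feat["items"]):
                grid[pos + k] = item
            placements.append((feat, list(range(pos, pos + L))))
            pos += L + _FEATURE_BUFFER

        # --- materialize gene records, hits, roles, truth
        for i, (role, fam, product) in enumerate(grid):
            contig = f"{mag}_c{i // _GENES_PER_CONTIG + 1}"
            within = i % _GENES_PER_CONTIG
            gid = f"{mag}_g{i + 1:05d}"
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    mag_id=mag,
                    contig_id=contig,
                    start=1 + within * 1000,
                    end=within * 1000 + 900,
                    strand="+" if rng.random() < 0.5 else "-",
                    product_label=product,
                )
            )
            if role == "CAZyme" and fam is not None:
                truth_family[gid] = fam
                roles[gid] = "CAZyme"
                hits.extend(_emit_hits(gid, fam, family_keys, fam_ec, plan, rng))
            elif role == "sulfatase" and fam is not None:
                truth_s1[gid] = fam
                roles[gid] = "other"
                hits.append(
                    AnnotationHit(
                        protein_id=gid,
                        source="DIAMOND",
                        label=fam,
                        coverage=float(rng.uniform(0.6, 0.95)),
                        identity=float(rng.uniform(0.35, 0.8)),
                        evalue=float(10 ** rng.uniform(-60, -10)),
                        domains=frozenset({"PF00884"}),
                    )
                )
            elif role in ("TC", "TF", "STP"):
                roles[gid] = role
            else:
                roles[gid] = "other"

        for feat, positions in placements:
            if feat["kind"] == "cgc":
                truth_cgcs.append(
                    {
                        "mag_id": mag,
                        "gene_ids": [f"{mag}_g{p + 1:05d}" for p in positions],
                        "substrate": feat["substrate"],
                    }
                )

        # --- truth capability row: planted families are guild-restricted by
        # construction, so the row equals the guild's substrate set
        for sub in degradable:
            capability.loc[mag, sub] = True
        # ambiguous planted families may add substrates, but families are
        # guild-restricted by construction, so the guild row is exact
        if "sulfate_removal" in guild:
            capability.loc[mag, "sulfatases"] = True
        mannitol_genes = set(MANNITOL_GENES_BY_CLASS.get(cls, ())) if "mannitol" in guild else set()
        if {"m2dh", "fructokinase"} <= mannitol_genes or {"pts_mannitol", "m1pdh"} <= mannitol_genes:
            capability.loc[mag, "mannitol"] = True

        metas.append(
            MagMeta(
                mag_id=mag,
                taxonomy=(*CLASS_TAXONOMY[cls], f"{mag} sp."),
                completeness=float(rng.uniform(*plan.completeness_range)),
                contamination=float(rng.uniform(*plan.contamination_range)),
                n_genes=G,
                genome_size=G * 1000,
            )
        )

    # --- abundance
    blocks = plan.coabund_blocks if plan.coabund_blocks is not None else default_blocks(plan)
    mag_base = {}
    for mag in plan.mag_ids:
        cls = mag_class[mag]
        base = plan.class_abundance.get(cls, 1.0) / max(1, plan.n_mags_per_class[cls])
        mag_base[mag] = base * math.exp(rng.normal(0.0, 0.5))
    samples = [
        SampleMeta(
            sample_id=f"S{f + 1}_{sec}",
            fish_id=f"fish{f + 1}",
            section=sec,
            year=2017,
            assay="metagenome",
        )
        for f in range(plan.n_fish)
        for sec in plan.sections
    ]
    abundance = sample_abundances(mag_base, blocks, samples, rng, plan.residual_sd)

    # --- transcript counts (metatranscriptome samples; annotated genes only)
    mt_samples = [
        SampleMeta(
            sample_id=f"T{f + 1}_{sec}",
            fish_id=f"fish{f + 1}",
            section=sec,
            year=2020,
            assay="metatranscriptome",
        )
        for f in range(plan.n_fish)
        for sec in plan.sections
    ]
    expressed = sorted(set(truth_family) | set(truth_s1))
    gene_mag = {g.gene_id: g.mag_id for g in genes}
    expr_rows = []
    for s in mt_samples:
        mult = DEFAULT_EXPR_MULT.get(s.section, {})
        for gid in expressed:
            cls = mag_class[gene_mag[gid]]
            mean = 20.0 * mult.get(cls, _EXPR_MULT_DEFAULT) * mag_base[gene_mag[gid]]
            mean = max(mean, 0.05)
            # negative binomial with dispersion r=2
            r_disp = 2.0
            p_nb = r_disp / (r_disp + mean)
            count = int(rng.negative_binomial(r_disp, p_nb))
            if count > 0:
                expr_rows.append({"gene_id": gid, "sample_id": s.sample_id, "count": count})
    expression = pd.DataFrame(expr_rows, columns=["gene_id", "sample_id", "count"])

    truth = GroundTruth(
        protein_family=truth_family,
        protein_s1=truth_s1,
        capability=capability,
        cgcs=truth_cgcs,
        blocks={f"block{i + 1}": list(b.members) for i, b in enumerate(blocks)},
        mag_class=mag_class,
    )
    bundle = {
        "genes": genes,
        "hits": hits,
        "roles": roles,
        "mag_metadata": metas,
        "samples": samples + mt_samples,
        "abundance": abundance,
        "expression": expression,
    }
    if out_dir is not None:
        write_bundle(bundle, truth, out_dir)
    return bundle, truth


def write_bundle(bundle: dict, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write a generated bundle plus ground-truth sidecars to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_table(bundle["genes"], out / "genes.gff")
    write_annotation_hits(bundle["hits"], out / "annotation_hits.tsv")
    write_mag_metadata(bundle["mag_metadata"], out / "mag_metadata.tsv")
    write_sample_metadata(bundle["samples"], out / "samples.tsv")
    write_abundance_table(bundle["abundance"], out / "abundance.tsv")
    write_expression_table(bundle["expression"], out / "expression.tsv")
    pd.DataFrame(
        sorted(bundle["roles"].items()), columns=["gene_id", "role"]
    ).to_csv(out / "gene_roles.tsv", sep="\t", index=False)

    tdir = out / "ground_truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(
        sorted(truth.protein_family.items()), columns=["gene_id", "family"]
    ).to_csv(tdir / "true_families.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.protein_s1.items()), columns=["gene_id", "s1_family"]
    ).to_csv(tdir / "true_sulfatases.tsv", sep="\t", index=False)
    truth.capability.astype(int).to_csv(tdir / "true_capability.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "mag_id": c["mag_id"],
                "gene_ids": ",".join(c["gene_ids"]),
                "substrate": c["substrate"],
            }
            for c in truth.cgcs
        ],
        columns=["mag_id", "gene_ids", "substrate"],
    ).to_csv(tdir / "true_cgcs.tsv", sep="\t", index=False)
    with open(tdir / "true_blocks.yaml", "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in truth.blocks.items()}, fh, sort_keys=True)


def read_bundle(in_dir: str | Path) -> dict:
    """Read a bundle directory back into in-memory tables."""
    from .io import (
        read_abundance_table,
        read_annotation_hits,
        read_expression_table,
        read_gene_table,
        read_mag_metadata,
        read_sample_metadata,
    )

    p = Path(in_dir)
    for name in ("genes.gff", "annotation_hits.tsv", "mag_metadata.tsv",
                 "samples.tsv", "abundance.tsv", "expression.tsv"):
        if not (p / name).exists():
            raise FileNotFoundError(f"{name} not found in {in_dir}")
    roles_df = pd.read_csv(p / "gene_roles.tsv", sep="\t", dtype=str)
    return {
        "genes": read_gene_table(p / "genes.gff"),
        "hits": read_annotation_hits(p / "annotation_hits.tsv"),
        "roles": dict(zip(roles_df["gene_id"], roles_df["role"])),
        "mag_metadata": read_mag_metadata(p / "mag_metadata.tsv"),
        "samples": read_sample_metadata(p / "samples.tsv"),
        "abundance": read_abundance_table(p / "abundance.tsv"),
        "expression": read_expression_table(p / "expression.tsv"),
    }
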