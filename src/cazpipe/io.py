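"""On-disk formats shared by all pipeline stages.

Gene tables are a GFF3 subset (seqid, source, type, start, end, score,
strand, phase, attributes with an ``ID=`` tag plus a ``mag_id=`` tag);
coordinates are 1-based inclusive throughout the package.  Evidence and
result tables are TSV with documented headers.  Every writer/reader pair
round-trips records exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .config import EVIDENCE_SOURCES, SECTIONS


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GeneRecord:
    """One predicted gene on a MAG contig (1-based inclusive coordinates)."""

    gene_id: str
    mag_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product_label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class AnnotationHit:
    """One evidence record for a protein from one annotation stream.

    ``label`` may be a comma-joined set when a stream reports several
    candidate families for the same protein.  Coverage and identity are
    fractions of the database target.
    """

    protein_id: str
    source: str
    label: str
    coverage: float
    identity: float
    evalue: float
    ec: str | None = None
    domains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(
                f"unknown evidence source {self.source!r}; allowed: {list(EVIDENCE_SOURCES)}"
            )
        if not self.label:
            raise ValueError(f"hit for {self.protein_id}: empty label")
        for name, v in (("coverage", self.coverage), ("identity", self.identity)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"hit for {self.protein_id}: {name} must be in [0, 1], got {v}"
                )

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(x for x in self.label.split(",") if x)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    fish_id: str
    section: str
    year: int = 2017
    assay: str = "metagenome"

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValueError(f"sample {self.sample_id}: section must be one of {list(SECTIONS)}")
        if self.assay not in ("metagenome", "metatranscriptome"):
            raise ValueError(f"sample {self.sample_id}: unknown assay {self.assay!r}")


@dataclass(frozen=True)
class MagMeta:
    """MAG taxonomy (7 GTDB-style ranks) and assembly QC."""

    mag_id: str
    taxonomy: tuple[str, ...]  # domain..species; 'unclassified' below resolution
    completeness: float  # percent
    contamination: float  # percent
    n_genes: int
    genome_size: int  # bp

    def __post_init__(self) -> None:
        if len(self.taxonomy) != 7:
            raise ValueError(f"MAG {self.mag_id}: taxonomy must have 7 ranks")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"MAG {self.mag_id}: completeness out of [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"MAG {self.mag_id}: contamination must be >= 0")

    @property
    def class_label(self) -> str:
        return self.taxonomy[2]

    @property
    def genus_label(self) -> str:
        return self.taxonomy[5]


RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


# ---------------------------------------------------------------------------
# gene tables (GFF3 subset)

def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a GFF3-subset gene table.

    Expects 9 tab-separated columns; attribute tags ``ID`` (gene id,
    globally unique) and ``mag_id`` are required, ``product`` is optional.
    Records are returned sorted by (mag_id, contig_id, start).
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, _source, _type, start_s, end_s, _score, strand, _phase, attrs = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: malformed coordinate ({start_s!r}, {end_s!r})"
                ) from None
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            if "ID" not in tags:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            if "mag_id" not in tags:
                raise ParseError(f"{path}:{lineno}: missing mag_id attribute")
            gene_id = tags["ID"]
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                rec = GeneRecord(
                    gene_id=gene_id,
                    mag_id=tags["mag_id"],
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    product_label=tags.get("product"),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    records.sort(key=lambda r: (r.mag_id, r.contig_id, r.start))
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(records, key=lambda r: (r.mag_id, r.contig_id, r.start)):
            attrs = f"ID={r.gene_id};mag_id={r.mag_id}"
            if r.product_label:
                attrs += f";product={r.product_label}"
            fh.write(
                f"{r.contig_id}\tcazpipe\tCDS\t{r.start}\t{r.end}\t.\t{r.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# annotation hits

HIT_COLUMNS = ["protein_id", "source", "label", "coverage", "identity",
               "evalue", "ec", "domains"]


def read_annotation_hits(path: str | Path) -> list[AnnotationHit]:
    """Read a TSV of annotation evidence records (one row per hit).

    ``ec`` and ``domains`` use ``-`` for "none"; domains are comma-joined
    Pfam-style accessions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    hits: list[AnnotationHit] = []
    for row in df.itertuples(index=False):
        try:
            hits.append(
                AnnotationHit(
                    protein_id=row.protein_id,
                    source=row.source,
                    label=row.label,
                    coverage=float(row.coverage),
                    identity=float(row.identity),
                    evalue=float(row.evalue),
                    ec=None if row.ec in ("-", "") else row.ec,
                    domains=frozenset()
                    if row.domains in ("-", "")
                    else frozenset(row.domains.split(",")),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return hits


def write_annotation_hits(hits: Iterable[AnnotationHit], path: str | Path) -> None:
    rows = [
        {
            "protein_id": h.protein_id,
            "source": h.source,
            "label": h.label,
            "coverage": f"{h.coverage:.4f}",
            "identity": f"{h.identity:.4f}",
            "evalue": f"{h.evalue:.3g}",
            "ec": h.ec or "-",
            "domains": ",".join(sorted(h.domains)) or "-",
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAG metadata

def read_mag_metadata(path: str | Path) -> list[MagMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["mag_id", *RANKS, "completeness", "contamination", "n_genes", "genome_size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    metas = []
    for row in df.to_dict("records"):  # 'class' clashes with itertuples fields
        metas.append(
            MagMeta(
                mag_id=row["mag_id"],
                taxonomy=tuple(row[rank] for rank in RANKS),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                n_genes=int(row["n_genes"]),
                genome_size=int(row["genome_size"]),
            )
        )
    return metas


def write_mag_metadata(metas: Iterable[MagMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        row = {"mag_id": m.mag_id}
        row.update(dict(zip(RANKS, m.taxonomy)))
        row.update(
            completeness=f"{m.completeness:.2f}",
            contamination=f"{m.contamination:.2f}",
            n_genes=m.n_genes,
            genome_size=m.genome_size,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata and abundance / expression tables

def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "fish_id", "section", "year", "assay"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    return [
        SampleMeta(
            sample_id=r.sample_id,
            fish_id=r.fish_id,
            section=r.section,
            year=int(r.year),
            assay=r.assay,
        )
        for r in df.itertuples(index=False)
    ]


def write_sample_metadata(samples: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "fish_id": s.fish_id,
                "section": s.section,
                "year": s.year,
                "assay": s.assay,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Samples x MAGs relative-abundance matrix (%, rows ~ sum to 100)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative abundance")
    return df


def write_abundance_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Long-format transcript counts: gene_id, sample_id, count."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    missing = [c for c in ("gene_id", "sample_id", "count") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if (df["count"] < 0).any():
        raise ParseError(f"{path}: negative transcript count")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
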