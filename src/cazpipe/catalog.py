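"""Substrate catalog: family/EC/sulfatase/pathway-gene -> substrate mapping.

The catalog is shipped as an editable TSV (``data/substrate_catalog.tsv``)
so curation changes are diffable; this module loads it, validates its
invariants, and derives per-MAG capability calls from accepted annotation
calls.  The capability matrix mirrors the nine presence/absence panels used
for seaweed-diet gut communities: alginate, laminarin, FCSP, carrageenan,
agarose, derived galactans, starch, sulfatases, and mannitol utilization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

#: Substrate vocabulary (sulfate_removal marks desulfation capacity).
SUBSTRATES = (
    "alginate", "laminarin", "FCSP", "carrageenan", "agarose",
    "galactan", "starch", "sulfate_removal", "mannitol",
)

#: Capability-matrix panels, in display order.
PANELS = (
    "alginate", "laminarin", "FCSP", "carrageenan", "agarose",
    "galactan", "starch", "sulfatases", "mannitol",
)

MECHANISMS = ("GH", "PL", "CE", "CBM", "GT", "AA")
DEGRADATIVE_MECHANISMS = frozenset({"GH", "PL", "CE"})

_SUBFAMILY_RE = re.compile(r"^((?:GH|PL|CE|CBM|GT|AA)\d+)_\d+$")


def collapse_subfamily(label: str) -> str:
    """Collapse a CAZy subfamily label (GH13_10) to its family (GH13).

    Sulfatase subfamily labels (S1_15) are *not* CAZy subfamilies and pass
    through unchanged.
    """
    m = _SUBFAMILY_RE.match(label)
    return m.group(1) if m else label


def family_mechanism(family: str) -> str | None:
    """CAZy mechanism prefix (GH/PL/CE/CBM/GT/AA) of a family label."""
    for mech in sorted(MECHANISMS, key=len, reverse=True):
        if family.startswith(mech) and family[len(mech):][:1].isdigit():
            return mech
    return None


@dataclass(frozen=True)
class SubstrateRule:
    """Mapping of one key (family, EC, S1 subfamily or gene symbol)."""

    key: str
    key_type: str  # family | ec | s1 | gene | unmapped
    substrates: frozenset[str]
    weight_class: str  # HMW | LMW | NA
    dedicated: bool
    enzyme_label: str

    @property
    def mapped(self) -> bool:
        return self.key_type != "unmapped"


def _unmapped(key: str) -> SubstrateRule:
    return SubstrateRule(key, "unmapped", frozenset(), "NA", False, "")


@dataclass(frozen=True)
class MannitolGenotype:
    """Presence of the two mannitol -> fructose-6-phosphate routes.

    The cytoplasmic route needs mannitol 2-dehydrogenase (M2DH) plus
    fructokinase; the phosphotransferase route needs a mannitol PTS
    component plus mannitol-1-phosphate 5-dehydrogenase (M1PDH).
    """

    mag_id: str
    has_m2dh: bool = False
    has_fructokinase: bool = False
    has_pts_component: bool = False
    has_m1pdh: bool = False

    @property
    def routes(self) -> frozenset[str]:
        r = set()
        if self.has_m2dh and self.has_fructokinase:
            r.add("M2DH_route")
        if self.has_m1pdh and self.has_pts_component:
            r.add("PTS_M1PDH_route")
        return frozenset(r)


class SubstrateCatalog:
    """Lookup table over families, ECs, S1 subfamilies and gene symbols."""

    def __init__(self, rules: list[SubstrateRule]):
        self._rules: dict[str, SubstrateRule] = {}
        for rule in rules:
            if rule.dedicated and len(rule.substrates) != 1:
                raise ValueError(
                    f"catalog entry {rule.key}: dedicated requires exactly one substrate"
                )
            unknown = rule.substrates - set(SUBSTRATES)
            if unknown:
                raise ValueError(f"catalog entry {rule.key}: unknown substrates {sorted(unknown)}")
            if rule.key in self._rules:
                raise ValueError(f"duplicate catalog key {rule.key}")
            self._rules[rule.key] = rule

    def __len__(self) -> int:
        return len(self._rules)

    def __contains__(self, key: str) -> bool:
        return collapse_subfamily(key) in self._rules

    @property
    def rules(self) -> list[SubstrateRule]:
        return list(self._rules.values())

    def classify_family(self, key: str) -> SubstrateRule:
        """Look up a CAZy family (subfamilies collapsed) or EC number.

        Unknown keys yield an explicit unmapped rule, never an error.
        """
        return self._rules.get(collapse_subfamily(key)) or _unmapped(key)

    def classify_sulfatase(self, s1_family: str) -> SubstrateRule:
        """Look up a SulfAtlas S1 subfamily (e.g. S1_19)."""
        rule = self._rules.get(s1_family)
        if rule is not None and rule.key_type == "s1":
            return rule
        return _unmapped(s1_family)

    def classify_gene(self, symbol: str) -> SubstrateRule:
        rule = self._rules.get(symbol)
        if rule is not None and rule.key_type == "gene":
            return rule
        return _unmapped(symbol)


def load_catalog(path: str | Path | None = None) -> SubstrateCatalog:
    """Load the shipped (or a user-supplied) substrate-catalog TSV."""
    if path is None:
        ref = resources.files("cazpipe").joinpath("data/substrate_catalog.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    rules = [
        SubstrateRule(
            key=r.key,
            key_type=r.key_type,
            substrates=frozenset() if r.substrates in ("-", "") else frozenset(r.substrates.split(",")),
            weight_class=r.weight_class,
            dedicated=r.dedicated == "1",
            enzyme_label=r.enzyme_label,
        )
        for r in df.itertuples(index=False)
    ]
    return SubstrateCatalog(rules)


def call_mannitol_routes(
    mag_id: str, gene_flags: set[str] | frozenset[str]
) -> MannitolGenotype:
    """Build a mannitol genotype from present pathway gene symbols."""
    return MannitolGenotype(
        mag_id=mag_id,
        has_m2dh="m2dh" in gene_flags,
        has_fructokinase="fructokinase" in gene_flags,
        has_pts_component="pts_mannitol" in gene_flags,
        has_m1pdh="m1pdh" in gene_flags,
    )


def build_capability_matrix(
    calls: pd.DataFrame,
    sulfatase_calls: pd.DataFrame,
    mannitol_genotypes: list[MannitolGenotype],
    mag_ids: list[str],
    catalog: SubstrateCatalog,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[str]]]:
    """Per-MAG boolean capability matrix over the nine substrate panels.

    ``calls`` columns: protein_id, mag_id, family; ``sulfatase_calls``
    columns: protein_id, mag_id, s1_family.  Returns the boolean matrix
    (rows = ``mag_ids``, columns = PANELS) plus per-cell supporting enzyme
    labels.  A call referencing a MAG not in ``mag_ids`` is an error.
    """
    matrix = pd.DataFrame(False, index=list(mag_ids), columns=list(PANELS))
    support: dict[tuple[str, str], list[str]] = {}

    def _mark(mag: str, panel: str, label: str) -> None:
        if mag not in matrix.index:
            raise KeyError(f"call references unknown MAG {mag!r}")
        matrix.loc[mag, panel] = True
        support.setdefault((mag, panel), []).append(label)

    if len(calls):
        for row in calls.itertuples(index=False):
            rule = catalog.classify_family(row.family)
            for sub in rule.substrates:
                if sub in ("sulfate_removal", "mannitol"):
                    continue
                _mark(row.mag_id, sub, rule.enzyme_label or row.family)
    if len(sulfatase_calls):
        for row in sulfatase_calls.itertuples(index=False):
            rule = catalog.classify_sulfatase(row.s1_family)
            _mark(row.mag_id, "sulfatases", rule.enzyme_label or row.s1_family)
    for geno in mannitol_genotypes:
        if geno.routes:
            _mark(geno.mag_id, "mannitol", "+".join(sorted(geno.routes)))

    for key in support:
        support[key] = sorted(set(support[key]))
    return matrix, support


def count_weight_classes(
    calls: pd.DataFrame, catalog: SubstrateCatalog
) -> dict[str, tuple[int, int]]:
    """Gene and MAG counts per molecular-weight class.

    Counts accepted degradative calls (GH/PL/CE) whose family maps to HMW
    or LMW; the MAG count is the number of MAGs with at least one such call.
    """
    out = {}
    for wc in ("HMW", "LMW"):
        genes = 0
        mags: set[str] = set()
        for row in calls.itertuples(index=False):
            rule = catalog.classify_family(row.family)
            mech = family_mechanism(collapse_subfamily(row.family))
            if rule.weight_class == wc and mech in DEGRADATIVE_MECHANISMS:
                genes += 1
                mags.add(row.mag_id)
        out[wc] = (genes, len(mags))
    return out
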