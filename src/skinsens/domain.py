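"""Mechanistic applicability-domain filtering for anilines and phenols.

The discriminant model is only claimed valid for compounds that (a) carry an
aniline (primary aromatic amine) or phenol (aromatic hydroxyl) moiety and
(b) do not belong to one of the well-understood electrophilic hapten
mechanism classes — Michael acceptors, SN2 electrophiles, SNAr
electrophiles, Schiff-base formers, acylating agents — or form quinones /
quinone-imines by oxidation of two OH/NH2 groups on one aromatic ring.
Compounds matching any such structural alert react with skin proteins by a
known route and are excluded; what remains is the "mechanistically
hard-to-classify" chemical space the model addresses.

Alert patterns are curated SMARTS. The literature names the mechanism
classes but supplies no machine-readable patterns, so each rule carries a
note documenting its chemistry; the rule set is versioned, serializable and
fully replaceable by the caller.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .errors import RuleError, StructureError

__all__ = [
    "MECHANISM_CLASSES",
    "AlertRule",
    "AlertHit",
    "DomainDecision",
    "DEFAULT_CHEMICAL_RULES",
    "DEFAULT_DRUG_RULES",
    "detect_aniline_moiety",
    "detect_phenol_moiety",
    "match_alerts",
    "in_applicability_domain",
    "load_rules",
    "save_rules",
]

#: Closed vocabulary of electrophilic / exclusion mechanism classes.
MECHANISM_CLASSES = frozenset(
    {
        "MICHAEL_ACCEPTOR",
        "SN2_ELECTROPHILE",
        "SNAR_ELECTROPHILE",
        "SCHIFF_BASE_FORMER",
        "ACYLATOR",
        "QUINONE_PRECURSOR",
        "SULFONAMIDE_DRUG",
    }
)

_ANILINE_SMARTS = Chem.MolFromSmarts("[NX3H2][c]")
_PHENOL_SMARTS = Chem.MolFromSmarts("[OX2H][c]")


@dataclass(frozen=True)
class AlertRule:
    """One substructure alert tied to an exclusion mechanism class."""

    rule_id: str
    mechanism: str
    pattern: str  # SMARTS
    note: str = ""

    def __post_init__(self):
        if self.mechanism not in MECHANISM_CLASSES:
            raise RuleError(f"unknown mechanism class {self.mechanism!r}")
        query = Chem.MolFromSmarts(self.pattern)
        if query is None:
            raise RuleError(
                f"rule {self.rule_id!r}: SMARTS does not compile: {self.pattern!r}"
            )
        object.__setattr__(self, "_query", query)

    @property
    def query(self):
        return self._query


@dataclass(frozen=True)
class AlertHit:
    rule_id: str
    mechanism: str
    atom_indices: tuple[int, ...]


@dataclass(frozen=True)
class DomainDecision:
    """Outcome of the applicability-domain check for one structure."""

    in_domain: bool
    has_aniline: bool
    has_phenol: bool
    hits: tuple[AlertHit, ...] = field(default_factory=tuple)


# Default alert set. The donor veto on the nitro-activated SNAr rule
# (no NH2/OH on the activated ring) is deliberate: strong pi-donors
# deactivate a ring toward nucleophilic aromatic substitution, and
# nitro-haloanilines such as 2-fluoro-5-nitroaniline belong to the
# hard-to-classify domain, not to the SNAr class.
_NO_DONOR_C = "[c;!$(c[NX3H2]);!$(c[OX2H])]"
DEFAULT_CHEMICAL_RULES: tuple[AlertRule, ...] = (
    AlertRule(
        "michael_enone",
        "MICHAEL_ACCEPTOR",
        "[CX3]=[CX3][CX3]=[OX1]",
        "alpha,beta-unsaturated carbonyl; 1,4-addition of protein nucleophiles",
    ),
    AlertRule(
        "michael_vinyl_sulfone",
        "MICHAEL_ACCEPTOR",
        "[CX3]=[CX3][SX4](=[OX1])=[OX1]",
        "vinyl sulfone Michael acceptor",
    ),
    AlertRule(
        "michael_nitroalkene",
        "MICHAEL_ACCEPTOR",
        "[CX3]=[CX3][NX3+](=[OX1])[OX1-]",
        "nitroalkene Michael acceptor",
    ),
    AlertRule(
        "sn2_alkyl_halide",
        "SN2_ELECTROPHILE",
        "[CX4][Cl,Br,I]",
        "halide leaving group on sp3 carbon",
    ),
    AlertRule(
        "sn2_epoxide",
        "SN2_ELECTROPHILE",
        "[CX4]1[OX2][CX4]1",
        "strained epoxide opened by protein nucleophiles",
    ),
    AlertRule(
        "sn2_sulfonate_ester",
        "SN2_ELECTROPHILE",
        "[CX4][OX2][SX4](=[OX1])(=[OX1])",
        "sulfonate ester leaving group on sp3 carbon",
    ),
    AlertRule(
        "snar_polyhalide",
        "SNAR_ELECTROPHILE",
        "c([F,Cl,Br,I])c([F,Cl,Br,I])c([F,Cl,Br,I])",
        "contiguously polyhalogenated aromatic (e.g. pentachlorophenol)",
    ),
    AlertRule(
        "snar_nitro_halide_ortho",
        "SNAR_ELECTROPHILE",
        f"[F,Cl,Br,I]c1c([NX3+](=[OX1])[OX1-]){_NO_DONOR_C}{_NO_DONOR_C}"
        f"{_NO_DONOR_C}{_NO_DONOR_C}1",
        "aryl halide ortho to nitro on a donor-free ring",
    ),
    AlertRule(
        "snar_nitro_halide_para",
        "SNAR_ELECTROPHILE",
        f"[F,Cl,Br,I]c1{_NO_DONOR_C}{_NO_DONOR_C}c([NX3+](=[OX1])[OX1-])"
        f"{_NO_DONOR_C}{_NO_DONOR_C}1",
        "aryl halide para to nitro on a donor-free ring",
    ),
    AlertRule(
        "schiff_aldehyde",
        "SCHIFF_BASE_FORMER",
        "[CX3H1](=[OX1])[#6]",
        "aldehyde condensing with lysine amines",
    ),
    AlertRule(
        "schiff_dicarbonyl",
        "SCHIFF_BASE_FORMER",
        "[CX3](=[OX1])[CX3](=[OX1])",
        "1,2-dicarbonyl (activated ketone) Schiff-base former",
    ),
    AlertRule(
        "acyl_halide",
        "ACYLATOR",
        "[CX3](=[OX1])[Cl,Br,I]",
        "acyl halide",
    ),
    AlertRule(
        "acyl_anhydride",
        "ACYLATOR",
        "[CX3](=[OX1])[OX2][CX3](=[OX1])",
        "carboxylic anhydride",
    ),
    AlertRule(
        "acyl_aryl_ester",
        "ACYLATOR",
        "[CX3](=[OX1])[OX2][c]",
        "activated (aryl) ester; phenolate leaving group",
    ),
    AlertRule(
        "acyl_benzyl_ester",
        "ACYLATOR",
        "[CX3](=[OX1])[OX2][CH2][c]",
        "benzylic ester, activated toward acyl transfer (e.g. benzyl salicylate)",
    ),
    AlertRule(
        "quinone_ortho",
        "QUINONE_PRECURSOR",
        "[OX2H,NX3H2]-c:c-[OX2H,NX3H2]",
        "two OH/NH2 ortho on one aromatic ring; oxidizes to an o-quinone(imine)",
    ),
    AlertRule(
        "quinone_para",
        "QUINONE_PRECURSOR",
        "[OX2H,NX3H2]c1ccc([OX2H,NX3H2])cc1",
        "two OH/NH2 para on one benzene ring; oxidizes to a p-quinone(imine)",
    ),
)

#: Drug screening adds removal of sulfonamide drugs, which sensitize through
#: a distinct hydroxylamine/nitroso bioactivation route.
DEFAULT_DRUG_RULES: tuple[AlertRule, ...] = DEFAULT_CHEMICAL_RULES + (
    AlertRule(
        "sulfonamide_drug",
        "SULFONAMIDE_DRUG",
        "[SX4](=[OX1])(=[OX1])[NX3]",
        "sulfonamide drug class; N-hydroxylamine/nitroso bioactivation",
    ),
)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, strip salt counter-ions (keep the largest fragment)."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureError("empty structure string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        # deterministic: heavy-atom count, ties broken by canonical SMILES
        mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return mol


def detect_aniline_moiety(smiles: str) -> bool:
    """True iff a primary amine (-NH2) sits on an aromatic ring atom.

    Heteroaromatic rings count (aminopyridines are anilines here).
    """
    return mol_from_smiles(smiles).HasSubstructMatch(_ANILINE_SMARTS)


def detect_phenol_moiety(smiles: str) -> bool:
    """True iff a hydroxyl oxygen sits on an aromatic ring atom."""
    return mol_from_smiles(smiles).HasSubstructMatch(_PHENOL_SMARTS)


def match_alerts(
    smiles: str, rules: Iterable[AlertRule] = DEFAULT_CHEMICAL_RULES
) -> list[AlertHit]:
    """All alert-rule matches, ordered by (rule_id, first matched atom)."""
    mol = mol_from_smiles(smiles)
    hits: list[AlertHit] = []
    for rule in rules:
        for match in mol.GetSubstructMatches(rule.query):
            hits.append(AlertHit(rule.rule_id, rule.mechanism, tuple(match)))
    hits.sort(key=lambda h: (h.rule_id, h.atom_indices))
    return hits


def in_applicability_domain(
    record, rules: Iterable[AlertRule] = DEFAULT_CHEMICAL_RULES
) -> DomainDecision:
    """Applicability-domain decision for a record or bare SMILES string.

    In-domain means: has an aniline and/or phenol moiety and fires no alert
    in the active rule set. The rule set is a parameter so the drug screen
    can activate the sulfonamide rule that the chemical stage omits.
    """
    smiles = record if isinstance(record, str) else getattr(record, "smiles", None)
    if not smiles:
        raise StructureError("record has no structure")
    rules = tuple(rules)
    has_aniline = detect_aniline_moiety(smiles)
    has_phenol = detect_phenol_moiety(smiles)
    hits = tuple(match_alerts(smiles, rules))
    return DomainDecision(
        in_domain=(has_aniline or has_phenol) and not hits,
        has_aniline=has_aniline,
        has_phenol=has_phenol,
        hits=hits,
    )


def save_rules(rules: Sequence[AlertRule], path) -> None:
    """Serialize a rule set as a tab-separated table."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["rule_id", "mechanism", "pattern", "note"])
        for rule in rules:
            writer.writerow([rule.rule_id, rule.mechanism, rule.pattern, rule.note])


def load_rules(path) -> tuple[AlertRule, ...]:
    """Load a rule set from the tab-separated table written by save_rules."""
    path = Path(path)
    rules = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {
            "rule_id",
            "mechanism",
            "pattern",
        }.issubset(reader.fieldnames):
            raise RuleError(f"{path}: expected columns rule_id, mechanism, pattern")
        seen = set()
        for row in reader:
            if row["rule_id"] in seen:
                raise RuleError(f"duplicate rule_id {row['rule_id']!r}")
            seen.add(row["rule_id"])
            rules.append(
                AlertRule(
                    row["rule_id"],
                    row["mechanism"],
                    row["pattern"],
                    row.get("note", "") or "",
                )
            )
    return tuple(rules)
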