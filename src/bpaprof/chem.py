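"""Compound library handling for the benzylphenoxyacetamide (BPA) series.

The BPA scaffold is a phenoxy-propanamide carrying a (substituted
benzoyl/benzyl)phenyl group.  Four regions of the skeleton are treated as
variable:

* region **A** — the halogen on the distal aromatic ring (Cl, F, H, ...),
* region **B** — the linker between the two rings (carbonyl, methylene,
  ether, or a fully reduced cyclohexylmethyl arm),
* region **C** — the alpha substitution of the acyl carbon (gem-dimethyl,
  monomethyl, unsubstituted),
* region **D** — the amide (or ester/acid) moiety.

This module parses structures, loads the packaged reference library of
literature compounds with their transcribed cell-viability data, and
enumerates virtual variant libraries over the four-region design space.
"""

from __future__ import annotations

import contextlib
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, rdBase

__all__ = [
    "Atom",
    "Bond",
    "Compound",
    "CvRecord",
    "EnumerationError",
    "LibraryError",
    "LibraryTable",
    "MoleculeGraph",
    "SmilesParseError",
    "enumerate_bpa_variants",
    "load_library",
    "load_reference_library",
    "parse_structure",
    "REGION_A_FRAGMENTS",
    "REGION_B_FRAGMENTS",
    "REGION_C_FRAGMENTS",
    "REGION_D_FRAGMENTS",
    "AMIDE_CLASS_BY_D_LABEL",
]


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be perceived as a molecule."""

    def __init__(self, smiles: str, position: int, detail: str = ""):
        self.smiles = smiles
        self.position = position
        msg = f"cannot parse SMILES {smiles!r}: offending token at position {position}"
        if detail:
            msg += f" ({detail.strip()})"
        super().__init__(msg)


class LibraryError(ValueError):
    """Raised for malformed library tables (duplicate ids, orphan CV rows...)."""


class EnumerationError(ValueError):
    """Raised when a region fragment choice yields an invalid structure."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    formal_charge: int
    aromatic: bool
    n_hydrogens: int
    in_ring: bool


@dataclass(frozen=True)
class Bond:
    begin: int
    end: int
    order: float  # 1, 2, 3 or 1.5 for aromatic


@dataclass
class MoleculeGraph:
    """A perceived molecule: parent organic fragment plus marked counterions.

    ``mol`` is the parent fragment (largest fragment by heavy-atom count,
    formal charges preserved); ``counterions`` holds the stripped fragments
    as canonical SMILES.  All descriptor work downstream operates on the
    parent only.
    """

    smiles: str
    mol: Chem.Mol
    counterions: tuple[str, ...] = ()

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                index=a.GetIdx(),
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                aromatic=a.GetIsAromatic(),
                n_hydrogens=a.GetTotalNumHs(),
                in_ring=a.IsInRing(),
            )
            for a in self.mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[Bond]:
        return [
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]

    @property
    def num_rings(self) -> int:
        return self.mol.GetRingInfo().NumRings()

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass(frozen=True)
class CvRecord:
    compound_id: str
    concentration: float  # micromolar
    mean_cv: float        # % of vehicle control
    sd: float | None = None  # percentage points; None when not reported


@dataclass
class Compound:
    id: str
    name: str
    smiles: str
    region_tags: dict[str, str] = field(default_factory=dict)
    salt: str | None = None

    def graph(self) -> MoleculeGraph:
        return parse_structure(self.smiles)


@dataclass
class LibraryTable:
    compounds: list[Compound]
    measurements: list[CvRecord] = field(default_factory=list)
    # populated by the synthetic generator only:
    true_flags: dict | None = None
    planted_rule: object | None = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise LibraryError(f"duplicate compound id(s): {sorted(dupes)}")
        known = set(ids)
        for m in self.measurements:
            if m.compound_id not in known:
                raise LibraryError(f"CV record references unknown id {m.compound_id!r}")
            if m.sd is not None and m.sd < 0:
                raise LibraryError(f"negative SD for {m.compound_id!r}")
            if m.concentration <= 0:
                raise LibraryError(f"non-positive concentration for {m.compound_id!r}")

    def compound(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def measurements_for(self, cid: str) -> list[CvRecord]:
        return [m for m in self.measurements if m.compound_id == cid]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\[[^\]]*\]"          # bracket atom
    r"|Cl|Br"              # two-letter organic-subset atoms
    r"|[BCNOPSFIbcnops]"   # one-letter organic subset
    r"|%\d\d"              # two-digit ring closure
    r"|[0-9]"              # ring closure
    r"|[-=#$:/\\.()+*~@]"  # bonds, branches, dots, wildcards
)


def _offending_position(smiles: str) -> int:
    """Best-effort location of the first bad token in an unparseable SMILES."""
    pos = 0
    ring_open: dict[str, int] = {}
    paren_stack: list[int] = []
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            return pos  # lexically invalid character
        tok = m.group(0)
        if tok == "(":
            paren_stack.append(pos)
        elif tok == ")":
            if not paren_stack:
                return pos
            paren_stack.pop()
        elif tok.isdigit() or tok.startswith("%"):
            if tok in ring_open:
                ring_open.pop(tok)
            else:
                ring_open[tok] = pos
        pos = m.end()
    if paren_stack:
        return paren_stack[0]
    if ring_open:
        return min(ring_open.values())
    return 0


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    rdBase.LogToPythonStderr()
    buf = io.StringIO()
    with contextlib.redirect_stderr(buf):
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, _offending_position(smiles), buf.getvalue())
    return mol


def parse_structure(smiles: str) -> MoleculeGraph:
    """Perceive a molecule from SMILES.

    Multi-fragment (salt) notation is allowed: the largest fragment by
    heavy-atom count becomes the parent (formal charges preserved, so e.g.
    a quaternary ammonium parent stays cationic); the remaining fragments
    are retained as counterion SMILES.  Aromaticity and implicit hydrogens
    are resolved by the perception step.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles or "", 0, "empty SMILES")
    mol = _mol_from_smiles(smiles.strip())
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return MoleculeGraph(smiles=smiles.strip(), mol=frags[0])
    ranked = sorted(
        frags,
        key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
        reverse=True,
    )
    parent, *ions = ranked
    return MoleculeGraph(
        smiles=smiles.strip(),
        mol=parent,
        counterions=tuple(Chem.MolToSmiles(i) for i in ions),
    )


# --------------------------------------------------------------------------
# library I/O
# --------------------------------------------------------------------------

_COLUMNS = ["id", "name", "smiles", "region_a", "region_b", "region_c",
            "region_d", "salt", "conc_um", "mean_cv", "sd_cv"]


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and not value.strip()
    )


def load_library(path) -> LibraryTable:
    """Load a delimited compound table (UTF-8, comma, ``#`` comments).

    Rows with a SMILES define compounds; rows with an id but no SMILES are
    viability measurement rows referencing an earlier compound.  Compound
    rows may also carry inline CV columns.  Errors: duplicate id, CV row
    with unknown id, negative SD.
    """
    df = pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    missing = [c for c in ("id", "smiles") if c not in df.columns]
    if missing:
        raise LibraryError(f"library table missing column(s): {missing}")
    compounds: list[Compound] = []
    measurements: list[CvRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        cid = str(row["id"]).strip()
        if _is_blank(row["smiles"]):
            # measurement-only row
            if cid not in seen:
                raise LibraryError(f"CV row references unknown id {cid!r}")
        else:
            if cid in seen:
                raise LibraryError(f"duplicate compound id {cid!r}")
            seen.add(cid)
            tags = {}
            for region, col in (("A", "region_a"), ("B", "region_b"),
                                ("C", "region_c"), ("D", "region_d")):
                if col in df.columns and not _is_blank(row.get(col)):
                    tags[region] = str(row[col]).strip()
            salt = None
            if "salt" in df.columns and not _is_blank(row.get("salt")):
                salt = str(row["salt"]).strip()
                if salt.lower() == "none":
                    salt = None
            compound = Compound(
                id=cid,
                name="" if _is_blank(row.get("name")) else str(row["name"]).strip(),
                smiles=str(row["smiles"]).strip(),
                region_tags=tags,
                salt=salt,
            )
            parse_structure(compound.smiles)  # must be a valid molecule
            compounds.append(compound)
        if "conc_um" in df.columns and not _is_blank(row.get("conc_um")):
            sd = None if _is_blank(row.get("sd_cv")) else float(row["sd_cv"])
            if sd is not None and sd < 0:
                raise LibraryError(f"negative SD for {cid!r}")
            measurements.append(
                CvRecord(cid, float(row["conc_um"]), float(row["mean_cv"]), sd)
            )
    return LibraryTable(compounds, measurements)


def load_reference_library() -> LibraryTable:
    """Load the packaged literature compounds and their transcribed CV data."""
    ref = resources.files("bpaprof").joinpath("data/bpa_reference.csv")
    with resources.as_file(ref) as path:
        return load_library(path)


# --------------------------------------------------------------------------
# enumeration over the four-region design space
# --------------------------------------------------------------------------

# region A: para substituent on the distal ring
REGION_A_FRAGMENTS: dict[str, str] = {
    "Cl": "Cl",
    "F": "F",
    "Br": "Br",
    "H": "",
}

# region B: linker plus distal ring; ``{a}`` receives the region-A substituent
REGION_B_FRAGMENTS: dict[str, str] = {
    "carbonyl": "C(=O)c2ccc({a})cc2",
    "methylene": "Cc2ccc({a})cc2",
    "ether": "Oc2ccc({a})cc2",
    "reduced_ring": "CC2CCC({a})CC2",
}

# region C: alpha carbon written as the first atom of the SMILES
REGION_C_FRAGMENTS: dict[str, str] = {
    "gem_dimethyl": "C(C)(C)",
    "monomethyl": "C(C)",
    "unsubstituted": "C",
}

# region D: acyl substituent (amide N, ester O or acid OH) after ``C(=O)``
REGION_D_FRAGMENTS: dict[str, str] = {
    "N_methyl_N_hydroxyethyl": "N(C)CCO",
    "NN_dimethyl": "N(C)C",
    "NN_bis_hydroxyethyl": "N(CCO)CCO",
    "N_methylpiperazine": "N2CCN(C)CC2",
    "NN_dimethylpiperazinium": "N2CC[N+](C)(C)CC2",
    "N_diethylaminoethyl": "NCCN(CC)CC",
    "N_methyl": "NC",
    "N_hydroxyethyl": "NCCO",
    "primary_amide": "N",
    "isopropyl_ester": "OC(C)C",
    "carboxylic_acid": "O",
}

AMIDE_CLASS_BY_D_LABEL: dict[str, str] = {
    "N_methyl_N_hydroxyethyl": "tertiary",
    "NN_dimethyl": "tertiary",
    "NN_bis_hydroxyethyl": "tertiary",
    "N_methylpiperazine": "tertiary",
    "NN_dimethylpiperazinium": "tertiary",
    "N_diethylaminoethyl": "secondary",
    "N_methyl": "secondary",
    "N_hydroxyethyl": "secondary",
    "primary_amide": "primary",
    "isopropyl_ester": "ester",
    "carboxylic_acid": "acid",
}


def _fragment(table: Mapping[str, str], region: str, choice: str) -> str:
    """Resolve a choice label to its fragment; raw SMILES passes through."""
    return table.get(choice, choice)


def assemble_variant_smiles(a: str, b: str, c: str, d: str) -> str:
    """Write the variant SMILES for one choice per region."""
    a_frag = _fragment(REGION_A_FRAGMENTS, "A", a)
    b_frag = _fragment(REGION_B_FRAGMENTS, "B", b).format(a=a_frag)
    b_frag = b_frag.replace("()", "")  # A = H leaves an empty branch
    c_frag = _fragment(REGION_C_FRAGMENTS, "C", c)
    d_frag = _fragment(REGION_D_FRAGMENTS, "D", d)
    return f"{c_frag}(Oc1ccc({b_frag})cc1)C(=O){d_frag}"


def enumerate_bpa_variants(
    options: Mapping[str, Sequence[str]],
    id_prefix: str = "V",
) -> list[Compound]:
    """Enumerate the Cartesian product of per-region fragment choices.

    Every combination must yield a valid structure; output is deterministic
    (compounds ordered by the option grid, ``V0001``-style ids) and
    deduplicated on canonical SMILES, so distinct fragment choices give the
    product of the per-region option counts.
    """
    for region in "ABCD":
        if not options.get(region):
            raise EnumerationError(f"region {region} needs at least one choice")
    variants: list[Compound] = []
    seen: dict[str, str] = {}
    n = 0
    for a in options["A"]:
        for b in options["B"]:
            for c in options["C"]:
                for d in options["D"]:
                    n += 1
                    smi = assemble_variant_smiles(a, b, c, d)
                    try:
                        graph = parse_structure(smi)
                    except SmilesParseError as exc:
                        bad = _first_bad_choice(a, b, c, d)
                        raise EnumerationError(
                            f"invalid structure from region {bad[0]} choice "
                            f"{bad[1]!r}: {exc}"
                        ) from exc
                    canonical = Chem.MolToSmiles(graph.mol)
                    if graph.counterions:
                        canonical = ".".join([canonical, *graph.counterions])
                    if canonical in seen:
                        continue  # dedupe on canonical form; first wins
                    cid = f"{id_prefix}{n:04d}"
                    seen[canonical] = cid
                    variants.append(
                        Compound(
                            id=cid,
                            name=f"BPA variant {a}/{b}/{c}/{d}",
                            smiles=canonical,
                            region_tags={"A": a, "B": b, "C": c, "D": d},
                        )
                    )
    return variants


def _first_bad_choice(a: str, b: str, c: str, d: str) -> tuple[str, str]:
    """Locate which region's choice breaks the assembled SMILES."""
    probes = {
        "A": assemble_variant_smiles(a, "carbonyl", "gem_dimethyl", "N_methyl"),
        "B": assemble_variant_smiles("Cl", b, "gem_dimethyl", "N_methyl"),
        "C": assemble_variant_smiles("Cl", "carbonyl", c, "N_methyl"),
        "D": assemble_variant_smiles("Cl", "carbonyl", "gem_dimethyl", d),
    }
    choices = {"A": a, "B": b, "C": c, "D": d}
    for region, probe in probes.items():
        if Chem.MolFromSmiles(probe) is None:
            return region, choices[region]
    return "A/B/C/D", f"({a}, {b}, {c}, {d})"
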