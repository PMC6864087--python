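"""Physicochemical descriptor panel for BPA-series compounds.

The panel mirrors the property table used to triage the series:

===========  =============================================================
clogp        calculated octanol/water partition (Wildman–Crippen atom sums)
psa          topological polar surface area, Å² (Ertl N/O fragment sums)
hbd / hba    H-bond donors / acceptors at pH 7 (microspecies convention)
mw           molecular weight, g/mol
mp           molecular polarizability, Å³ (Miller atomic-hybrid components)
logs         aqueous solubility, log10(mg/mL) (ESOL linear model + MW shift)
mpa          minimal projection area, Å² (3D conformer silhouette search)
pka_basic    pKa of the most basic centre (rule table), ``None`` when no
             basic nitrogen, ``"permanent_cation"`` for quaternary N+
clogd        distribution coefficient at pH 7.4 derived from clogp + pKa
===========  =============================================================

All calculations operate on the parent fragment of a salt (counterions
stripped, formal charges preserved).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

from .chem import MoleculeGraph, parse_structure

__all__ = [
    "Conformer3D",
    "DescriptorPanel",
    "PERMANENT_CATION",
    "VDW_RADII",
    "build_panel",
    "compute_clogd",
    "compute_clogp",
    "compute_logs",
    "compute_mpa",
    "compute_polarizability",
    "compute_tpsa",
    "count_hbd_hba",
    "estimate_pka_basic",
    "generate_conformer",
    "projection_area",
]

PERMANENT_CATION = "permanent_cation"


@dataclass
class DescriptorPanel:
    clogp: float
    psa: float
    hbd: int
    hba: int
    mw: float
    mp: float
    logs: float
    mpa: float
    pka_basic: float | str | None
    clogd: float
    id: str | None = None

    def as_dict(self) -> dict:
        return {
            "id": self.id, "clogp": self.clogp, "psa": self.psa,
            "hbd": self.hbd, "hba": self.hba, "mw": self.mw, "mp": self.mp,
            "logs": self.logs, "mpa": self.mpa,
            "pka_basic": self.pka_basic, "clogd": self.clogd,
        }


# --------------------------------------------------------------------------
# topological polar surface area — Ertl, Rohde & Selzer fragment scheme
# --------------------------------------------------------------------------
# Each key: (element, aromatic, total_H, formal_charge, n_single, n_double,
# n_triple, in_3_ring).  Aromatic entries use the pattern key instead (below).
# Contributions in Å²; the scheme covers N and O environments only, so pure
# hydrocarbons score 0 and uncovered atoms contribute 0 with a warning.

_TPSA_N = {
    # neutral, non-aromatic
    ("N", 0, 0, (3, 0, 0), False): 3.24,   # N(-*)(-*)-*
    ("N", 0, 0, (1, 1, 0), False): 12.36,  # N(-*)=*
    ("N", 0, 0, (0, 0, 1), False): 23.79,  # N#*
    ("N", 0, 0, (1, 2, 0), False): 11.68,  # N(-*)(=*)=*  (pentavalent nitro)
    ("N", 0, 0, (0, 1, 1), False): 13.60,  # N(=*)#*
    ("N", 0, 0, (3, 0, 0), True): 3.01,    # three-membered-ring N
    ("N", 1, 0, (2, 0, 0), False): 12.03,  # NH(-*)-*
    ("N", 1, 0, (2, 0, 0), True): 21.94,   # three-membered-ring NH
    ("N", 1, 0, (0, 1, 0), False): 23.85,  # NH=*
    ("N", 2, 0, (1, 0, 0), False): 26.02,  # NH2-*
    # cationic, non-aromatic
    ("N", 0, 1, (4, 0, 0), False): 0.00,   # quaternary N+
    ("N", 0, 1, (2, 1, 0), False): 3.01,
    ("N", 0, 1, (1, 0, 1), False): 4.36,
    ("N", 1, 1, (3, 0, 0), False): 4.44,
    ("N", 1, 1, (1, 1, 0), False): 13.97,
    ("N", 2, 1, (2, 0, 0), False): 16.61,
    ("N", 2, 1, (0, 1, 0), False): 25.59,
    ("N", 3, 1, (1, 0, 0), False): 27.64,
}

_TPSA_O = {
    ("O", 0, 0, (2, 0, 0), False): 9.23,   # ether / ester O
    ("O", 0, 0, (2, 0, 0), True): 12.53,   # three-membered-ring O
    ("O", 0, 0, (0, 1, 0), False): 17.07,  # carbonyl O
    ("O", 1, 0, (1, 0, 0), False): 20.23,  # hydroxyl
    ("O", 0, -1, (1, 0, 0), False): 23.06, # oxide anion
}

# aromatic entries keyed on (H count, charge, n ring-aromatic neighbours,
# has exocyclic single bond, has exocyclic double bond)
_TPSA_N_AROM = {
    (0, 0, 2, False, False): 12.89,  # pyridine-type :n:
    (0, 0, 3, False, False): 4.41,   # fused :n(:*):
    (0, 0, 2, True, False): 4.93,    # substituted n(-*)
    (0, 0, 2, False, True): 8.39,    # n with exocyclic double bond
    (1, 0, 2, False, False): 15.79,  # pyrrole-type [nH]
    (0, 1, 3, False, False): 4.10,
    (0, 1, 2, True, False): 3.88,
    (1, 1, 2, False, False): 14.14,
}
_TPSA_O_AROM = 13.14  # aromatic :o:


def _tpsa_atom_contribution(atom: Chem.Atom) -> float | None:
    sym = atom.GetSymbol()
    if sym not in ("N", "O"):
        return 0.0  # scheme covers N/O; other elements contribute nothing
    h = atom.GetTotalNumHs()
    q = atom.GetFormalCharge()
    if atom.GetIsAromatic():
        if sym == "O":
            return _TPSA_O_AROM if (h, q) == (0, 0) else None
        n_arom = sum(1 for b in atom.GetBonds() if b.GetIsAromatic())
        single = any(
            not b.GetIsAromatic() and b.GetBondType() == Chem.BondType.SINGLE
            for b in atom.GetBonds()
        )
        double = any(
            not b.GetIsAromatic() and b.GetBondType() == Chem.BondType.DOUBLE
            for b in atom.GetBonds()
        )
        return _TPSA_N_AROM.get((h, q, n_arom, single, double))
    counts = [0, 0, 0]
    for b in atom.GetBonds():
        order = b.GetBondTypeAsDouble()
        if order == 1.0:
            counts[0] += 1
        elif order == 2.0:
            counts[1] += 1
        elif order == 3.0:
            counts[2] += 1
    table = _TPSA_N if sym == "N" else _TPSA_O
    key = (sym, h, q, tuple(counts), atom.IsInRingSize(3))
    return table.get(key)


def compute_tpsa(mol: MoleculeGraph | Chem.Mol) -> float:
    """Topological polar surface area (Å²) from N/O fragment contributions.

    Additive over atoms (hence over disconnected fragments) and invariant
    to atom ordering.  N or O environments missing from the published table
    contribute 0 and emit a warning.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeGraph) else mol
    total = 0.0
    for atom in rdmol.GetAtoms():
        contrib = _tpsa_atom_contribution(atom)
        if contrib is None:
            warnings.warn(
                f"no TPSA fragment for atom {atom.GetIdx()} "
                f"({atom.GetSymbol()}); contributing 0",
                stacklevel=2,
            )
            contrib = 0.0
        total += contrib
    return total


# --------------------------------------------------------------------------
# calculated logP
# --------------------------------------------------------------------------

def compute_clogp(mol: MoleculeGraph | Chem.Mol) -> float:
    """Octanol/water partition estimate by Wildman–Crippen atom contributions
    (e.g. methane 0.6361 = one aliphatic C plus four H-on-C terms)."""
    rdmol = mol.mol if isinstance(mol, MoleculeGraph) else mol
    return Crippen.MolLogP(rdmol)


# --------------------------------------------------------------------------
# H-bond donors / acceptors at pH 7
# --------------------------------------------------------------------------

_AMIDE_N = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")
_SULFONAMIDE_N = Chem.MolFromSmarts("[NX3][SX4](=O)=O")


def _is_amide_like(atom: Chem.Atom, rdmol: Chem.Mol) -> bool:
    idx = atom.GetIdx()
    for patt in (_AMIDE_N, _SULFONAMIDE_N):
        for match in rdmol.GetSubstructMatches(patt):
            if match[0] == idx:
                return True
    return False


def _pyrrole_type(atom: Chem.Atom) -> bool:
    # aromatic N whose lone pair is part of the ring pi system
    if not atom.GetIsAromatic() or atom.GetSymbol() != "N":
        return False
    return atom.GetTotalNumHs() > 0 or atom.GetDegree() == 3


def count_hbd_hba(
    mol: MoleculeGraph | Chem.Mol,
    pH: float = 7.0,
    pka_basic: float | str | None = "auto",
) -> tuple[int, int]:
    """Donor / acceptor counts on the pH-adjusted microspecies.

    HBD counts N–H and O–H hydrogens; HBA counts N and O atoms with an
    available lone pair, excluding amide/sulfonamide N, pyrrole-type
    aromatic N and positively charged N.  A basic centre whose rule-table
    pKa exceeds ``pH`` is taken as protonated: one extra donor hydrogen,
    and that nitrogen no longer accepts.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeGraph) else mol
    if pka_basic == "auto":
        pka_basic = estimate_pka_basic(rdmol)
    hbd = 0
    hba = 0
    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        hbd += atom.GetTotalNumHs()
        if sym == "O":
            if atom.GetFormalCharge() <= 0:
                hba += 1
        else:
            if (
                atom.GetFormalCharge() <= 0
                and not _is_amide_like(atom, rdmol)
                and not _pyrrole_type(atom)
            ):
                hba += 1
    if isinstance(pka_basic, (int, float)) and pka_basic > pH:
        basic = _most_basic_atom(rdmol)
        if basic is not None and basic.GetFormalCharge() == 0:
            hbd += 1  # protonation adds one N-H
            hba -= 1  # the protonated N no longer accepts
    return hbd, hba


# --------------------------------------------------------------------------
# molecular polarizability — Miller atomic-hybrid components (ahc), Å³
# --------------------------------------------------------------------------

_AHC = {
    "H": 0.387,
    ("C", "sp3"): 1.061, ("C", "sp2"): 1.352, ("C", "sp"): 1.283,
    ("C", "ar"): 1.352, ("C", "ar_fused"): 1.896,
    ("N", "sp3"): 0.964, ("N", "sp2"): 1.030, ("N", "sp"): 0.956,
    ("N", "ar"): 1.030, ("N", "ar_pyrrole"): 1.090,
    ("O", "sp3"): 0.637, ("O", "sp2"): 0.569, ("O", "ar"): 0.274,
    ("S", "sp3"): 3.000, ("S", "sp2"): 3.729, ("S", "ar"): 2.700,
    ("P", "sp3"): 1.538,
    "F": 0.296, "Cl": 2.315, "Br": 3.013, "I": 5.415,
}

_ELEMENT_FALLBACK = {"C": 1.061, "N": 0.964, "O": 0.637, "S": 3.000, "P": 1.538}


def _hybrid_key(atom: Chem.Atom):
    sym = atom.GetSymbol()
    if sym in ("H", "F", "Cl", "Br", "I"):
        return sym
    if atom.GetIsAromatic():
        if sym == "C":
            n_arom_rings = sum(
                1 for ring in atom.GetOwningMol().GetRingInfo().AtomRings()
                if atom.GetIdx() in ring
            )
            return ("C", "ar_fused") if n_arom_rings > 1 else ("C", "ar")
        if sym == "N":
            return ("N", "ar_pyrrole") if _pyrrole_type(atom) else ("N", "ar")
        return (sym, "ar")
    orders = [b.GetBondTypeAsDouble() for b in atom.GetBonds()]
    if 3.0 in orders:
        hyb = "sp"
    elif 2.0 in orders:
        hyb = "sp2"
    else:
        hyb = "sp3"
    return (sym, hyb)


def compute_polarizability(mol: MoleculeGraph | Chem.Mol) -> float:
    """Additive molecular polarizability (Å³) over atomic-hybrid components;
    e.g. CH4 = 1.061 + 4 x 0.387 = 2.609.  Strictly additive, so any fixed
    structural increment (one CH2) shifts the value by a constant."""
    rdmol = mol.mol if isinstance(mol, MoleculeGraph) else mol
    total = 0.0
    for atom in rdmol.GetAtoms():
        key = _hybrid_key(atom)
        contrib = _AHC.get(key)
        if contrib is None:
            contrib = _ELEMENT_FALLBACK.get(atom.GetSymbol())
            if contrib is None:
                warnings.warn(
                    f"no polarizability component for {atom.GetSymbol()}; "
                    "contributing 0", stacklevel=2,
                )
                contrib = 0.0
            else:
                warnings.warn(
                    f"element-level polarizability fallback for "
                    f"{atom.GetSymbol()}", stacklevel=2,
                )
        total += contrib
        total += atom.GetTotalNumHs() * _AHC["H"]
    return total


# --------------------------------------------------------------------------
# aqueous solubility — ESOL linear model
# --------------------------------------------------------------------------

def compute_logs(
    clogp: float,
    mw: float,
    rotatable_bonds: int,
    aromatic_proportion: float,
) -> float:
    """Estimated solubility as log10(mg/mL).

    The linear model predicts log10(mol/L):
    0.16 − 0.63·clogP − 0.0062·MW + 0.066·RB − 0.74·AP; adding log10(MW)
    converts to the mg/mL scale the panel reports.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    log_mol_per_l = (
        0.16 - 0.63 * clogp - 0.0062 * mw
        + 0.066 * rotatable_bonds - 0.74 * aromatic_proportion
    )
    return log_mol_per_l + math.log10(mw)


def _logs_inputs(rdmol: Chem.Mol) -> tuple[float, int, float]:
    mw = Descriptors.MolWt(rdmol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(rdmol)
    heavy = rdmol.GetNumHeavyAtoms()
    arom = sum(1 for a in rdmol.GetAtoms() if a.GetIsAromatic())
    return mw, rb, (arom / heavy if heavy else 0.0)


# --------------------------------------------------------------------------
# basic pKa — functional-group rule table
# --------------------------------------------------------------------------
# No open per-molecule pKa engine is assumed; a configurable lookup covers
# the basic centres that occur in the series.  Patterns are ordered from
# specific to generic; the first match assigns the atom's pKa and the
# molecule reports its most basic centre.

PKA_RULES: list[tuple[str, float]] = [
    # acylated piperazine: the distal N of an amide-substituted piperazine
    ("[NX3;H0,H1;$(N1CCN(C(=O)*)CC1)]", 7.8),
    ("[NX4+;H1;$(N1CCN(C(=O)*)CC1)]", 7.8),      # same centre, protonated
    # N,N-diethylaminoethyl amide side chain
    ("[NX3;H0;$(N(CC)(CC)CCNC(=O)*)]", 9.5),
    # anilines
    ("[NX3;H1,H2;$(N[c])]", 4.6),
    # generic aliphatic amines (amide/sulfonamide N never matches: no C=O/S=O
    # neighbour allowed)
    ("[NX3;H0;!$(N[C,S]=O);!$(N[c]);!$(N~[!#6])]", 9.8),   # tertiary
    ("[NX3;H1;!$(N[C,S]=O);!$(N[c]);!$(N~[!#6])]", 10.8),  # secondary
    ("[NX3;H2;!$(N[C,S]=O);!$(N[c]);!$(N~[!#6])]", 10.6),  # primary
    # protonated aliphatic amines map to their neutral class
    ("[NX4+;H1;!$(N[C,S]=O)]", 9.8),
    ("[NX4+;H2;!$(N[C,S]=O)]", 10.8),
    ("[NX4+;H3;!$(N[C,S]=O)]", 10.6),
]

_QUAT_N = Chem.MolFromSmarts("[NX4+;H0]")
_AROM_QUAT_N = Chem.MolFromSmarts("[n+;H0;$(n(-*)(:*):*)]")
_PKA_PATTERNS = [(Chem.MolFromSmarts(s), pka) for s, pka in PKA_RULES]


def estimate_pka_basic(mol: MoleculeGraph | Chem.Mol) -> float | str | None:
    """pKa of the most basic nitrogen by rule lookup.

    Returns ``None`` when no basic nitrogen exists (amide N is non-basic)
    and the sentinel ``"permanent_cation"`` for quaternary ammonium parents.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeGraph) else mol
    if rdmol.HasSubstructMatch(_QUAT_N) or rdmol.HasSubstructMatch(_AROM_QUAT_N):
        return PERMANENT_CATION
    best: float | None = None
    assigned: set[int] = set()
    for patt, pka in _PKA_PATTERNS:
        if patt is None:
            continue
        for match in rdmol.GetSubstructMatches(patt):
            idx = match[0]
            if idx in assigned:
                continue  # a more specific earlier rule already claimed it
            assigned.add(idx)
            if best is None or pka > best:
                best = pka
    return best


def _most_basic_atom(rdmol: Chem.Mol) -> Chem.Atom | None:
    best_pka, best_idx = None, None
    assigned: set[int] = set()
    for patt, pka in _PKA_PATTERNS:
        for match in rdmol.GetSubstructMatches(patt):
            idx = match[0]
            if idx in assigned:
                continue
            assigned.add(idx)
            if best_pka is None or pka > best_pka:
                best_pka, best_idx = pka, idx
    return None if best_idx is None else rdmol.GetAtomWithIdx(best_idx)


# --------------------------------------------------------------------------
# distribution coefficient
# --------------------------------------------------------------------------

_PERMANENT_CATION_PENALTY = 4.0  # capped logD penalty for fixed charges


def compute_clogd(
    clogp: float,
    pka_basic: float | str | None,
    pH: float = 7.4,
) -> float:
    """logD at ``pH`` for a monobasic centre:
    clogd = clogp − log10(1 + 10^(pKa − pH)); equals clogp with no basic
    centre; permanently charged parents get a capped −4 penalty."""
    if pka_basic is None:
        return clogp
    if pka_basic == PERMANENT_CATION:
        return clogp - _PERMANENT_CATION_PENALTY
    return clogp - math.log10(1.0 + 10.0 ** (float(pka_basic) - pH))


# --------------------------------------------------------------------------
# 3D conformers and minimal projection area
# --------------------------------------------------------------------------

# Bondi van der Waals radii (Å); fixed published element table.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

# single/double/triple covalent radii (Å) for bond-length validation
_COV_R1 = {"H": 0.32, "C": 0.75, "N": 0.71, "O": 0.63, "F": 0.64,
           "P": 1.11, "S": 1.03, "Cl": 0.99, "Br": 1.14, "I": 1.33}
_COV_R2 = {"C": 0.67, "N": 0.60, "O": 0.57, "S": 0.94, "P": 1.02}
_COV_R3 = {"C": 0.60, "N": 0.54, "O": 0.53}


@dataclass
class Conformer3D:
    coords: np.ndarray            # (n_atoms, 3) Cartesian Å, explicit H
    radii: np.ndarray             # per-atom van der Waals radii
    elements: tuple[str, ...]
    seed: int
    bonds: tuple[tuple[int, int, float], ...] = ()

    def validate(self, bond_tol: float = 0.15, clash_factor: float = 0.7) -> None:
        """Check bonded distances against reference lengths and non-bonded
        clashes against scaled vdW sums; raises ``ValueError`` on failure."""
        bonded = set()
        for i, j, order in self.bonds:
            bonded.add((min(i, j), max(i, j)))
            d = float(np.linalg.norm(self.coords[i] - self.coords[j]))
            ref = _reference_bond_length(self.elements[i], self.elements[j], order)
            if abs(d - ref) > bond_tol * ref:
                raise ValueError(
                    f"bond {i}-{j} length {d:.3f} deviates from {ref:.3f}"
                )
        # 1-3 (geminal) pairs are geometry-constrained by bond angles, not
        # van der Waals contact; exclude them along with bonded pairs.
        neighbours: dict[int, set[int]] = {}
        for i, j in bonded:
            neighbours.setdefault(i, set()).add(j)
            neighbours.setdefault(j, set()).add(i)
        n = len(self.coords)
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded:
                    continue
                if neighbours.get(i, set()) & neighbours.get(j, set()):
                    continue  # share a neighbour: 1-3 pair
                if dist[i, j] < clash_factor * (self.radii[i] + self.radii[j]):
                    raise ValueError(f"non-bonded clash between atoms {i} and {j}")


def _reference_bond_length(e1: str, e2: str, order: float) -> float:
    if order >= 3.0:
        r = (_COV_R3.get(e1, _COV_R1[e1]), _COV_R3.get(e2, _COV_R1[e2]))
    elif order >= 2.0:
        r = (_COV_R2.get(e1, _COV_R1[e1]), _COV_R2.get(e2, _COV_R1[e2]))
    elif order > 1.0:  # aromatic: midway between single and double
        r = (
            0.5 * (_COV_R1[e1] + _COV_R2.get(e1, _COV_R1[e1])),
            0.5 * (_COV_R1[e2] + _COV_R2.get(e2, _COV_R1[e2])),
        )
    else:
        r = (_COV_R1[e1], _COV_R1[e2])
    return r[0] + r[1]


def generate_conformer(
    mol: MoleculeGraph | Chem.Mol,
    seed: int,
    max_attempts: int = 5,
) -> Conformer3D:
    """Embed a single 3D conformer (ETKDG + MMFF94 relaxation).

    Deterministic: identical (molecule, seed) gives identical coordinates.
    Raises ``RuntimeError`` when embedding fails after bounded retries.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeGraph) else mol
    if rdmol.GetNumAtoms() > 200:
        raise ValueError("molecule too large for conformer embedding (>200 atoms)")
    molh = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    conf_id = AllChem.EmbedMolecule(molh, params)
    attempt = 1
    while conf_id < 0 and attempt < max_attempts:
        params.randomSeed = (int(seed) + 7919 * attempt) % (2 ** 31 - 1)
        conf_id = AllChem.EmbedMolecule(molh, params)
        attempt += 1
    if conf_id < 0:
        raise RuntimeError("conformer embedding failed after bounded retries")
    try:
        AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
    except Exception:  # pragma: no cover - MMFF missing params; keep raw ETKDG
        pass
    conf = molh.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    elements = tuple(a.GetSymbol() for a in molh.GetAtoms())
    radii = np.array([VDW_RADII.get(e, 1.70) for e in elements])
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in molh.GetBonds()
    )
    return Conformer3D(coords, radii, elements, int(seed), bonds)


def projection_area(
    points2d: np.ndarray,
    radii: np.ndarray,
    spacing: float = 0.1,
) -> float:
    """Area (Å²) of the union of discs on a 2D raster with the given spacing."""
    rmax = float(radii.max())
    xmin, ymin = points2d.min(axis=0) - rmax - spacing
    xmax, ymax = points2d.max(axis=0) + rmax + spacing
    xs = np.arange(xmin, xmax, spacing) + spacing / 2
    ys = np.arange(ymin, ymax, spacing) + spacing / 2
    grid = np.zeros((ys.size, xs.size), dtype=bool)
    for (cx, cy), r in zip(points2d, radii):
        i0 = max(0, int((cx - r - xmin) / spacing) - 1)
        i1 = min(xs.size, int((cx + r - xmin) / spacing) + 2)
        j0 = max(0, int((cy - r - ymin) / spacing) - 1)
        j1 = min(ys.size, int((cy + r - ymin) / spacing) + 2)
        sub_x = xs[i0:i1] - cx
        sub_y = ys[j0:j1] - cy
        mask = (sub_x[None, :] ** 2 + sub_y[:, None] ** 2) <= r * r
        grid[j0:j1, i0:i1] |= mask
    return float(grid.sum()) * spacing * spacing


def _orientation_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _area_along(conf: Conformer3D, direction: np.ndarray, spacing: float) -> float:
    u, v = _orientation_basis(direction)
    pts = np.column_stack((conf.coords @ u, conf.coords @ v))
    return projection_area(pts, conf.radii, spacing)


def _sphere_grid(step_deg: float) -> np.ndarray:
    # hemisphere suffices: projection along d equals projection along -d
    dirs = []
    thetas = np.deg2rad(np.arange(0.0, 90.0 + 1e-9, step_deg))
    for theta in thetas:
        if theta < 1e-12:
            dirs.append((0.0, 0.0, 1.0))
            continue
        n_phi = max(1, int(round(360.0 / step_deg * math.sin(theta))))
        for phi in np.linspace(0.0, np.pi, n_phi, endpoint=False):
            dirs.append(
                (math.sin(theta) * math.cos(phi),
                 math.sin(theta) * math.sin(phi),
                 math.cos(theta))
            )
    return np.array(dirs)


def compute_mpa(
    conf: Conformer3D,
    spacing: float = 0.1,
    coarse_step_deg: float = 10.0,
    refine_levels: int = 2,
) -> float:
    """Minimal projection area (Å²): the smallest silhouette of the van der
    Waals body over viewing directions.

    Orientation search: a coarse grid over the unit hemisphere (default
    10°) followed by local refinement (step halving around the incumbent);
    each silhouette is the union of projected atom discs on a raster with
    grid spacing ≤ 0.1 Å.
    """
    best_dir, best_area = None, math.inf
    for d in _sphere_grid(coarse_step_deg):
        area = _area_along(conf, np.asarray(d), spacing)
        if area < best_area:
            best_area, best_dir = area, np.asarray(d)
    step = coarse_step_deg
    for _ in range(refine_levels):
        step /= 2.0
        u, v = _orientation_basis(best_dir)
        improved = True
        while improved:
            improved = False
            for du in (-1, 0, 1):
                for dv in (-1, 0, 1):
                    if du == 0 and dv == 0:
                        continue
                    cand = best_dir + math.tan(math.radians(step)) * (du * u + dv * v)
                    cand /= np.linalg.norm(cand)
                    area = _area_along(conf, cand, spacing)
                    if area < best_area - 1e-9:
                        best_area, best_dir = area, cand
                        u, v = _orientation_basis(best_dir)
                        improved = True
    return best_area


# --------------------------------------------------------------------------
# panel assembly
# --------------------------------------------------------------------------

def build_panel(
    mol: MoleculeGraph | str,
    seed: int = 7,
    compound_id: str | None = None,
    with_mpa: bool = True,
) -> DescriptorPanel:
    """Compute the full descriptor panel for one structure.

    Accepts a SMILES or a perceived molecule; descriptor work runs on the
    parent fragment.  ``with_mpa=False`` skips the (3D) projection-area
    search and reports ``nan`` — useful when only 2D properties are needed.
    """
    graph = parse_structure(mol) if isinstance(mol, str) else mol
    rdmol = graph.mol
    clogp = compute_clogp(rdmol)
    psa = compute_tpsa(rdmol)
    pka = estimate_pka_basic(rdmol)
    hbd, hba = count_hbd_hba(rdmol, pka_basic=pka)
    mw, rb, ap = _logs_inputs(rdmol)
    logs = compute_logs(clogp, mw, rb, ap)
    mp = compute_polarizability(rdmol)
    if with_mpa:
        mpa = compute_mpa(generate_conformer(rdmol, seed))
    else:
        mpa = float("nan")
    return DescriptorPanel(
        clogp=clogp, psa=psa, hbd=hbd, hba=hba, mw=mw, mp=mp,
        logs=logs, mpa=mpa, pka_basic=pka,
        clogd=compute_clogd(clogp, pka),
        id=compound_id,
    )
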