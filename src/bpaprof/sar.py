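"""Structure–activity analysis for the BPA series.

Joins structural feature flags with cell-viability (CV) data to

* call compounds active/inactive at a reference concentration,
* list region-wise matched pairs (compounds identical in three regions,
  differing in the fourth),
* induce the minimal pharmacophore rule — the feature set present in
  essentially all actives that also enriches activity — using transparent
  necessity / sufficiency statistics rather than a regression (the series
  is small and the flags are correlated),
* fit four-parameter logistic dose–response curves with the asymptotes
  fixed at 100 % (vehicle control) and 0 %, yielding IC50 and Hill slope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from scipy.optimize import least_squares

from .chem import CvRecord, LibraryTable, MoleculeGraph

__all__ = [
    "AMIDE_ORDER",
    "CvMeasurement",
    "DoseResponseFit",
    "PharmacophoreFlags",
    "PharmacophoreRule",
    "RegionComparison",
    "activity_labels",
    "call_activity",
    "fit_dose_response",
    "induce_rule",
    "matched_pairs",
    "substructure_flags",
]

CvMeasurement = CvRecord  # viability observation: (id, μM, mean %, SD)

BINARY_FLAGS = ("carbonyl_linker", "para_chloro", "gem_dimethyl", "permanent_cation")
AMIDE_ORDER = {"ester": 0, "acid": 0, "none": 0, "primary": 1,
               "secondary": 2, "tertiary": 3}


# --------------------------------------------------------------------------
# structural flags
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PharmacophoreFlags:
    carbonyl_linker: bool     # diaryl ketone (benzophenone) linker
    para_chloro: bool         # 4'-Cl on the distal ring
    gem_dimethyl: bool        # two alpha methyls on the acyl carbon
    amide_class: str          # primary | secondary | tertiary | ester | acid | none
    permanent_cation: bool    # quaternary ammonium

    def get(self, name: str) -> bool:
        return getattr(self, name)


_SMARTS = {
    "carbonyl_linker": Chem.MolFromSmarts("[c][CX3](=O)[c]"),
    "para_chloro": Chem.MolFromSmarts("Clc1ccc([!#1])cc1"),
    "gem_dimethyl": Chem.MolFromSmarts("[CX3](=O)[CX4]([CH3])([CH3])O[c]"),
    "monomethyl": Chem.MolFromSmarts("[CX3](=O)[CX4;H1]([CH3])O[c]"),
    "permanent_cation": Chem.MolFromSmarts("[NX4+;H0]"),
    # acyl group classes, preferring the phenoxy-acyl carbonyl
    "scaffold_acyl": Chem.MolFromSmarts("[CX3](=O)[CX4]O[c]"),
    "ester": Chem.MolFromSmarts("[CX3](=O)O[#6]"),
    "acid": Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),
    "acid_anion": Chem.MolFromSmarts("[CX3](=O)[OX1-]"),
    "amide_primary": Chem.MolFromSmarts("[CX3](=O)[NX3;H2]"),
    "amide_secondary": Chem.MolFromSmarts("[CX3](=O)[NX3;H1][#6]"),
    "amide_tertiary": Chem.MolFromSmarts("[CX3](=O)[NX3,NX4+;H0]([#6])[#6]"),
}


def _acyl_class(rdmol: Chem.Mol) -> str:
    """Classify the acyl group, restricted to the phenoxy-acyl carbonyl when
    the scaffold is present so the benzophenone ketone is not mistaken for
    the amide carbonyl."""
    scaffold = rdmol.GetSubstructMatches(_SMARTS["scaffold_acyl"])
    allowed = {m[0] for m in scaffold} if scaffold else None
    for cls in ("amide_tertiary", "amide_secondary", "amide_primary",
                "ester", "acid", "acid_anion"):
        for match in rdmol.GetSubstructMatches(_SMARTS[cls]):
            if allowed is None or match[0] in allowed:
                return cls.replace("amide_", "").replace("acid_anion", "acid")
    return "none"


def substructure_flags(mol: MoleculeGraph | Chem.Mol) -> PharmacophoreFlags:
    """Pattern-match the pharmacophore feature flags on the parent fragment."""
    rdmol = mol.mol if isinstance(mol, MoleculeGraph) else mol
    return PharmacophoreFlags(
        carbonyl_linker=rdmol.HasSubstructMatch(_SMARTS["carbonyl_linker"]),
        para_chloro=rdmol.HasSubstructMatch(_SMARTS["para_chloro"]),
        gem_dimethyl=rdmol.HasSubstructMatch(_SMARTS["gem_dimethyl"]),
        amide_class=_acyl_class(rdmol),
        permanent_cation=rdmol.HasSubstructMatch(_SMARTS["permanent_cation"]),
    )


# --------------------------------------------------------------------------
# activity calls
# --------------------------------------------------------------------------

def call_activity(
    cv: CvMeasurement | Sequence[CvMeasurement],
    threshold: float = 50.0,
    concentration: float = 25.0,
) -> bool:
    """Active iff mean CV <= ``threshold`` % at the reference concentration.

    Accepts a single measurement (which must be at ``concentration``) or a
    compound's measurement list, from which the record at ``concentration``
    is selected; a missing record raises ``ValueError``.
    """
    if isinstance(cv, CvRecord):
        records = [cv]
    else:
        records = list(cv)
    at_conc = [r for r in records if math.isclose(r.concentration, concentration)]
    if not at_conc:
        raise ValueError(f"no CV record at {concentration} uM")
    return at_conc[0].mean_cv <= threshold


def activity_labels(
    lib: LibraryTable,
    threshold: float = 50.0,
    concentration: float = 25.0,
) -> dict[str, bool]:
    """Activity call per compound id, skipping compounds without a record
    at the reference concentration."""
    labels: dict[str, bool] = {}
    for comp in lib.compounds:
        recs = [
            m for m in lib.measurements_for(comp.id)
            if math.isclose(m.concentration, concentration)
        ]
        if recs:
            labels[comp.id] = recs[0].mean_cv <= threshold
    return labels


# --------------------------------------------------------------------------
# matched pairs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionComparison:
    region: str
    id_a: str
    id_b: str
    tag_a: str
    tag_b: str
    delta_cv: float | None            # cv(a) - cv(b), percentage points
    delta_panel: Mapping[str, float] = field(default_factory=dict)


def matched_pairs(
    lib: LibraryTable,
    region: str,
    panels: Mapping[str, Mapping[str, float]] | None = None,
    concentration: float = 25.0,
) -> list[RegionComparison]:
    """All unordered pairs identical in three regions, differing in ``region``.

    Pairs are canonically ordered by lexicographic id (id_a < id_b); deltas
    are a-minus-b.  CV deltas use the record at ``concentration`` when both
    compounds have one; descriptor deltas are included when ``panels`` maps
    ids to descriptor dicts.
    """
    if region not in "ABCD":
        raise ValueError(f"region must be one of A-D, got {region!r}")
    others = [r for r in "ABCD" if r != region]
    cv = {
        m.compound_id: m.mean_cv
        for m in lib.measurements
        if math.isclose(m.concentration, concentration)
    }
    tagged = [c for c in lib.compounds if set("ABCD") <= set(c.region_tags)]
    out: list[RegionComparison] = []
    for c1, c2 in itertools.combinations(sorted(tagged, key=lambda c: c.id), 2):
        if any(c1.region_tags[r] != c2.region_tags[r] for r in others):
            continue
        if c1.region_tags[region] == c2.region_tags[region]:
            continue
        a, b = (c1, c2) if c1.id < c2.id else (c2, c1)
        delta_cv = None
        if a.id in cv and b.id in cv:
            delta_cv = cv[a.id] - cv[b.id]
        delta_panel: dict[str, float] = {}
        if panels and a.id in panels and b.id in panels:
            pa, pb = panels[a.id], panels[b.id]
            for key in pa:
                va, vb = pa[key], pb.get(key)
                if isinstance(va, (int, float)) and isinstance(vb, (int, float)):
                    delta_panel[key] = va - vb
        out.append(
            RegionComparison(
                region=region, id_a=a.id, id_b=b.id,
                tag_a=a.region_tags[region], tag_b=b.region_tags[region],
                delta_cv=delta_cv, delta_panel=delta_panel,
            )
        )
    return out


# --------------------------------------------------------------------------
# pharmacophore rule induction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PharmacophoreRule:
    """Conjunctive structural requirement for activity.

    ``required`` holds binary flags; ``min_amide_class`` is an ordinal
    requirement (tertiary > secondary > primary) or ``None``.
    """

    required: frozenset[str]
    min_amide_class: str | None = None

    def satisfied_by(self, flags: PharmacophoreFlags) -> bool:
        if any(not flags.get(name) for name in self.required):
            return False
        if self.min_amide_class is not None:
            if AMIDE_ORDER.get(flags.amide_class, 0) < AMIDE_ORDER[self.min_amide_class]:
                return False
        return True


def _necessity_sufficiency(
    has_flag: np.ndarray, active: np.ndarray
) -> tuple[float, float]:
    necessity = float(has_flag[active].mean()) if active.any() else 0.0
    p_with = float(active[has_flag].mean()) if has_flag.any() else 0.0
    # no negative examples of the flag: no counter-evidence, gap vs zero
    p_without = float(active[~has_flag].mean()) if (~has_flag).any() else 0.0
    return necessity, p_with - p_without


def induce_rule(
    flags: Sequence[PharmacophoreFlags],
    activity: Sequence[bool],
    necessity_min: float = 0.9,
    min_labelled: int = 10,
) -> PharmacophoreRule:
    """Induce the pharmacophore rule from labelled compounds.

    A binary flag joins the rule when its necessity P(flag | active) is at
    least ``necessity_min`` and its sufficiency gap
    P(active | flag) − P(active | no flag) is positive.  The amide class is
    handled ordinally: the strictest minimum level whose indicator passes
    both criteria is required.  Degenerate labels (all active or all
    inactive) raise ``ValueError``.
    """
    if len(flags) != len(activity):
        raise ValueError("flags and activity must be the same length")
    if len(flags) < min_labelled:
        raise ValueError(f"need at least {min_labelled} labelled compounds")
    active = np.asarray(activity, dtype=bool)
    if active.all() or not active.any():
        raise ValueError("degenerate labels: need both active and inactive compounds")
    required: set[str] = set()
    for name in BINARY_FLAGS:
        has = np.array([f.get(name) for f in flags], dtype=bool)
        necessity, gap = _necessity_sufficiency(has, active)
        if necessity >= necessity_min and gap > 0:
            required.add(name)
    min_amide = None
    for level in ("primary", "secondary", "tertiary"):  # ascending strictness
        has = np.array(
            [AMIDE_ORDER.get(f.amide_class, 0) >= AMIDE_ORDER[level] for f in flags],
            dtype=bool,
        )
        necessity, gap = _necessity_sufficiency(has, active)
        if necessity >= necessity_min and gap > 0:
            min_amide = level
    return PharmacophoreRule(required=frozenset(required), min_amide_class=min_amide)


def rule_statistics(
    flags: Sequence[PharmacophoreFlags], activity: Sequence[bool]
) -> list[dict]:
    """Per-flag necessity / sufficiency table (for reports)."""
    active = np.asarray(activity, dtype=bool)
    rows = []
    candidates: list[tuple[str, np.ndarray]] = [
        (name, np.array([f.get(name) for f in flags], dtype=bool))
        for name in BINARY_FLAGS
    ]
    for level in ("primary", "secondary", "tertiary"):
        candidates.append(
            (f"amide_ge_{level}",
             np.array([AMIDE_ORDER.get(f.amide_class, 0) >= AMIDE_ORDER[level]
                       for f in flags], dtype=bool))
        )
    for name, has in candidates:
        necessity, gap = _necessity_sufficiency(has, active)
        rows.append({"flag": name, "prevalence": float(has.mean()),
                     "necessity": necessity, "sufficiency_gap": gap})
    return rows


# --------------------------------------------------------------------------
# dose-response fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float            # micromolar
    hill: float
    residual_sse: float
    converged: bool


def _logistic(conc: np.ndarray, ic50: float, hill: float,
              top: float, bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def fit_dose_response(
    cvs: Sequence[CvMeasurement],
    top: float = 100.0,
    bottom: float = 0.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit with fixed asymptotes (two free parameters).

    Four points cannot support four free parameters, so the vehicle control
    pins the top at 100 % and the bottom at 0 %.  Multi-start over a
    geometric IC50 grid spanning the tested concentrations crossed with a
    small Hill-slope grid; ``converged`` is False when no start beats a
    flat-line fit (e.g. non-monotone data).
    """
    conc = np.array([m.concentration for m in cvs], dtype=float)
    resp = np.array([m.mean_cv for m in cvs], dtype=float)
    if len(conc) < 4:
        raise ValueError("need at least 4 concentrations for a dose-response fit")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")

    def residuals(params):
        log_ic50, hill = params
        return _logistic(conc, math.exp(log_ic50), hill, top, bottom) - resp

    best = None
    for ic50_0 in np.geomspace(conc.min(), conc.max(), 5):
        for hill_0 in (0.5, 1.0, 1.5, 2.0, 4.0):
            sol = least_squares(
                residuals,
                x0=[math.log(ic50_0), hill_0],
                bounds=([math.log(conc.min()) - 7, 1e-3],
                        [math.log(conc.max()) + 7, 20.0]),
            )
            if best is None or sol.cost < best.cost:
                best = sol
    ic50 = float(math.exp(best.x[0]))
    hill = float(best.x[1])
    sse = float(2.0 * best.cost)
    flat_sse = float(((resp - resp.mean()) ** 2).sum())
    converged = bool(best.success and ic50 > 0 and sse < 0.9 * flat_sse + 1e-12)
    return DoseResponseFit(ic50=ic50, hill=hill, residual_sse=sse, converged=converged)
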