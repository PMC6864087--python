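"""Synthetic compound libraries and viability data with known ground truth.

The generator emulates the four-region BPA design space: a virtual library
is sampled without replacement from the enumeration of a region-option
grid, a planted pharmacophore rule decides which compounds are truly
active, and cell-viability readouts are drawn as

    CV(25 uM) = active_mean                     if the rule is satisfied
              = inactive_mean - partial effects otherwise
    + Gaussian noise, clamped to [0, 110] %

with defaults matching the study conditions the series reports: strong
actives near 5 % of control, inactives around 92 %, and noise of 4
percentage points — the magnitude of the printed +-SD values (1.6-11.4),
with the clamp allowing >100 % control readouts as observed.  Everything
is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    AMIDE_CLASS_BY_D_LABEL,
    Compound,
    CvRecord,
    LibraryTable,
    enumerate_bpa_variants,
)
from .descriptors import PERMANENT_CATION, DescriptorPanel
from .descriptors import compute_clogd
from .sar import PharmacophoreFlags, PharmacophoreRule

__all__ = [
    "DEFAULT_REGION_OPTIONS",
    "SyntheticLibrarySpec",
    "flags_from_tags",
    "generate_descriptor_table",
    "generate_dose_response",
    "generate_virtual_library",
]

# Compact default grid: 2 x 2 x 2 x 8 = 64 variants, half of the D pool
# tertiary amides, so a 60-compound sample carries a handful of true
# actives under the default planted rule.
DEFAULT_REGION_OPTIONS: dict[str, tuple[str, ...]] = {
    "A": ("Cl", "F"),
    "B": ("carbonyl", "methylene"),
    "C": ("gem_dimethyl", "unsubstituted"),
    "D": (
        "N_methyl_N_hydroxyethyl", "NN_dimethyl", "NN_bis_hydroxyethyl",
        "N_methylpiperazine",                      # tertiary
        "N_methyl", "N_hydroxyethyl",              # secondary
        "primary_amide", "isopropyl_ester",
    ),
}

DEFAULT_PLANTED_RULE = PharmacophoreRule(
    required=frozenset({"carbonyl_linker", "para_chloro", "gem_dimethyl"}),
    min_amide_class="tertiary",
)


@dataclass
class SyntheticLibrarySpec:
    regions: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_OPTIONS)
    )
    planted_rule: PharmacophoreRule = DEFAULT_PLANTED_RULE
    cv_active_mean: float = 5.0      # % of control for rule-satisfying compounds
    cv_inactive_mean: float = 92.0   # % of control otherwise
    partial_effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 4.0            # percentage points
    n_compounds: int = 60
    seed: int = 0
    concentration: float = 25.0      # reference dose, micromolar

    def __post_init__(self):
        if not (0.0 <= self.cv_active_mean <= 110.0):
            raise ValueError("cv_active_mean must lie in [0, 110]")
        if not (0.0 <= self.cv_inactive_mean <= 110.0):
            raise ValueError("cv_inactive_mean must lie in [0, 110]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def flags_from_tags(tags: Mapping[str, str]) -> PharmacophoreFlags:
    """Ground-truth feature flags implied by the generating region choices."""
    d_label = tags["D"]
    return PharmacophoreFlags(
        carbonyl_linker=tags["B"] == "carbonyl",
        para_chloro=tags["A"] == "Cl",
        gem_dimethyl=tags["C"] == "gem_dimethyl",
        amide_class=AMIDE_CLASS_BY_D_LABEL.get(d_label, "none"),
        permanent_cation=d_label == "NN_dimethylpiperazinium",
    )


def generate_virtual_library(spec: SyntheticLibrarySpec) -> LibraryTable:
    """Sample a virtual library with planted activity and noisy CV readouts.

    Compounds are drawn without replacement from the full enumeration of
    ``spec.regions`` (sampling the whole grid keeps the region tags exactly
    balanced).  The returned table carries the ground truth: ``true_flags``
    maps compound id to its generating flags and ``planted_rule`` records
    the rule that produced the labels.
    """
    pool = enumerate_bpa_variants(spec.regions, id_prefix="S")
    if spec.n_compounds > len(pool):
        raise ValueError(
            f"n_compounds={spec.n_compounds} exceeds enumeration size {len(pool)}"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(pool), size=spec.n_compounds, replace=False)
    idx.sort()
    compounds: list[Compound] = []
    measurements: list[CvRecord] = []
    true_flags: dict[str, PharmacophoreFlags] = {}
    for i in idx:
        comp = pool[int(i)]
        flags = flags_from_tags(comp.region_tags)
        true_flags[comp.id] = flags
        if spec.planted_rule.satisfied_by(flags):
            mean = spec.cv_active_mean
        else:
            mean = spec.cv_inactive_mean - sum(
                effect for name, effect in spec.partial_effects.items()
                if flags.get(name)
            )
        cv = float(np.clip(mean + rng.normal(0.0, spec.noise_sd), 0.0, 110.0))
        compounds.append(comp)
        measurements.append(
            CvRecord(comp.id, spec.concentration, cv, spec.noise_sd)
        )
    return LibraryTable(
        compounds=compounds,
        measurements=measurements,
        true_flags=true_flags,
        planted_rule=spec.planted_rule,
    )


# --------------------------------------------------------------------------
# descriptor-panel sampler (for score-level property sweeps)
# --------------------------------------------------------------------------

DEFAULT_PANEL_RANGES = {
    "clogp": (-0.5, 5.5),
    "psa": (40.0, 120.0),
    "hbd": (0, 3),
    "hba": (2, 8),
    "mw": (250.0, 500.0),
    "mp": (25.0, 45.0),
    "logs": (-6.0, 1.0),
    "mpa": (35.0, 80.0),
    "pka": (7.0, 10.5),
}

_P_NO_BASIC_CENTRE = 0.3  # chance of sampling a panel without a basic N


def generate_descriptor_table(
    n: int,
    seed: int,
    ranges: Mapping | None = None,
) -> list[DescriptorPanel]:
    """Sample descriptor panels uniformly from the observed property ranges."""
    if n < 1:
        raise ValueError("n must be at least 1")
    r = dict(DEFAULT_PANEL_RANGES)
    if ranges:
        r.update(ranges)
    rng = np.random.default_rng(seed)
    panels: list[DescriptorPanel] = []
    for i in range(n):
        clogp = rng.uniform(*r["clogp"])
        if rng.random() < _P_NO_BASIC_CENTRE:
            pka: float | None = None
        else:
            pka = float(rng.uniform(*r["pka"]))
        panels.append(
            DescriptorPanel(
                clogp=float(clogp),
                psa=float(rng.uniform(*r["psa"])),
                hbd=int(rng.integers(r["hbd"][0], r["hbd"][1] + 1)),
                hba=int(rng.integers(r["hba"][0], r["hba"][1] + 1)),
                mw=float(rng.uniform(*r["mw"])),
                mp=float(rng.uniform(*r["mp"])),
                logs=float(rng.uniform(*r["logs"])),
                mpa=float(rng.uniform(*r["mpa"])),
                pka_basic=pka,
                clogd=compute_clogd(float(clogp), pka),
                id=f"R{i:04d}",
            )
        )
    return panels


# --------------------------------------------------------------------------
# dose-response forward model
# --------------------------------------------------------------------------

def generate_dose_response(
    ic50: float,
    hill: float,
    concentrations: Sequence[float],
    noise_sd: float = 4.0,
    seed: int = 0,
    compound_id: str = "SYN",
    top: float = 100.0,
    bottom: float = 0.0,
) -> list[CvRecord]:
    """Draw noisy viability observations from a 4PL curve (clamped to
    [0, 110] % like the library generator)."""
    rng = np.random.default_rng(seed)
    out = []
    for c in concentrations:
        mean = bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
        cv = float(np.clip(mean + rng.normal(0.0, noise_sd), 0.0, 110.0))
        out.append(CvRecord(compound_id, float(c), cv, noise_sd))
    return out
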