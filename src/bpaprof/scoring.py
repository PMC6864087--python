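"""CNS-penetration scoring and threshold triage.

Two estimators are combined with a set of single-property criteria:

* **CNS-MPO** — a multiparameter-optimization desirability score: six
  properties (clogP, clogD, MW, TPSA, HBD, pKa of the most basic centre)
  are each mapped to [0, 1] by a piecewise-linear desirability transform
  and summed, giving a 0–6 scale; >= 4.0 is the customary CNS drug-likeness
  cut-off.
* **logBB** — the log10 brain/plasma concentration ratio from the linear
  QSAR ``logBB = 0.152*ClogP - 0.0148*PSA + 0.139``; > 0.3 marks compounds
  that readily cross the blood-brain barrier, < -1.0 poor distribution.

Triage additionally applies the series' working criteria: minimal
projection area <= 70 Å², logS >= -4.5, molecular polarizability in the
30–40 Å³ optimum, and clogP inside 2.0–5.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .descriptors import PERMANENT_CATION, DescriptorPanel

__all__ = [
    "BbbAssessment",
    "DesirabilitySpec",
    "MpoScore",
    "TriageResult",
    "DEFAULT_MPO_SPECS",
    "DEFAULT_TRIAGE_THRESHOLDS",
    "apply_triage",
    "classify_bbb",
    "cns_mpo",
    "compute_logbb",
    "desirability",
    "load_thresholds",
    "rank_candidates",
]


# --------------------------------------------------------------------------
# desirability transforms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesirabilitySpec:
    """Piecewise-linear desirability.

    ``monotone_decreasing``: 1 at/below the first breakpoint, 0 at/above
    the second, linear between.  ``hump``: 0 outside the outer breakpoints,
    1 between the inner pair, linear on the shoulders.
    """

    kind: str  # "monotone_decreasing" | "hump"
    breakpoints: tuple[float, ...]

    def __post_init__(self):
        n = {"monotone_decreasing": 2, "hump": 4}.get(self.kind)
        if n is None:
            raise ValueError(f"unknown desirability kind {self.kind!r}")
        if len(self.breakpoints) != n:
            raise ValueError(f"{self.kind} needs {n} breakpoints")
        if any(b1 >= b2 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly ascending")


def desirability(value: float, spec: DesirabilitySpec) -> float:
    if not math.isfinite(value):
        raise ValueError("desirability input must be finite")
    b = spec.breakpoints
    if spec.kind == "monotone_decreasing":
        lo, hi = b
        if value <= lo:
            return 1.0
        if value >= hi:
            return 0.0
        return (hi - value) / (hi - lo)
    a, inner_lo, inner_hi, d = b
    if value <= a or value >= d:
        return 0.0
    if inner_lo <= value <= inner_hi:
        return 1.0
    if value < inner_lo:
        return (value - a) / (inner_lo - a)
    return (d - value) / (d - inner_hi)


# Default component transforms for the published CNS-MPO definition.  The
# source series never prints them, so they live in config and can be
# overridden from YAML.
DEFAULT_MPO_SPECS: dict[str, DesirabilitySpec] = {
    "clogp": DesirabilitySpec("monotone_decreasing", (3.0, 5.0)),
    "clogd": DesirabilitySpec("monotone_decreasing", (2.0, 4.0)),
    "mw": DesirabilitySpec("monotone_decreasing", (360.0, 500.0)),
    "tpsa": DesirabilitySpec("hump", (20.0, 40.0, 90.0, 120.0)),
    "hbd": DesirabilitySpec("monotone_decreasing", (0.5, 3.5)),
    "pka": DesirabilitySpec("monotone_decreasing", (8.0, 10.0)),
}


@dataclass(frozen=True)
class MpoScore:
    components: Mapping[str, float]
    total: float

    def __post_init__(self):
        if not (-1e-9 <= self.total <= 6.0 + 1e-9):
            raise ValueError("MPO total outside [0, 6]")


class MissingDescriptorError(ValueError):
    pass


def cns_mpo(
    panel: DescriptorPanel,
    specs: Mapping[str, DesirabilitySpec] | None = None,
) -> MpoScore:
    """Six-component CNS-MPO desirability sum on the 0–6 scale.

    pKa handling: no basic centre means the pKa criterion cannot be
    violated (component 1); a permanently charged parent gets 0 — such
    compounds behave as worst-case for CNS exposure regardless of pKa.
    Components are summed unweighted, the cited method's standard form.
    """
    specs = dict(DEFAULT_MPO_SPECS) if specs is None else dict(specs)
    values = {
        "clogp": panel.clogp, "clogd": panel.clogd, "mw": panel.mw,
        "tpsa": panel.psa, "hbd": panel.hbd,
    }
    components: dict[str, float] = {}
    for name, value in values.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingDescriptorError(f"missing descriptor: {name}")
        components[name] = desirability(float(value), specs[name])
    pka = panel.pka_basic
    if pka is None:
        components["pka"] = 1.0
    elif pka == PERMANENT_CATION:
        components["pka"] = 0.0
    else:
        components["pka"] = desirability(float(pka), specs["pka"])
    return MpoScore(components=components, total=sum(components.values()))


# --------------------------------------------------------------------------
# logBB
# --------------------------------------------------------------------------

LOGBB_CLOGP_SLOPE = 0.152
LOGBB_PSA_SLOPE = -0.0148
LOGBB_INTERCEPT = 0.139

BBB_READILY_CUTOFF = 0.3
BBB_POOR_CUTOFF = -1.0


@dataclass(frozen=True)
class BbbAssessment:
    logbb: float
    cls: str  # readily_crosses | intermediate | poor


def compute_logbb(clogp: float, psa: float) -> float:
    """Linear blood-brain partition estimate (modified Clark equation)."""
    if not (math.isfinite(clogp) and math.isfinite(psa)):
        raise ValueError("logBB inputs must be finite")
    return LOGBB_CLOGP_SLOPE * clogp + LOGBB_PSA_SLOPE * psa + LOGBB_INTERCEPT


def classify_bbb(logbb: float) -> str:
    if not math.isfinite(logbb):
        raise ValueError("logBB must be finite")
    if logbb > BBB_READILY_CUTOFF:
        return "readily_crosses"
    if logbb < BBB_POOR_CUTOFF:
        return "poor"
    return "intermediate"


def assess_bbb(clogp: float, psa: float) -> BbbAssessment:
    logbb = compute_logbb(clogp, psa)
    return BbbAssessment(logbb=logbb, cls=classify_bbb(logbb))


# --------------------------------------------------------------------------
# triage
# --------------------------------------------------------------------------

DEFAULT_TRIAGE_THRESHOLDS = {
    "mpo_min": 4.0,
    "mpa_max": 70.0,       # larger substrates are less well transported
    "logs_min": -4.5,      # acceptable water solubility
    "mp_range": (30.0, 40.0),
    "clogp_range": (2.0, 5.0),
}


@dataclass(frozen=True)
class TriageResult:
    id: str | None
    mpo_ge_4: bool
    logbb_class: str
    mpa_le_70: bool
    logs_ge_minus4_5: bool
    mp_in_30_40: bool
    clogp_in_2_5: bool
    rank_score: int
    mpo_total: float
    logbb: float

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "mpo_ge_4": self.mpo_ge_4,
            "logbb_readily_crosses": self.logbb_class == "readily_crosses",
            "mpa_le_70": self.mpa_le_70,
            "logs_ge_minus4_5": self.logs_ge_minus4_5,
            "mp_in_30_40": self.mp_in_30_40,
            "clogp_in_2_5": self.clogp_in_2_5,
        }


def apply_triage(
    panel: DescriptorPanel,
    mpo: MpoScore,
    bbb: BbbAssessment,
    thresholds: Mapping | None = None,
) -> TriageResult:
    """Evaluate the per-criterion pass/fail flags for one compound.

    The rank score counts passed criteria; candidate ordering breaks ties
    by MPO total, then logBB (both descending), then id.
    """
    t = dict(DEFAULT_TRIAGE_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    mp_lo, mp_hi = t["mp_range"]
    cp_lo, cp_hi = t["clogp_range"]
    result = TriageResult(
        id=panel.id,
        mpo_ge_4=mpo.total >= t["mpo_min"],
        logbb_class=bbb.cls,
        mpa_le_70=panel.mpa <= t["mpa_max"],
        logs_ge_minus4_5=panel.logs >= t["logs_min"],
        mp_in_30_40=mp_lo <= panel.mp <= mp_hi,
        clogp_in_2_5=cp_lo <= panel.clogp <= cp_hi,
        rank_score=0,
        mpo_total=mpo.total,
        logbb=bbb.logbb,
    )
    score = sum(result.flags.values())
    return TriageResult(**{**result.__dict__, "rank_score": score})


def rank_candidates(results: Sequence[TriageResult]) -> list[TriageResult]:
    """Order triage results best-first (rank score, MPO, logBB, id)."""
    return sorted(
        results,
        key=lambda r: (-r.rank_score, -r.mpo_total, -r.logbb, r.id or ""),
    )


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

def load_thresholds(path) -> tuple[dict[str, DesirabilitySpec], dict]:
    """Read MPO breakpoints and triage cutoffs from a YAML file.

    The file may override any subset; absent keys keep their defaults.
    Expected layout::

        mpo:
          clogp: {kind: monotone_decreasing, breakpoints: [3, 5]}
          tpsa:  {kind: hump, breakpoints: [20, 40, 90, 120]}
        triage:
          mpo_min: 4.0
          mpa_max: 70
          logs_min: -4.5
          mp_range: [30, 40]
          clogp_range: [2, 5]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    specs = dict(DEFAULT_MPO_SPECS)
    for name, entry in (raw.get("mpo") or {}).items():
        specs[name] = DesirabilitySpec(
            kind=entry["kind"], breakpoints=tuple(float(x) for x in entry["breakpoints"])
        )
    thresholds = dict(DEFAULT_TRIAGE_THRESHOLDS)
    for key, value in (raw.get("triage") or {}).items():
        thresholds[key] = tuple(value) if isinstance(value, list) else value
    return specs, thresholds
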