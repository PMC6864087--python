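# Methods

`bpaprof` models the desk stage of a BPA-series anti-glioblastoma
campaign: compute a physicochemical panel for each candidate structure,
score CNS penetrability, triage on working thresholds, and relate
structural features to measured glioblastoma cell viability. This note
records the models, the defaults and why they were chosen, and what the
synthetic benchmarks do and do not demonstrate.

## Structures and salts

Structures enter as SMILES. Multi-fragment inputs are split and the
largest fragment by heavy-atom count becomes the *parent*; counterions
are retained as annotations but excluded from every descriptor. Formal
charges on the parent are preserved: the quaternary piperazinium HR36
is profiled as a cation, which is what makes its scores (zero pKa
desirability, strongly negative logD) reflect its observed behaviour —
a permanently charged, hydrophilic, inactive compound. Protonated amine
salts (HR35) keep their proton on the parent; their basic-centre pKa is
looked up as for the corresponding free base.

The packaged reference library transcribes only compounds whose
structures are unambiguous from the printed synthesis names or from
explicit textual derivations (halogen swap, carbonyl→ether, reduction);
everything known only from figure artwork is excluded and listed in the
file header. Viability entries carry the printed mean ± SD at the stated
micromolar dose; SDs the text omits are left blank rather than invented.

## Descriptor panel

* **ClogP** — Wildman–Crippen atom-contribution logP. This published
  atom-typing scheme reproduces textbook hand sums exactly (methane
  0.6361 = C contribution + 4 H-on-C terms; benzene 6 × 0.2811).
* **TPSA** — Ertl topological polar surface area: a per-atom lookup of
  N/O environment contributions (charge, H count, bond orders,
  aromaticity, three-membered rings), summed. The table is embedded in
  `descriptors.py`; atoms without a tabulated environment contribute 0
  with a warning. The implementation is checked in the test suite
  against an independent fragment-summing oracle, and it reproduces the
  series' printed values (PP1 66.84 Å², HR1 49.77 Å²) exactly.
* **HBD/HBA at pH 7** — a microspecies convention: donors are N–H/O–H
  hydrogens; acceptors are N and O atoms with an available lone pair,
  excluding amide and sulfonamide N, pyrrole-type aromatic N and
  positively charged N. If the molecule's most basic centre has a
  rule-table pKa above the working pH it is treated as protonated: one
  extra donor, that nitrogen removed from the acceptors. Acidic groups
  are *not* deprotonated — the series contains one carboxylic acid and
  the simpler convention keeps the counts interpretable.
* **Molecular polarizability (MP, Å³)** — Miller's additive
  atomic-hybrid components (e.g. CH₄ = 1.061 + 4×0.387 = 2.609 Å³).
  Strict additivity is the point: swapping 4′-Cl for 4′-F changes MP by
  exactly α(Cl) − α(F) = 2.019 Å³, mirroring the qualitative
  halogen-polarizability argument used to rationalize activity
  differences in the series.
* **LogS** — the ESOL linear model in log₁₀(mol/L)
  (0.16 − 0.63·clogP − 0.0062·MW + 0.066·RB − 0.74·AP), shifted by
  +log₁₀(MW) so the panel reports log₁₀(mg/mL), matching the series'
  mg/mL solubility convention. Whether the literature panel's "LogS" is
  the log or the raw value is not documented; the log reading is this
  package's recorded choice.
* **Basic pKa** — no open per-molecule pKa engine is assumed; a small,
  configurable rule table assigns values by functional class (primary /
  secondary / tertiary aliphatic amine 10.6 / 10.8 / 9.8; the
  N,N-diethylaminoethyl-amide side chain 9.5; amide-substituted
  piperazine 7.8; aniline 4.6; amide N non-basic). Quaternary N⁺
  returns the sentinel `permanent_cation`. Specific patterns take
  precedence over generic ones per atom; the molecule reports its most
  basic centre.
* **ClogD at pH 7.4** — closed form for a monobasic centre,
  clogD = clogP − log₁₀(1 + 10^(pKa − pH)); equal to clogP with no basic
  centre. Permanent cations receive a capped −4 penalty: the Henderson–
  Hasselbalch form diverges for a fixed charge, and −4 places such
  compounds firmly in the hydrophilic regime without producing
  unbounded values. ClogD ≤ ClogP always, with equality iff no basic
  centre.
* **Minimal projection area (MPA, Å²)** — the smallest silhouette of
  the van der Waals body over viewing directions. One conformer is
  embedded per molecule (ETKDG, caller-supplied seed, MMFF94
  relaxation; deterministic for a given seed), Bondi radii are
  assigned, and the search minimizes the area of the union of projected
  atom discs: a coarse 10° grid over the unit hemisphere followed by
  two levels of step-halving hill descent around the incumbent
  direction. Each silhouette is rasterized at 0.1 Å; the raster
  resolution bounds the reproducibility of the area at about 2 % under
  rigid rotation, which is the tolerance used in tests (including a
  1000-orientation Monte-Carlo lower-bound oracle). The vendor
  algorithm behind the literature panel is unpublished; only the
  ≤ 70 Å² criterion semantics are reproduced here, so printed MPA
  values are treated as reference-only.

Conformer sanity invariants: bonded distances within 15 % of reference
covalent-radius sums (order-aware), and no non-bonded pair (excluding
geminal 1-3 pairs, whose distance is fixed by bond angles rather than
van der Waals contact) closer than 0.7 × the sum of vdW radii.

## CNS scoring and triage

The CNS-MPO desirability transforms are not printed in the source
series, so the published definition's standard breakpoints are the
defaults — clogP (3, 5), clogD (2, 4), MW (360, 500) monotone; TPSA hump
(20, 40, 90, 120); HBD (0.5, 3.5); pKa (8, 10) — and live in config
(`scoring.load_thresholds`) so alternates can be tested. Components are
summed unweighted (the cited method's standard form). Compounds with no
basic centre score 1.0 on the pKa component (the criterion cannot be
violated); permanent cations score 0.0, consistent with the charged
HR36 being non-penetrant. Because vendor clogD/pKa models differ from
the open ones used here, printed MPO values for individual compounds
are reference-only; the scale endpoints, monotonicity and the worked
cases are what the tests pin down.

Triage flags: MPO ≥ 4.0; BBB class from logBB (> 0.3 readily crosses,
< −1.0 poor); MPA ≤ 70 Å²; LogS ≥ −4.5; MP in the 30–40 Å³ optimum;
ClogP in 2.0–5.0. The rank score counts passed criteria, with ties
broken by MPO total, then logBB (both descending), then id — a
deterministic ordering that exposes candidate selection as a ranked
list rather than asserting any particular final pick, since the
literature's lead set mixes computation with judgment.

Display rounding follows the source precision: logBB to one decimal,
MPO to two.

## SAR

* **Activity calls** — active ⇔ mean CV ≤ 50 % of control at 25 μM
  (boundary inclusive). The 50 % default separates the described
  actives (CV ≈ 0.2–43 %) from inactives (58–98 %). The fixture
  regression test labels *strong* actives at a 30 % cutoff: with only
  seven labelled literature compounds, the weaker fluoro analog HR9
  (CV 35.55 %) otherwise dilutes the necessity statistic for the
  4′-chloro flag that the series' own conclusions single out.
* **Matched pairs** — pairs identical in three region tags and
  differing in the named one; near-pairs are deliberately out of scope.
  Output is canonically ordered (lexicographic ids, a-minus-b deltas).
* **Rule induction** — necessity ≥ 0.9 plus a positive sufficiency gap,
  amide class ordinal. When a flag has no negative examples in the
  labelled set, the gap is computed against 0 (no counter-evidence);
  this matters only for tiny libraries where a flag is universal.
  Degenerate label sets (all active / all inactive) and sets smaller
  than `min_labelled` (default 10) are rejected. This transparent
  counting approach was chosen over a regression because the design
  space is small and the flags are strongly correlated.
* **Dose–response** — two free parameters (IC50, Hill slope) with
  asymptotes fixed at 100/0: four points cannot support four free
  parameters and the vehicle control defines 100 %. Least squares in
  log-IC50 space, multi-started over a 5-point geometric IC50 grid ×
  5 Hill values; `converged` requires the best fit to beat a flat-line
  (mean) model by 10 % in SSE, which flags non-monotone data. The fit
  is scale-equivariant in concentration by construction.

## Synthetic benchmarks

`synth.generate_virtual_library` emulates the four-region design space:
variants are sampled *without replacement* from the enumeration of a
region grid, a planted rule (default: carbonyl linker + 4′-Cl +
gem-dimethyl + tertiary amide) decides true activity, and CV(25 μM) is
drawn at 5 % (active) or 92 % (inactive, minus any configured partial
effects) plus Gaussian noise of SD 4 percentage points, clamped to
[0, 110] %. The noise magnitude matches the printed ±SD range of the
assay (≈ 1.6–11.4 points), and the clamp allows the >100 % control
readouts that real MTT data shows. The default grid (2×2×2×8 = 64
variants, half of the amide pool tertiary) keeps a 60-compound sample
carrying a handful of true actives, the regime the series itself
operates in.

What passing these benchmarks shows: the induction machinery recovers a
conjunctive structural rule from realistic-noise viability data and
does not hallucinate it under label permutation; the 4PL fitter
recovers IC50 within 15 % at assay-scale noise. What it does not show:
anything about biological mechanism, about descriptor–activity
causality in real cells, or about rule recovery when activity is
graded rather than near-binary — real series have partial effects,
which the generator only models as fixed CV offsets.

## Problem sizes

The shipped tests and the acceptance script run the stages at the sizes
the analyses themselves need: 60-compound synthetic libraries over 10
seeds for rule recovery, 1000 random panels for the MPO sweep, 10
conformers × 1000 Monte-Carlo orientations for the MPA oracle, and
≤ 500-compound enumeration grids. These are the package's benchmark
sizes; all scale linearly if enlarged.

## Known limitations

* Printed vendor panel values (ClogP, LogS, MPA, pKa, MPO of specific
  compounds) are not bit-reproducible by open schemes and are treated
  as reference-only; the scheme-independent quantities (TPSA, the logBB
  arithmetic, scale endpoints) are reproduced exactly.
* Single-conformer MPA underestimates flexible molecules' effective
  size spread; no conformational ensemble is attempted.
* The pKa table covers the functional classes present in the series;
  exotic basic centres fall back to generic amine classes or to "no
  basic centre".
* Electrostatic-potential surface comparisons (a quantum-chemistry
  exercise in the source work) are out of scope.
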