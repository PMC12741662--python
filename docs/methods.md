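# Methods

## Scientific setting

In angiosperm xylem, water moves through vessels — multicellular pipes a
few centimetres long — and must cross inter-vessel pit membranes at every
vessel end wall. Whether a tree can grow taller without paying an ever
larger hydraulic price depends on how three anatomical dimensions scale
from the branch tips to the stem base: vessel diameter *D*, mean vessel
length *L<sub>V</sub>*, and the total inter-vessel pit membrane area per
vessel *A<sub>P</sub>*. This package implements the complete analysis chain
for one intensively sampled sapling: 58 stem/branch segments, each with a
pneumatic vessel-length measurement, several hundred measured vessel
lumina, and a handful of SEM pit-field measurements.

## Models and formulas

**Vessel length from pneumatic trimming.** Cutting a segment progressively
shorter opens more vessels to the measuring reservoir, so gas conductivity
rises exponentially as the remaining length *x* falls. With decay rate
λ<sub>v</sub> < 0 the vessel length density is
P(x) = x·λ<sub>v</sub>²·exp(λ<sub>v</sub>·x), normalised on [0, ∞) with
mean L<sub>V</sub> = −2/λ<sub>v</sub>. λ<sub>v</sub> is fitted as the OLS
slope of ln(conductivity) against *x* — the only reading consistent with
the exponential form — with a raw nonlinear exponential fit available
behind a flag (`fit_lambda(..., log_fit=False)`). Points are unweighted.
Segments whose conductivity at full length exceeds 10% (configurable) of
the fully-trimmed value trigger an open-vessel warning but are not
corrected: a short-skewed length distribution makes a few open vessels
harmless.

**Anatomy.** D = √(4A/π) per lumen; per-segment mean D is the arithmetic
mean of per-vessel equivalent diameters (the plain reading of a reported
"mean vessel diameter", not the diameter of the mean area). The contact
fraction F<sub>C</sub> = ΣL<sub>VW</sub>/ΣP<sub>V</sub> pools all pit
fields of a segment; the pit-field fraction F<sub>PF</sub> is their
unweighted mean; F<sub>P</sub> = F<sub>C</sub>·F<sub>PF</sub>; and
A<sub>P</sub> = F<sub>C</sub>·F<sub>P</sub>·D·L<sub>V</sub>. Note that
this product applies F<sub>C</sub> twice (once inside F<sub>P</sub>) and
contains no π factor; it is implemented as the field defines it, with a
cylinder-lateral-surface variant (π·D·L<sub>V</sub>·F<sub>P</sub>) behind
`surface_variant=True` for sensitivity analysis.

**Hydraulics.** Per segment, in strict SI:

    K_H = π·D⁴ / (128·μ·L_V)            lumen (Hagen–Poiseuille)
    K_W = k·A_P / (μ·T_PM)              end wall (Darcy)
    ΔP  = μ·T_PM·Q / (k·A_P) = Q/K_W    safety proxy at fixed flux

Defaults: μ = 0.001002 Pa·s (water, 20 °C), T<sub>PM</sub> = 234 nm,
Q = 5×10⁻¹³ m³ s⁻¹, k = 1×10⁻¹³ m², all overridable in config.
Resistivities are reciprocals. ΔP·K<sub>W</sub> = Q is an exact algebraic
identity and is enforced by test.

**A deliberate strict-SI stance on k.** With every quantity in SI, the
literature default k = 10⁻¹³ m² places K<sub>W</sub> roughly five orders
of magnitude above K<sub>H</sub> for realistic anatomies (A<sub>P</sub>
~10⁻⁸ m², D ~22 µm, L<sub>V</sub> ~6 cm); a k near 10⁻¹⁸ m² is what
actually balances the two. This magnitude tension is inherent to the
formula set when A<sub>P</sub> is carried in m² rather than mm², and the
package does not silently patch it: all computation is strict SI, k is
treated as the one calibratable parameter, and the calibration module
reports the full RMSD-vs-k profile so any unit convention can be audited.

**Calibration.** Since K<sub>W</sub> ∝ k and K<sub>H</sub> is independent
of it, varying k rigidly shifts log₁₀K<sub>W</sub>. The calibration scans
a log-spaced grid (default 10⁻¹⁷–10⁻¹¹ m², 61 points; any grid can be
passed) and minimises RMSD = √mean((log₁₀K<sub>H</sub> −
log₁₀K<sub>W</sub>)²), the vertical deviation from the 1:1 line in log₁₀
space. The objective is convex in log₁₀k, so a grid locates the optimum to
grid resolution; ties break to the smaller k. T<sub>PM</sub> and k are not
jointly calibrated — only k/T<sub>PM</sub> enters K<sub>W</sub>.

**Scaling statistics.** Theil–Sen slope = median of all pairwise slopes
(equal-x pairs skipped); intercept = median(y − slope·x); the 95% CI is
read from the 2.5th/97.5th percentiles of the raw pairwise-slope
distribution — deliberately not the rank-based Sen interval, because the
percentile definition is the one this analysis chain specifies. Kendall's
τ-b (scipy; exact enumeration for n ≤ 10 without ties, normal
approximation otherwise) measures monotonicity. Scaling exponents come
from OLS on log₁₀-transformed data (base 10 throughout, matching the RMSD
units). The piecewise fit is a continuous one-breakpoint hinge
y = β₀ + β₁x + β₂(x−c)₊, minimised over candidate breakpoints at midpoints
between consecutive distinct x (≥ 3 distinct x required on each side),
refined by bounded scalar minimisation between the neighbouring
candidates; ties go to the smallest breakpoint, and a pure line
degenerates to equal slopes with the breakpoint at the first candidate.
Residual diagnostics: Lilliefors statistic (KS distance to a normal with
estimated moments) with a seeded Monte-Carlo p (default 10 000 null
replicates; no usable closed form), Breusch–Pagan LM with χ²(1) p for the
single regressor (0 by definition when squared residuals are constant),
and Durbin–Watson Σ(Δe)²/Σe².

**Length–diameter class matching.** Individual vessel lengths are not
measurable here, so sorted vessel diameters are mapped to a monotone
ladder of length classes: class bounds evenly spaced on
[L<sub>V</sub>/3, 3·L<sub>V</sub>] (mean and maximum length assumed
linearly related), ⌈n/10⌉ classes of 10 vessels, smallest diameters to the
shortest class, empty classes omitted. Rank-block matching is the
deterministic reading of "sorted by diameter + wide implies long"; whether
the original procedure compared normalised magnitudes instead of ranks is
not decidable from its description, and the choice is documented here
rather than hidden.

## Synthetic sapling generator

The generator emulates the study conditions: one 2.75 m main stem (8
segments) plus 20 lateral branches (14 first-order, 6 second-order,
segment counts 2–8 adjusted to a 58-segment total), 333–1000 vessels per
segment, 3–5 pit fields of 10 vessels each, and a 10-point pneumatic
series per segment. Ground truth per segment:

* widening D(d) = tip_diameter·(1 + d/d₀)^b with b = 0.2, d₀ = 0.01 m
  (a softened power-law origin keeping tip diameters finite; distance d is
  measured to the tip of the segment's own branch);
* lengthening L<sub>V</sub> = a·D with a = 2530;
* tip_diameter = 10.5 µm — with the tree geometry above this puts the
  whole-tree means near 22 µm and 5.6 cm, the regime of a young beech;
* F<sub>C</sub> = 0.20 ± 0.02 with a weak (+10% tip→base) trend,
  F<sub>PF</sub> = 0.50 ± 0.05 with a −5% trend.

Noise is multiplicative lognormal with mean 1 (diameters CV 0.3 within a
segment, conductivities CV 0.05), guaranteeing positivity; fractions get
truncated Gaussian noise. All randomness flows through a single
`numpy.random.default_rng(seed)`, so a tree is a pure function of its
parameters. Setting all CVs/SDs to zero makes every stage exactly
invertible, which is the basis of the recovery tests.

A planted-identity mode (`planted_params(k0)`) instead chooses
per-segment contact fractions solving k₀·F<sub>C</sub>²·F<sub>PF</sub>·
D·L<sub>V</sub>/T<sub>PM</sub> = πD⁴/(128·L<sub>V</sub>), so that
K<sub>W</sub> = K<sub>H</sub> exactly at a known permeability. The default
k₀ = 10⁻¹⁸ m² puts the required contact fractions in the realistic
0.1–0.3 range. This dataset is the ground truth for the calibration tests:
the grid search must return k₀ with RMSD → 0 and all ratios 1.

What the generator does *not* emulate: spatial correlation of vessel
diameters within a section, the gas-diffusion kinetics inside the
pneumatic device (only the exponential signal the analysis consumes),
open-vessel truncation artefacts, ring-boundary effects, or measurement
error in the perimeter sums. Passing tests therefore demonstrate that the
analysis chain is a correct inverse of its own model assumptions at
realistic magnitudes — not that those assumptions hold in real wood.

## Numerical and design choices

* Strict SI internally; input CSVs may declare other units via column-name
  suffixes from a fixed registry (e.g. `lumen_area_um2`,
  `remaining_length_cm`), converted on ingest. No unit inference from
  magnitudes.
* Diameter tertiles (small/intermediate/large) split by rank so category
  sizes differ by ≤ 1; ties broken by a stable sort on segment id.
* The pipeline is a pure function of (inputs, config); reruns are
  byte-identical. Degenerate trait pairs (e.g. a constant fraction in a
  noise-free tree) are recorded as skipped fits, not fatal errors.
* Problem sizes in the test-suite simulations (100–500 replicates, 10⁵
  draws for law-of-large-numbers checks, 1000-replicate Monte-Carlo p
  values) were chosen as the smallest sizes at which the checked
  statistical property is stable across seeds.

## Known limitations

* The mean vessel length estimator assumes a single-exponential decay;
  real series with many open vessels or mixed vessel populations will
  bias λ<sub>v</sub> (flagged by warning only).
* End-wall formulas treat T<sub>PM</sub> as axially constant and k as
  global; axial variation in either is absorbed into A<sub>P</sub>.
* The class-matching procedure is constructive, not inferential — it
  visualises the wide-implies-long premise and cannot validate it.
* Hydraulic segmentation at branch junctions is outside the model: no
  series/parallel network composition is attempted.
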