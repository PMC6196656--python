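# Methods

## Response model and normalisation conventions

All concentration–response data are modelled with the four-parameter logistic
(4PL) in log₁₀ agonist concentration: parameters bottom, top (= Emax),
logEC50 (log₁₀ mM) and Hill slope. The sigmoid is defined for strictly
positive concentrations only; 0 mM inputs are rejected at validation, and the
basal condition is represented by 0.1 mM extracellular Ca²⁺ throughout.

Two normalisations mirror plate-assay practice:

- **percent of WT max** — every response divided by the wild type's largest
  per-concentration mean response for that pathway, ×100, so the WT maximum
  statistic maps to exactly 100. Values are deliberately *not* clipped to
  [0, 100]: gain-of-function constructs genuinely exceed the WT maximum, and
  clipping would erase that signal.
- **fold change over basal** — every response divided by its own
  (construct, pathway) mean response at the basal concentration, so that mean
  maps to 1.0.

RA and bias factors are computed from fits on the percent-of-WT scale (the
scale the bias plots use); raw-scale RA is emitted alongside for
transparency, since the choice of scale cancels in the WT-relative factor but
not in RA itself.

## Synthetic assay generator

The generator emulates per-stimulus peak Ca²⁺ᵢ responses and pERK responses
of transiently transfected cells stimulated with 0.1–10 mM Ca²⁺ₑ. Default
concentration grid: {0.1, 0.5, 1, 2, 2.5, 3, 5, 7.5, 10} mM. Replicate noise
is additive, Gaussian and homoscedastic across concentrations — the simplest
model consistent with mean ± SEM reporting; heteroscedastic options were
deliberately deferred. Defaults: 6 biological replicates per construct ×
pathway (within the 4–12 range typical of these assays) and noise SD 4 on the
percent-of-WT-max scale. All randomness flows from one explicit seed per
dataset; there is no global random state, and identical inputs reproduce a
dataset bit for bit.

The wild-type reference uses EC50 = 3.0 mM and Hill slope 2.0 for both
pathways — a realistic midpoint and steepness for cooperative Ca²⁺ₑ
activation of this receptor — with Ca²⁺ᵢ spanning 5→100 response units and
pERK 4→80. Both pathways share the same basal fraction (bottom/top = 5%) so
the WT bias plot overlays the identity line, as the reference construct must.
No supplementary table of measured WT EC50/Emax values was available to
calibrate against, so these are reference values, not empirical calibrations.

Mutant presets realise the observed phenotype classes relative to WT, using
one 2-fold potency step (±log₁₀2) and 0.6–1.3× Emax scalings:
`loss_both`, `gain_both` (concerted shifts in both pathways),
`loss_Ca_only` (right-shifted, blunted Ca²⁺ᵢ; pERK untouched),
`gain_pERK_shift` (pERK potency gain only) and
`uncoupled_gainCa_losspERK` (raised Ca²⁺ᵢ maximum with a reduced pERK
maximum). What the generator does **not** emulate: raw fluorescence
time-courses, receptor-expression differences, heteroscedastic or correlated
replicate error, and bell-shaped ("bimodal") MAPK responses such as those of
some TM6 mutants — passing tests therefore say nothing about those features
of real data, only about the monotone-4PL regime.

## Curve fitting

Fits minimise unweighted least squares over **all replicate points** (no
pre-averaging), which preserves residual degrees of freedom for the F test.
Bounds: bottom ≥ 0, Hill slope in [0.1, 10], logEC50 within ±2 decades of
the observed concentration range, top free. Initialisation is a
deterministic multi-start grid — logEC50 at the observed log-concentration
quartiles (25/50/75%), slope at {0.5, 1, 3}, bottom/top from the data range —
run to tight tolerances (xtol = ftol = gtol = 1e-12) with an analytic
Jacobian; the lowest residual sum of squares wins, exact ties broken toward
the slope nearest 1. Inputs are sorted internally so row order cannot affect
the result. Flat data (zero response variance) raise a degenerate-fit error
rather than returning an arbitrary sigmoid. Emax is defined as the fitted
top, not the largest observed response.

## Statistics

**EC50 F test.** Null model: both constructs share one logEC50 while bottom,
top and slope remain construct-specific (7 parameters); alternative: fully
separate fits (8 parameters). F = ((RSS₀ − RSS₁)/1)/(RSS₁/df₁) with
df₁ = N − 8. Because the null is nested, RSS₀ ≥ RSS₁ up to optimizer
round-off; tiny negative excursions are clamped to zero. Which parameters are
shared under the null is a genuine modelling choice — the test targets "EC50
differs?" specifically, so only logEC50 is shared — and is recorded in the
result object.

**Two-way ANOVA.** Fixed-effects genotype × concentration with interaction,
balanced designs only: unbalanced tables are rejected with an explicit
message rather than silently committing to a Type I/II/III sum-of-squares
convention (for balanced data the three coincide, and the SS decomposition
identity holds to ~1e-9 relative). Tukey comparisons are computed across
genotypes within each concentration — matching how per-concentration
significance is reported for such curves — using the pooled residual mean
square of the full model and studentized-range p-values. α = 0.05
throughout.

## Bias quantification

RA = (Emax_Ca · EC50_pERK)/(EC50_Ca · Emax_pERK); bias factor =
log₁₀(RA_mut/RA_WT), base 10 by the convention of the bias-factor
literature. The WT factor is exactly 0 by construction. Bias plots pair
per-concentration *mean* responses (matching mean ± SEM figures) of the two
pathways on identical grids; classification uses the signed mean deviation
(x − y) against a tolerance of 5 response units (% of WT max) — half-width
of the "unbiased" band, roughly one replicate noise SD.

A pathway is refused an RA (result: `undefined`, with reason) when its fit
did not converge, has top ≤ bottom, or has a fitted dynamic range smaller
than 3× the residual noise level √(RSS/df) — this last rule is what turns an
absent-pERK construct fitted through noise into an explicit "extreme bias,
RA not computable" record instead of a meaningless number.

## Structural measurements

Structures are read with gemmi (PDB and mmCIF); first model only, alternate
locations collapsed to the highest-occupancy conformer, hydrogens ignored
(crystal structures of this resolution lack them). "Side chain" = heavy
atoms excluding N, CA, C, O, OXT. A protomer is a chain; the opposing
protomer is selected explicitly by the caller — no biological-assembly
expansion is attempted. H-bonds use a distance-only donor–acceptor criterion,
default cutoff 3.5 Å; an angle term would over-specify what a distance claim
asserts. Residue numbering follows the file's author numbering, which for the
CaSR ECD entries matches full-length 1078-residue protein numbering.
Conservation scoring maps ungapped reference positions to alignment columns
and reports the fraction of non-reference sequences matching the reference
residue; gaps count as mismatches.

The TMD disease-switch residues (Ser657, Ser820, Thr828) sit in a region with
no deposited experimental structure; claims about their environment depend on
a homology model that is not reproducible here and are out of scope.

## Pipeline

A single declarative YAML config drives end-to-end runs; CLI flags override
config keys. All randomness derives from the config seed (construct *i* of a
preset list gets seed + *i*), so re-running a config reproduces every table
bit for bit, and the provenance block written with each report is sufficient
to re-run it. Partial failures (a degenerate pathway, an unbalanced ANOVA)
are recorded per construct in a failures table without aborting the run;
every input construct appears in the bias table exactly once, as a number or
as an explicit undefined record. Outputs are flat CSVs plus a plain-text log.

## Problem sizes and numerical tolerances

Zero-noise parameter recovery is checked over 20 generating parameter sets
(9-point grid, tolerance 1e-4 relative; achieved ~1e-12). Noisy EC50
recovery uses 200 simulations (SD 5, n = 6); F-test null calibration uses
1000 simulated dataset pairs (rejection rate vs α = 0.05 and
Kolmogorov–Smirnov distance of p-values from uniform); ANOVA agreement with
a from-definition computation is checked to 1e-8 relative on balanced
3 × 4 × 4 tables. These sizes give stable estimates while keeping a full run
of the test suite and acceptance script in the low minutes on one CPU.

Under the default study conditions (WT EC50 3.0 mM, slope 2.0, SD-5 noise,
n = 6 on the 9-point grid), the Cramér–Rao bound for SE(logEC50) is ≈0.025,
which caps the achievable "EC50 within 10% of truth" rate at ≈92%; the
fitter attains that bound empirically. This is an identifiability property of
the design (EC50 near the top of the concentration range), not an optimizer
limitation; designs with lower EC50 or steeper slope recover EC50 within 10%
in >95% of runs.

## Known limitations

- Monotone 4PL only; biphasic/bell-shaped MAPK responses are not modelled.
- Unweighted least squares assumes homoscedastic replicate noise.
- No operational-model (τ/K_A) bias metrics and no bootstrap confidence
  intervals on the bias factor.
- ANOVA is restricted to balanced designs by design.
- The bias-plot classification tolerance is a convention (5% of WT max), not
  an inferential threshold.
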