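# Methods

This note documents the models and estimators implemented in `serflux`, the
assumptions behind them, the choices made where the design was open, and
what the synthetic fixtures do and do not establish about real data.

## Constraint-based modelling

**Model.** A metabolic network is a stoichiometric matrix *S* (metabolites ×
reactions), flux bounds *lb ≤ v ≤ ub* in mmol·gDW⁻¹·h⁻¹, boolean GPR rules
per reaction, and one biomass objective reaction. Exchange reactions are
single-metabolite boundary reactions with the standard sign convention:
negative flux is uptake, positive is secretion; every user-facing uptake
value is a nonnegative magnitude converted internally. Gene deletions act
purely boolean: a reaction whose GPR evaluates false has both bounds set to
zero. No isozyme flux splitting is attempted — deletions only knock
reactions out, which is all the deletion analyses require.

**FBA/FVA.** FBA maximizes biomass subject to *S·v = 0* and the bounds; FVA
then fixes a floor *v*<sub>biomass</sub> ≥ *f·Z\** (fraction of optimum
*f* = 0.99 by default) and minimizes/maximizes each flux target. Targets may
be linear combinations (net serine production of a reaction set, weighted by
each reaction's net serine stoichiometry so positive = production); the
combination is optimized directly as one LP objective, never assembled from
per-reaction envelopes, which would ignore flux correlations. All LPs are
solved with HiGHS through `scipy.optimize.linprog` at 1e-9
feasibility/optimality tolerances; envelope comparisons in tests use 1e-6,
which is where double-precision LP noise lives. Only envelope bounds are
contractual — flux vectors attaining them are arbitrary alternate optima, so
no tie-breaking is needed. Targets hitting the conventional big bound
(±1000) are flagged `unbounded` rather than reported as infinities.

**Uptake scans.** The scan fixes the scanned exchange at each grid value
(`mode="fixed"`; `mode="max"` bounds it instead — both provided because
either reading of "at varying uptake rates" is defensible), then
*re-optimizes biomass at that point* and applies the fraction-of-optimum to
the per-point optimum. Applying a global floor instead would make low-uptake
points spuriously infeasible. Infeasible grid points yield envelopes flagged
invalid and the scan continues.

**Verification.** On networks with ≤ 8 reactions and all-finite bounds the
feasible region is a bounded polytope, and every LP optimum sits on a
vertex. `serflux.oracle` enumerates all vertices by exhausting active-set
candidates (the steady-state rows plus enough bound/floor rows to reach full
rank) and reads envelope bounds off the vertex list — a code path sharing
nothing with the LP solver. The test suite and the acceptance script check
engine-vs-oracle agreement to 1e-6 across hundreds of random feasible
networks (generated with a guaranteed chain "spine" so the optimum is
nonzero by construction).

**Media and genotypes.** Media are named maps exchange-id → maximum uptake
magnitude; applying one sets the listed lower bounds and (optionally) closes
all unlisted uptakes, leaving secretion untouched. The shipped SDC/YPD
presets open glucose at 10 and the 20 amino acids plus 4 nucleobases at
1 mmol·gDW⁻¹·h⁻¹ each — editable YAML, since the per-nutrient constants are
not universal; the preset exchange ids are placeholders to be mapped onto
whatever genome-scale model is loaded. A `sey6210` genotype preset carries
the laboratory-background marker deletions (LEU2, URA3, HIS3, TRP1, LYS2,
SUC2) to be applied before scans on a genome-scale model.

## The serine toy model

A ~12-reaction caricature of the serine economy: glucose uptake (capped at
2 mmol·gDW⁻¹·h⁻¹), serine import (GPR "GNP1 or AGP1"), serine synthesis from
glucose (GPR "SER2", standing in for the whole 3-phosphoglycerate branch), a
reversible serine↔glycine shuttle (GPR "SHM1 or SHM2"; forward = serine
consumption), a protein-synthesis drain, SPT (GPR "LCB1 and LCB2",
serine + palmitoyl-CoA → LCB), glycine overflow secretion, and a biomass
reaction consuming protein, glycine, LCB and bulk carbohydrate. The
carbohydrate demand keeps glucose fully used at optimum, which has two
wanted consequences: (i) the net serine-production envelope (SER2 − SHM)
changes sign along an uptake scan (synthesis obligatory at zero uptake,
excess serine pushed to glycine at high uptake, crossover near
1.4 mmol·gDW⁻¹·h⁻¹); (ii) at high uptake the synthesis branch has almost no
slack under the 99% biomass floor, so the net envelope over {SHM} alone is
nearly identical to the one over {SER2, SHM}. At *zero* uptake the two sets
necessarily differ — SER2 is then the only serine source — which is where
the caricature departs from a genome-scale model with multiple
compartmentalized producers.

## SILAC incorporation

Per peptide (filtered to exactly one serine and a finite positive H/L
ratio), the incorporation fraction is computed from the heavy/light ratio
*r*. Two formulas ship behind a flag: the as-printed form 1 − 1/(r − 1)
(default; undefined at r = 1, such records are flagged and excluded) and the
standard incorporation-check identity r/(r + 1). Both are strictly
increasing with limit 1; they disagree at low ratios, and keeping both makes
the choice explicit instead of silent. The strain-level estimate is the
maximum of a Gaussian KDE over the per-peptide values — a mode estimator,
deliberately robust to the heavy tails ratio noise produces — evaluated on a
512-point grid spanning [min − 3h, max + 3h] with Silverman's bandwidth
(both overridable; neither choice is canonical, and the recovery tests show
the mode is insensitive to them at n ≈ 2000). Ties resolve to the lowest
grid point and are flagged. At least 10 finite values are required; below
that a mode estimate is meaningless. Two headline statistics are reported
because both readings are in circulation: the density maximum (default) and
the fraction of peptides with incorporation > 0.5 (the "share of labeled
peptides"). Strain contrasts are percent decreases of levels,
100·(ref − test)/ref.

**Proteome outliers.** The tiered-significance calls on whole-proteome H/L
ratios use an intensity-binned robust z: proteins are sorted by intensity
into equal-count bins (default ≈ 300/bin), each bin contributes its median
log2 ratio and a robust sigma equal to half the 15.87–84.13 interpercentile
distance (the ±1σ quantiles of a normal), and each protein gets a two-sided
normal tail p-value, tiered at 1e-11, 1e-4, 0.05. The binning absorbs the
variance–intensity dependence of SILAC ratios. The exact test behind the
published tiers is not specified anywhere we could follow; this binned
robust-z construction is our documented choice, with bin size and
percentiles as configuration.

## Tracer quantification

All tracer arithmetic starts from integrated instrument output (counts,
peak areas, species amounts); no peak picking or spectral deconvolution is
in scope.

* **Uptake:** per-time uptake = max(counts − background, 0) / specific
  activity / protein mass (nmol·mg⁻¹). Negative background-subtracted counts
  clamp to zero with a warning — transported amounts are physically
  nonnegative. The specific activity of the labeled substrate is a required
  input, never a built-in constant. The initial rate defaults to the 5-min
  point (the time the strain comparisons are reported at); a least-squares
  line through the origin over all points is available for saturating
  courses.
* **Amino acids:** concentration = (area / internal-standard area) ×
  calibration factor / cell count, in nmol per 10⁸ cells; calibration
  factors come from a measured standard mixture and are required per
  analyte.
* **Lipids:** mol% = 100 × amount of the (class, channel) cell / total
  amount of all detected lipids in the sample; the per-sample mol% cells sum
  to 100 by construction, which the tests assert to 1e-9.
* **LCBs:** amount = intensity / standard intensity × spiked pmol / protein
  mg; fold changes versus a named reference sample, NaN-flagged when the
  reference amount is zero.
* Replicates aggregate as arithmetic mean ± sd with n; two-condition
  comparisons use Welch's t-test (unequal variances is the safe default when
  only "t-test" is specified).

## Screen mining

Interaction tables (gene, epsilon, p) are annotated with −log10 p and a
negative-significant call (epsilon < 0 and raw p < 0.05 by default — raw
because that is what the volcano representation plots), sorted by ascending
p with ties broken by descending |epsilon|, which makes the ranking a stable
total order. A Benjamini–Hochberg q-value column is emitted alongside for
transparency, but does not drive the default call.

## Synthetic data

Every generator is deterministic under a fixed seed, with per-generator
streams (seed derived from a stable hash of the generator name mixed with
the user seed) so adding generators never perturbs existing fixtures, and
writes a `.truth.json` sidecar consumed by recovery tests. Defaults encode
the study conditions the analyses target: strain incorporation levels
(WT 0.938, ser2 0.927, gnp1 0.59, agp1 0.908, gnp1 agp1 at an 81% decrease
from WT), uptake-rate ratios (gnp1 at 35% and agp1 at 66% of WT), labeled-
IPC fractions (gnp1 at 36% and gnp1 agp1 at 27% of WT), amino-acid feeding
contrasts (+67% serine, +120% glycine in fed WT), and a screen with two
planted aggravating partners on a 3000-gene Gaussian null. Peptide tables
use n = 2000, noise sd 0.03, 10% uniform outliers, 5% missing ratios —
enough contamination to exercise the mode estimator's robustness.

What the fixtures do *not* emulate: correlated peptide noise within
proteins, ratio compression, intensity-dependent missingness, chromatographic
drift, lipid-class-specific ionization response, or epsilon-score
correlation structure between genes. Passing the recovery tests therefore
shows the estimators are correct and robust under idealized noise, not that
they overcome every systematic artifact of real acquisitions.

## Problem sizes and numerical choices

Random networks for oracle cross-checks are capped at 8 reactions (vertex
enumeration is combinatorial); the acceptance run uses 200 networks, a
41-point toy-model scan, and n = 2000 peptide tables — sizes at which every
stage is exact or converged while the whole script finishes in about a
minute. Degenerate inputs are handled explicitly: empty GPRs are
unconditionally true, all-identical incorporation values short-circuit the
KDE to their common value, zero-total lipid samples and nonpositive
reference values raise errors rather than propagate nonsense.

## Known limitations

* No parsimonious FBA, loopless FVA, flux sampling, or integer constraints;
  the engine is exactly the LP family the envelope analyses need.
* The genome-scale workflow is implemented and tested against locally
  written SBML-FBC files; the public yeast genome-scale model is not
  redistributed, and the corresponding full-model scan test runs only when
  the user places the SBML file under `models/`.
* XLSX ingestion is a thin column-mapping layer over pandas/openpyxl;
  supplementary-file layouts vary and may need a custom mapping.
* The incorporation estimator assumes the labeled population dominates the
  density; under extreme outlier fractions (≫ 10%) the mode can jump.
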