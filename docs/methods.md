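# Methods

## The thermodynamic model

A synthetic promoter is an ordered string of binding-site tokens from a
small alphabet (Cbf1, Gcn4, Met31/Met32, Nrg1 in the study configuration),
integrated upstream of a reporter. The promoter's ensemble of microstates
assigns each site one occupant — empty, its cognate TF, or (in the
competitive variant, at Gcn4 sites only) an unidentified competitor — and
the implicit polymerase site one of bound/unbound. Unbound DNA is the
reference state with statistical weight 1. The energy of a state is the
sum of the ΔG terms of its molecular contacts, all in kT units with
negative = favorable:

* `dG_dna[f, c]` — apparent TF–DNA binding energy of factor *f* in growth
  condition *c*. "Apparent" because it absorbs the factor's nuclear
  concentration (chemical potential); that is why it may legitimately
  differ between conditions (for Gcn4, amino-acid starvation raises
  concentration, lowering the apparent ΔG).
* `dG_pol[f, c]` — TF–polymerase contact energy, added once per bound
  copy of *f* when polymerase is bound. Negative = activator, positive =
  repressor.
* `dG_pol_basal[c]` — polymerase–promoter energy with no TFs bound; sets
  the basal expression level per condition.
* `dG_tftf[{f, g}]` — cooperativity (negative) or anti-cooperativity
  (positive) added once per unordered pair of co-bound TFs; `{f, f}` self
  pairs contribute C(n, 2) terms when n copies are bound. Missing pairs
  mean independent binding. Because spacing, orientation and edge effects
  are deliberately out of scope, the all-pairs convention is the default;
  an adjacent-chain convention is available as `pair_mode="adjacent"` for
  sensitivity analysis.
* `dG_comp_dna`, `dG_comp_pol` — the competitor's DNA and polymerase
  contacts, shared between conditions (the competing hypothesis is that a
  condition-independent repressor explains the Gcn4 site's switching, so
  its parameters must not vary by condition). The competitor has no
  modeled contact with any TF.
* `dG_pol_override[(f, tag)]` — a library-specific TF–polymerase energy
  replacing `dG_pol` for promoters of one tagged-TF strain library. This
  implements the tagged-Cbf1 correction: the epitope tag perturbs the
  polymerase contact but the TF–DNA energy is shared with the untagged
  protein.

A state's weight is `exp(-E)`; the partition function Z sums weights over
all states; state probabilities are weights over Z. Predicted
(normalized) expression is `expr_scale × P(polymerase bound)`. Predicted
occupancy of factor *f* is its **expected bound-site count** — the sum
over its sites of the per-site bound probability — mapped onto the
measured background-relative scale as `1 + occ_scale[f] × count`, so a
promoter without sites for *f* predicts exactly 1, matching the
background-median normalization of the ChIP scores. The expected-count
reading (rather than "probability any site is bound", which saturates at
1) is chosen because measured Cbf1 occupancy grows almost linearly with
its site count.

`expr_scale` and `occ_scale` are calibration constants of the measurement
(normalization to no-insert controls; IP capture efficiency), not free
energies; by default they are fixed, with opt-in flags to fit them.

### Evaluation paths

Explicit state enumeration (`enumerate_states`/`partition`) is the
transparent reference path, capped at 20 sites. The production path
exploits exchangeability: under the all-pairs convention a state's energy
depends only on the per-factor bound counts (and competitor count), so
the ensemble collapses to count classes with multinomial multiplicities —
a promoter with eight sites has at most a few hundred classes instead of
up to 13 000 states. Both paths work in log space (log-sum-exp), and the
test suite certifies their agreement to 1e-12 on a thousand random
promoters.

## Occupancy scoring

For one ChIPed factor × condition, each promoter's score is

    (IP_i / IP_total) / (input_i / input_total)
    ───────────────────────────────────────────
    median of that ratio over background promoters

where background promoters are those lacking a binding site for the
ChIPed factor. The score is dimensionless, equals 1 at non-specific
background, and is invariant to rescaling all IP or all input counts.
Promoters with fewer than 50 input reads (summed over replicates by
default; a per-replicate variant is available) are excluded before any
computation. Replicates are combined by summing coverage; a
`single:<r>` mode reproduces the special case where only one replicate
is usable. Even-sized background sets use midpoint interpolation for the
median. Unassignable reads (tokens outside the site catalog) are tallied
and logged, never silently dropped.

## Fitting

Free energies are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective), best of
`n_starts` uniform random starts in [-10, 10] kT, reproducible
bit-for-bit from the seed. A model structure (`ModelSpec`) decides which
energies are free and how they are tied: per-condition DNA energies only
for factors expected to change concentration (Gcn4 by default),
per-condition polymerase energies only for the switching variant,
interactions free only when listed. Study-style structures carry 10–13
free energies.

Because every state energy is linear in the vector of energy slots, each
observation record reduces to a fixed coefficient matrix over its count
classes; residuals and an analytic Jacobian for all records are then two
dense matrix products plus segmented sums. This is what makes multistart
fitting, 200-replicate selection studies and cross-validation affordable
on one CPU.

**Residual scale.** Flow-cytometry ratios and sequencing-derived scores
carry multiplicative noise, so the default fitting scale is logarithmic:
residual = log(predicted) − log(observed). Under lognormal noise these
residuals are homoscedastic Gaussian, which is also what keeps the
nested-model F-tests calibrated; weighting raw residuals by 1/observed²
looks equivalent but correlates the weights with the noise and is
measurably anti-conservative. Plain (`absolute`) and `relative` scales
remain available; the `objective` convenience function defaults to the
plain sum of squared differences. The log scale requires strictly
positive observations — zero-score occupancy records (promoters with no
IP reads) should be filtered or fitted on the absolute scale.
Per-data-type weights (expression vs occupancy) default to 1:1 and are
exposed in the configuration, since fitting otherwise tends to favor
whichever data type has larger residual mass.

Missing expression values (the flow cytometer's dynamic range censors
high AAS values) are excluded from the objective, never imputed.

## Model comparison and selection

Nested models are compared with F = ((RSS0 − RSS1)/Δp)/(RSS1/(n − p1)).
Validity requires RSS1 ≤ RSS0, which is guaranteed by warm-starting the
alternative from the null optimum, and requires RSS0 to actually be the
null optimum: forward selection therefore polishes the current (null)
model to tight tolerance (1e-11) before each round, while candidate
refits may stop early (tolerance 1e-8, iteration cap) — early stopping
there can only understate a candidate's improvement, i.e. err
conservative. Within a round every remaining TF–TF pair is tested
against the current model at the Bonferroni level alpha/m (m = candidates
in the round by default; the all-candidates family is switchable); the
most significant passer is added; selection stops when none pass. The
full trail of every test is recorded.

Two properties the simulation studies established, documented as
operating conditions of the test:

* On designs where some energies are unidentifiable (e.g. factors with
  expression data only, whose weak-binding limit identifies only the
  product of association and polymerase weights), the null fit's Jacobian
  is singular — exactly the pathology the multistart diagnostics are
  designed to reveal — and F-test asymptotics degrade. Operating
  characteristics are therefore studied on designs with occupancy data
  for every factor.
* On identifiable designs the procedure runs at its nominal level, not
  below it: the candidate directions are near-orthogonal after
  projecting out the null model, so the Bonferroni union bound is nearly
  tight and the family-wise false-retention rate sits at ≈ alpha (checked
  three ways: residuals at the exact truth match n·σ², the linearized
  RSS drop equals the realized drop, and a fixed-design Monte Carlo of
  the single-candidate p-value is uniform). Expect ~5% of all-null
  datasets to retain some spurious pair at alpha = 0.05 — that is the
  contract of the correction, not a defect.

## Cross-validation

Records (non-missing expression values and occupancy scores pooled) are
randomly partitioned into k = 5 folds of equal size ±1; each fold is held
out once, the model refit on the rest, and held-out R² reported. Folds
whose held-out values have no variance are flagged and excluded from the
summary. Fold assignment and refits are deterministic given the seed.

## Multistart and identifiability diagnostics

`multistart_diagnostics` runs independent single-start fits, clusters the
final objectives at 1e-4 relative tolerance, and reports the fraction of
starts reaching the modal cluster plus the fraction with singular
Jacobian (condition number > 1e8 at the optimum). A mechanistically
adequate, identifiable model shows a high modal fraction and non-singular
Jacobians; this is the diagnostic that favors the competitive over the
switching reading of the Gcn4 site when occupancy data are included.

## The synthetic-data generator

The generator emulates the study's measurement chain with every
expectation recomputable from the emitted `TruthRecord`:

* **Library**: site count per promoter from a truncated geometric
  (decay 0.65 per site, range 1–8 — ligation products decay in length),
  tokens i.i.d. from a frequency vector (uniform by default; the real
  melting-temperature-based mixing ratios are not recoverable from the
  main text). Duplicate compositions arise naturally, as in picked
  colonies.
* **Expression**: model prediction × lognormal noise (default sd 0.05 on
  the log scale); values above the censor threshold (default 4.5
  no-insert-normalized units) become missing, emulating the flow
  cytometer's dynamic range. Censoring produces missingness, not
  clipping.
* **ChIP counts**: library abundances drawn once from a symmetric
  Dirichlet (concentration 5 — pooled cultures are uneven); per replicate,
  input reads are multinomial over abundances and IP reads multinomial
  over abundances reweighted by (1 + κ × true bound count), with κ
  defaulting to the truth model's occ_scale so that deep sequencing
  recovers the model's occupancy surface exactly. Column sums equal the
  configured per-replicate totals.
* A `direct` occupancy mode bypasses read sampling and draws
  lognormal-noised scores straight from the truth surface, for inference
  studies that need the occupancy noise level controlled exactly.

Default truth energies are chosen to reproduce the study's qualitative
physiology: Cbf1 a strong constitutive binder and mild activator; Nrg1 a
repressor; Gcn4 an activator whose apparent DNA energy drops by 2.5 kT
from glucose to starvation (concentration-driven); under competitive
truth, a weakly repressing competitor with condition-constant affinity
occupies Gcn4 sites, making them net-repressive in glucose while
expression still correlates positively with Gcn4 occupancy in both
conditions. The Gcn4 energies sit deliberately below site saturation:
occupancy that no longer responds to site count carries no information
about the binding energy (and the measured occupancy does keep rising
with site count).

What the generator does **not** emulate: sequence-level reads and
sequencing errors, PCR bias, growth competition in pooled culture,
nucleosomes, spacing/orientation/edge effects. Passing tests on this
generator certify the statistical machinery under the model's own
assumptions — they do not certify those assumptions against real
chromatin.

## Problem sizes and numerical choices

The test suite runs the full pipeline at the study's scale: 250–300
promoters, two conditions, 10–13 free energies, 25-start recovery fits,
30 planted-interaction and 200 null selection replicates (the null arm
uses 150-promoter libraries). Optimizer tolerances are 1e-12 for final
fits, 1e-8 with a 200-evaluation cap inside selection rounds, 1e-11 for
null polishing. Probabilities are computed via log-sum-exp throughout;
state enumeration is capped at 20 sites; predictions are floored at
1e-300 before taking logs. Degenerate inputs (empty observation sets,
missing background promoters, zero observed variance, non-nested fits)
raise explicit errors rather than returning silently wrong numbers.

## Known limitations

* The occupancy reading (expected bound count) and the exact
  pair-counting convention for three or more co-bound copies are model
  choices; the saturating state-level reading and the adjacent-chain
  convention are available but not defaults.
* The F-test's calibration is asymptotic and degrades on
  non-identifiable designs (see above); the multistart diagnostics should
  accompany any selection run on a new design.
* Real ChIP backgrounds need not be identical across factors; the
  background-median scaling assumes they are.
* The log residual scale cannot ingest zero occupancy scores.
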