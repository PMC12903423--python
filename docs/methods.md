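# Methods

## Problem setting

High-throughput, oxygen-tolerant photo-ATRP (and PET-RAFT) in 96-well plates
turns reaction optimization into a planning problem: a bench chemist specifies
each condition as reagent molar ratios relative to the alkyl-halide initiator
(monomer/initiator/metal/ligand/photocatalyst, e.g. 200/1/0.08/0.2/0.002), a
final monomer concentration [M]_f, and a well volume; a liquid handler needs an
explicit list of transfer volumes from stocks of fixed concentration. plateplan
performs that translation, chooses which extra dilutions of each stock to
prepare, designs screens, and evaluates a simple initiation classifier on
staged screening batches.

## Stoichiometry

With initiator concentration c_I = [M]_f / DP, every ratio-listed reagent sits
at c_x = r_x · c_I and each monomer at its mole fraction of [M]_f. The
theoretical molecular weight uses the full-conversion convention

    Mn,th = DP · M̄_monomer + M_initiator   (reported in kDa),

where M̄ is the mole-fraction-weighted mean monomer mass; statistical
copolymers with unspecified fractions default to equimolar. A
conversion-scaled variant `theoretical_mn(recipe, conversion=p)` multiplies
the DP term by p. End-group conventions finer than "+ initiator mass" (e.g.
explicit halide accounting) are indistinguishable at one-decimal kDa
precision for the monomers in the packaged table, so the simplest convention
is used. Internal units are mM / µL / g·mol⁻¹; [M]_f enters in mol/L at the
I/O boundary only.

## Dilution selection

Each reagent has a stock plus a user-listed set of permissible dilution
concentrations (arbitrary values, not necessarily a serial chain). A source c
can serve a target c_t in a well of volume V when the transfer
v = c_t·V/c lies within [v_min, v_max_frac·V]; monomers are exempt from the
upper cap (they legitimately occupy a large well fraction), solvent is the
makeup stream. Per reagent, the planner finds a minimum-cardinality subset of
the allowed dilutions such that every recipe has at least one feasible source
(the stock itself is free), by exact enumeration of subsets in increasing
cardinality — candidate lists are short (≤ ~10), so exhaustive search is
cheap and provably optimal; among equal-size covers the lexicographically
highest concentration set is preferred because higher concentrations mean
smaller transfers, and each recipe is assigned the highest feasible prepared
concentration. Recipes with no feasible source for some reagent, or whose
non-solvent volumes exceed the well, are reported in the diagnostics and
skipped; the rest of the batch proceeds.

Defaults: V = 200 µL in a 300 µL well (100 µL oxygen headspace is consumed by
the activator-regeneration chemistry), v_min = 1.0 µL (a typical
air-displacement accuracy floor), v_max_frac = 0.25 for non-monomer reagents,
rounding quantum 0.01 µL, dilution-prep dead volume 50 µL. Volumes are
quantized to the quantum and the solvent-makeup step absorbs the residue, so
well volumes sum to v_total exactly; before rounding, delivered moles match
targets to machine precision, and after rounding the error is bounded by
quantum/V · c_source. Dilutions are prepared directly from the stock; only
when the stock transfer itself would fall below v_min does the planner chain
through the next-higher prepared concentration (two-stage serial prep),
because direct preparation minimizes compounding volumetric error. The
planner contains no randomness: identical inputs give byte-identical
worklists.

## Screens and chain extension

Factorial screens cross ratio levels (per-reagent lists or explicit tuples)
with ligand and initiator identities; the count identity
|tuples|·|ligands|·|initiators| holds for all inputs and ordering is
deterministic (ligand-major, initiator next, tuples innermost). OFAT sweeps
emit the base recipe once plus one recipe per swept level, deduplicating
levels equal to the base value.

Chain extension uses the equal-volume withdraw-then-add model: removing v and
adding v of monomer stock at c_stock leaves the total volume unchanged and
sets the second-block monomer concentration to c_stock·v/V, so
v = m_target·V/c_stock (displayed at 0.1 µL). The second-block
monomer:initiator ratio is (c_stock·v)/(c_I·(V−v)); unreacted first-block
monomer is ignored, since it cannot be quantified without conversion data.

## Initiation classifier

Features are the ligand, metal, and photocatalyst molar ratios; the label is
binary initiation (polymer observed by SEC/NMR within the irradiation
window). The model is an SGD-trained linear classifier on log loss
(probabilistic output, 0.5 threshold), with features z-scored on the training
data. Hyperparameters — regularization strength α log-uniform over
[1e-5, 1e1] and the learning-rate schedule ("optimal" or "adaptive") — are
chosen by a seeded randomized search (default 50 draws) with 5-fold
stratified cross-validation scored by balanced accuracy inside an 80/20
split, then the best setting is refit on all training rows; the 20% holdout
score is stored on the model. Averaged SGD with a generous iteration budget
(max_iter 5000, tol 1e-4) is used because at screening batch sizes (tens of
rows) plain SGD weights are dominated by optimization noise;
constant/inverse-scaling schedules with a free initial rate are excluded from
the search space for the same reason. The split and CV folds are stratified
(the protocol only says "random"); with ~40-row imbalanced batches,
unstratified folds can be single-class, leaving balanced accuracy undefined.
Class imbalance is handled at evaluation via balanced accuracy (mean
per-class recall, which errors if a class is absent); inverse-frequency
sample weighting is exposed (`class_weight="balanced"`) but off by default.

The sequential protocol mirrors staged campaigns: fit on batch 1, score on
batch 2; refit on batches 1∪2, score on batch 3 — standardization refit at
each stage on the then-available training rows.

Attributions are exact for the linear model: with independent features the
Shapley value of feature i at sample x is w_i·(z_i − z̄_train,i), and
z̄_train = 0 by construction, so φ_i(x) = w_i·z_i. The efficiency identity
Σφ_i(x) = score(x) − score(training mean) holds to machine precision; feature
ranking is by mean |φ| over the scored set. No sampling approximation is
involved.

## Synthetic batches

The generator samples (ligand, metal, PC) ratio tuples over the screened
ranges (0.2–1, 0.08–0.4, 0.001–0.1) by Latin hypercube (default) or a
truncated lattice, and draws labels Bernoulli(σ(β₀ + z·β)) with z
standardized by the fixed uniform-design moments of the ranges (so the ground
truth does not depend on the sample), plus optional symmetric label flips.
The default ground truth is β = (+2, −1.5, +0.1), β₀ = 0, 5% noise: a
synthetic encoding of the mechanistic expectation that ligand promotes and
metal (deactivator) suppresses initiation while the photocatalyst loading
matters least — its magnitudes are this package's choice, not a fit to
measured data. The fixture campaign uses β₀ = 1.4, which under the ~2.5 score
s.d. gives the roughly 2:1 positive:negative balance typical of screening
data. Campaign batch sizes default to 42/37/88 (167 wells), the size of a
realistic three-stage screen.

What the generator does not emulate: kinetics and induction periods, monomer
identity, [M]_f or light-dose dependence, batch-to-batch labelling drift, or
correlated designs. Tests passing on this data show the pipeline recovers a
planted monotone structure at realistic n — not that any particular chemistry
behaves this way.

## Verified behaviors and their problem sizes

The test suite checks, among others: Mn,th values for DP-200 acrylate
homopolymers and the equimolar terpolymer at one-decimal kDa precision;
the 36.0 µL extension transfer; 64 = 16×2×2 factorial conditions and a
270-condition grid; minimal-cover optimality against an independent powerset
brute force on 200 random instances (≤5 candidates, ≤12 recipes); exact
volume conservation and quantum-bounded mole delivery on a 48-recipe batch
with byte-identical replanning; and the classifier properties on synthetic
campaigns — stage-2 ≥ stage-1 balanced accuracy in ≥70% of 50 seeded
42/37/88 replicates (a deterministic logistic-regression reference attains
the same fraction, so the residual is test-set difficulty variance, not fit
noise), weight-sign and attribution-ranking recovery in ≥90% of 50
replicates at n = 300, the attribution efficiency identity at 1e-9, and
near-chance held-out balanced accuracy (mean over 20 seeds in [0.4, 0.6]) on
label-randomized data at n = 500. The null bound is asserted on the mean
because a per-seed bound on a 100-row holdout would fail by binomial noise
alone with non-trivial probability even for a perfectly calibrated model.

## Known limitations

- The dilution cover is solved per reagent; cross-reagent interactions (e.g.
  shared prep-tube capacity) are not modelled.
- Serial prep chains only pass through concentrations already in the prepared
  set; a chain requiring an otherwise-unused intermediate raises an error
  rather than adding one.
- No instrument-native output (Hamilton/Tecan/Opentrons), liquid classes, or
  tip tracking; the worklist is a neutral CSV/XLSX schema.
- The classifier is linear by design; the closed-form attributions do not
  extend to nonlinear models.
- Conversion, dispersity, and measured molecular weights are outputs of the
  wet lab, not predictions of this package.
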