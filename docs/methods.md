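# Methods

## Model

`idpsol` treats the relative solubility of an intrinsically disordered
chain as a smooth function of two pH-dependent sequence properties,
expanded to first order in the whole-chain lipophilicity L and to second
order in the magnitude of the fractional net charge |Q|:

    S(pH) = α·L(pH) + β·|Q(pH)|² + γ·|Q(pH)| + δ

The default coefficients (α = −97.82, β = −0.00747, γ = 0.8770,
δ = 38.24) come from a published least-squares parameterization against
experimental solubility of charge-engineered variants of a disordered
model protein.  With β < 0 the charge term is concave with a vertex at
|Q| = −γ/(2β) ≈ 58.7: added net charge is protective up to that point.
Because the model is phenomenological and its training data are in
arbitrary units, scores are comparable along a pH sweep and across closely
related variants, not across unrelated proteins, and they are not
concentrations.

Assumptions inherited from the model's derivation: the chain is
disordered, so no structural burial or conformational pKa shifts modulate
the sequence properties; aggregation is driven by hydrophobicity and
opposed by net charge; temperature, ionic strength and cosolutes are
outside the model.  Folded proteins are out of scope.

## Net charge and isoelectric point

Q(pH) sums Henderson–Hasselbalch fractional charges over D, E, C, Y, K,
R, H side chains and the free termini.  Terminal blocking flags
(N-acetylation / C-amidation) remove the corresponding group.  Free
cysteines count as acids; disulfides are not modelled, but Cys can be
excluded with a flag.  Q is strictly decreasing in pH, so the isoelectric
point is the unique root of Q, found by bisection on [0.1, 13.9] and
accepted when |Q| ≤ 1e-4 (default) and the bracket is narrower than 1e-6
pH units.  Sequences with no acidic or no basic group have no root and
raise a documented error.

The default pKa set is the Bjellqvist-style table behind the classic
ExPASy pI tool (D 4.05, E 4.45, C 9.0, Y 10.0, C-term 3.55, H 5.98,
K 10.0, R 12.0, N-term 7.5); an EMBOSS-style set is also built in, and
any set can be loaded from YAML.  Under the default set the computed pI
of α-synuclein (4.67), Aβ40 (5.31) and mature IAPP (8.90, plain 37-mer
with free termini and free cysteines) reproduce the reference values for
these proteins; pI values shift by roughly ±0.1–0.2 between standard pKa
sets, which is why the tests allow a ±0.2 band.  Histidine is treated as
ionizable throughout, since its pKa (~6) sits inside every pH range of
interest.  The termini chemistry of a construct matters — amidated
peptide hormones lose the C-terminal acid — and is the user's
responsibility via the blocking flags; reported reference values here use
free termini.

## pH-dependent lipophilicity

Each residue carries two species-level lipophilicity values, neutral and
charged, mixed by the Henderson–Hasselbalch neutral fraction at the given
pH; non-ionizable residues are pH-invariant and ionization never
increases lipophilicity.  The default table uses Fauchère–Pliška
octanol/water side-chain values for the neutral species.

The charged species sit 0.3 *scale units* below the neutral species.
This gap is the one genuinely free constant of the default table and is
deliberately not the ~3 log-unit drop seen in small-molecule logD:
the published coefficients fix the exchange rate between lipophilicity
units (α ≈ −98 per unit) and charge units (γ ≈ 0.88 per elementary
charge), so a 3-unit species gap would let a single histidine transition
move the whole-chain score of any chain under ~300 residues by far more
than its one-unit charge shift.  That balance would contradict the
qualitative pH regimes the parameterized model is known to produce —
rising Aβ40 solubility from pH 6 to 8.5 through the His transitions, and
monotone dissolution of acidic functional-amyloid peptides towards
neutrality.  Working that constraint backwards bounds the gap at ≲0.35
units; 0.3 is adopted.  Users with the originally published pH-dependent
scale can load it verbatim from YAML and bypass this reconstruction
entirely.

Ambiguity codes are rejected by default; an opt-in mode maps X to the
scale's mean neutral value.

## Profiles

A sliding window of odd size w — 5 for chains shorter than 75 residues,
7 below 175, 9 below 300, 11 otherwise (half-open intervals, so length
75 gets 7 and length 300 gets 11) — assigns each full window's mean to
its centre.  Terminal positions that cannot centre a full window receive
no value, so a length-L chain yields exactly L − w + 1 points, and the
global lipophilicity is the unweighted mean of those points.  Scoring
only full windows avoids inventing boundary values that would bias
short-peptide averages; a padded mode was considered and rejected.

The per-position solubility profile applies the surface window-by-window
using the whole-chain |Q| (charge is global and is not localized).  It
is a region-ranking heuristic for finding the stretches that depress the
whole-chain score; its mean equals the whole-chain score exactly, but
individual positions are not additive contributions.

## Fitting and validation

Re-parameterization minimizes Σ(S_obs − S(L, |Q|; θ))² with scipy's
trust-region least-squares solver, initialized at the published
coefficients with parameter tolerance 1e-10.  The surface is linear in
θ, so the optimum is unique whenever the design matrix [L, |Q|², |Q|, 1]
has full rank; a closed-form solution (`method="linear"`) is exposed and
the two routes agree to 1e-8 relative in the tests.  Rank-deficient
designs raise an error naming the offending columns.  Standard errors
come from the usual linear-model covariance s²(XᵀX)⁻¹.  At least five
observations are required, and both predictors must vary.

Validation regresses an experimental observable on predicted solubility
by ordinary least squares and reports slope, intercept, R², the
two-tailed p-value of the slope (t = r·√((n−2)/(1−r²)), n−2 df) and a
standard mean-response confidence band.  R² and p are invariant under
affine rescaling of the predictions, which is what makes the arbitrary
score units harmless for validation.  An orientation flag records
whether larger observable values mean more aggregation and hence which
slope sign is expected; the sign is reported, never enforced.

## Synthetic benchmark

The generator emulates the charge-variant experiment that produced the
training data: a 230-residue disordered chain with 40% charged residues
(composition enriched in D/E/K/R/S/P/G/Q, depleted in aromatics,
branched apolars and Cys), plus an acidic variant (every K/R → E) and a
basic variant (every D/E → K).  Flipping only charged positions keeps
the apolar scaffold fixed while moving the isoelectric point far in each
direction, which spreads the (L, |Q|) design and makes all four
coefficients identifiable.  Histidine is left unflipped by default
(weakly basic; a flag flips it to Q).  Solubility observations are drawn
on 10 equispaced pH points on [2, 12] — the package's canonical sweep
interval — as surface value plus additive homoscedastic Gaussian noise;
the default noise SD is 2% of the noiseless score range, and one seed
fixes the sequence draw and the noise.  The noise model is the simplest
one consistent with a homoscedastic least-squares fit; real solubility
assays are bounded and often heteroscedastic, so passing recovery tests
demonstrate estimator correctness, not assay realism.  Likewise the
generator makes no attempt at residue-order realism (no NAC-like
hydrophobic clustering), so it exercises composition-driven behaviour
only.

A power note on parameter recovery under these conditions: with n = 30
observations and noise at 2% of the score range, the theoretical
standard errors of α, β, γ sit at roughly 2.5–3% of the parameter
values (the score range cannot fall below the ~26-unit span of the
charge term itself, which floors the noise).  Recovery of all four
coefficients within 5% relative error therefore succeeds in only about
90–93% of replicates — a property of the stated design, not of the
estimator, which is exact on noiseless data and calibrated in its
standard errors (both asserted in the tests).

## Numerical choices and edge cases

- pH arguments are validated to the open interval (0, 14); sweeps default
  to [2, 12] with step 0.1.
- Window sizes must be odd, ≥ 3 and no longer than the sequence; chains
  shorter than 5 residues cannot be profiled.
- pI is reported to 2 decimals at the CLI; the full-precision root is
  kept internally.
- Charge-variant flipping of a chain with no charged residues is a no-op
  with a warning.
- FASTA reading is strict by default (duplicate ids, lowercase and
  non-standard characters are errors); the lenient policy uppercases,
  strips whitespace and trailing stops.  CSV outputs use UTF-8 and "."
  decimals, with a provenance header naming the tables, coefficients and
  package version.

## Known limitations

- The default lipophilicity table is a documented reconstruction, not the
  originally published pH-dependent scale; absolute scores differ from
  those of the original parameterization even though the functional form
  and coefficients are identical.  Drop in the published scale via YAML
  for exact reproduction.
- Charge is treated as a whole-chain scalar; segregated charge
  architectures (e.g. a charged C-terminal tail next to a hydrophobic
  core region) are averaged over.
- No structure, temperature, ionic strength, binding partners or
  post-translational modifications beyond terminal blocking.
- Kinetic observables (elongation constants, lag times) are supported
  only as regression targets for validation, never predicted directly.
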