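# Methods

## Model and assumptions

The response is per-residue burial status: Y = 0 if the residue's relative
solvent accessibility (RSA) is below a threshold, Y = 1 otherwise.  The
linear predictor mixes quantitative descriptors with dummy-coded
qualitative ones,

    η = β₀ + Σ_q β_q X_q + Σ_j β_j X_j,      p = e^η / (1 + e^η),

and Y | descriptors ~ Bernoulli(p).  Residues are treated as independent;
in reality neighbors are correlated, so standard errors are, if anything,
slightly optimistic.  Fitted probabilities are classified accessible at
p ≥ cutoff (default 0.5, boundary inclusive — the convention had to be
fixed somewhere and "at least as likely accessible as not" reads
naturally).

Named models: `classic` = E20+E6+FSR+FSHP+AA, `comprehensive` =
E6+FSR+FSHP+AA+LGDP+AQN, `non_homology` = LGDP+AA+AQN.  A published
classic-model coefficient table (1363-chain X-ray learning set, 20%
threshold) ships in `logit_model.PUBLISHED_CLASSIC_COEFFICIENTS` for
prediction without refitting.

## Descriptors

All descriptors are per 1-based query position k.

- **E20, E6** (nats): column entropy −Σ P ln P over the aligned non-gap
  homolog residues, over 20 types or 6 classes.  Gaps and non-standard
  letters are excluded from numerator *and* denominator: treating the gap
  as a 21st symbol conflates alignment coverage with conservation.  The
  query's own residue contributes no pseudo-count (users wanting one can
  add a self-hit).  Positions with N_k = 0 get missing descriptors even
  inside an optimum-homology chain and drop out of homology-model fits.
- **FSHP, FSR**: fractions of the same aligned residues in {V,L,I,F,Y,M,W}
  and {G,A}.
- **AA**: query residue type, treatment-coded with Val baseline (19
  indicators, columns ordered alphabetically by three-letter code).
- **AQN_prev / AQN_next**: residue types at k−1 / k+1 read off the FASTA
  query.  Chain termini are coded as a distinguished 21st "boundary" level
  (`*`) rather than dropped or imputed — it fabricates no residue and
  affects under 1% of positions.  An undefined residue (X) appearing as a
  *neighbor* is assumed to be alanine; a record whose *own* residue is X
  cannot be dummy-coded and is dropped with a logged count.
- **LGDP**: externally computed disorder propensity in [0, 1], consumed as
  given.  The Ising-model machinery that produces it is not
  re-implemented; the fixture generator supplies a statistical stand-in.

### Six-class scheme

The six-class partition is not canonical in the literature, so it is
explicit and overridable (`AminoClassScheme`).  The default groups
{A,V,L,I,M,C} aliphatic/hydrophobic, {F,W,Y,H} aromatic, {S,T,N,Q} polar,
{K,R} basic, {D,E} acidic, {G,P} conformationally special.  Entropies use
the natural log; classification accuracy is invariant to the base (it
rescales one column of a fitted linear predictor) but coefficient
magnitudes are not, so the base is recorded in the model JSON.

## Homology handling

Hits are kept at bit score ≥ 40% of the best score (inclusive).  A chain
with ≥ 10 surviving subject *sequences* (not covered positions) has
optimum homology; only there are homology descriptors considered reliable.
Identical subjects are not deduplicated — descriptors are frequencies of
what BLAST returned.  Evaluation enforces the branch policy: a homology
model is never applied to non-optimum chains; the all-proteins number is
the residue-weighted mean of the two branch accuracies (identically the
pooled accuracy — asserted exactly in tests).  Accuracies are
residue-pooled within strata, not averaged per protein.

## Labels and interfaces

`binarize_rsa` marks buried strictly below the threshold (so RSA exactly
at 20% is accessible); 20% is the default, 25% the stock alternative.
Relative accessibilities slightly above 100% (extended conformations) are
accepted.  For oligomeric chains the gold-standard label uses the
complex-context (biological-unit) RSA.  A residue is flagged *likely
interfacial* when single-chain RSA exceeds complex-context RSA by more
than `min_delta`; the default 0 ("any measurable increase") is
configurable since no principled cutoff exists.  RSA tables map to FASTA
positions by sequential order of RES lines; length mismatches are
reported and unmatched residues drop from fitting/evaluation — about 5%
of residues are typically unresolved in X-ray structures, and there is no
gold standard for them.

Missing values are explicit (never zero-filled); a record missing any
descriptor required by the active model is excluded from that model's fit
and evaluation only.

## Fitting: numerical choices

IRLS (Newton–Raphson on the Bernoulli log-likelihood) from β = 0,
convergence when the relative log-likelihood change is below 1e-10, at
most 100 iterations.  Weights are floored at 1e-12 for numerical safety.
Standard errors come from the inverse observed information at the
optimum; Wald p-values are two-sided with no multiple-testing correction.
No regularization: perfect separation (recognized by a log-likelihood at
numerical zero or runaway coefficients) and rank deficiency (recognized
via pivoted QR) are flagged non-converged with the offending columns
named, never silently penalized.  The tests cross-check coefficients,
standard errors and log-likelihood against statsmodels' GLM on the same
design to 1e-7.  Predicted probabilities use a numerically stable
logistic, exact at |η| ≥ 40.

The linear baseline regresses continuous RSA on one quantitative
descriptor plus per-AA intercepts (one common slope) by ordinary least
squares, and classifies by thresholding predicted RSA with the same
boundary convention as label binarization.

## Synthetic data: what it emulates, and what it does not

`synthetic_fixtures` generates the study conditions end to end.  Alignment
columns are Dirichlet-multinomial with per-position concentration 0.08
(conserved) or 1.2 (variable), half and half — chosen once to give a
realistic spread of entropies from near 0 to near the maximum.  The query
is drawn from the same column composition, coupling it to its family.
Hit counts are Poisson with mean 24, or mean 5 for the 25% of chains
designated low-homology so both evaluation branches are populated; bit
scores are the best score times Uniform(0.15, 1), putting hits on both
sides of the 40% cut.  Chain lengths are Uniform(60, 220).  Labels are
drawn from the logistic model at a known β (default: the published
classic coefficients, so simulated data live in the fitted regime);
continuous RSA is sampled uniformly inside the matching buried/accessible
band, so thresholding reproduces the label exactly.  Half the chains are
oligomers; one-fifth of oligomer residues are interfacial (both matching
the observed test-set regime), their single-chain RSA is raised 15
percentage points above the complex value, and by default their labels
are re-drawn fair-coin — decoupled from the descriptors — because real
interface burial is invisible to single-chain descriptors.  The LGDP stub
is a noisy logistic transform of the true predictor, correlated with
accessibility like a real disorder score but with none of the Ising
model's sequence structure.

Not emulated: phylogenetic correlation between subjects (columns are
exchangeable), real secondary/tertiary structure, indel geometry, BLAST
score statistics, or the actual LGDP algorithm.  Passing tests therefore
demonstrate correctness of the descriptor arithmetic, estimator and
evaluation logic under the model's own assumptions — not real-world
prediction accuracy, which depends on how far real proteins deviate from
those assumptions.

## Problem sizes used in the validation suite

Entropy kernel: 1 000 random columns against a brute-force multiset
oracle (agreement to 1e-12).  Parameter recovery: 20 000 residues
simulated at known β, estimates required within 3 SE; the score identity
(mean fitted probability = observed accessible fraction) to 1e-8.
Wald-interval coverage: 300 replicates of n = 250.  Determinism: the full
simulate→descriptors→fit→evaluate chain on 14 chains, byte-compared
across reruns.  Two-branch identity and interface-removal checks: 24- and
20-chain studies (~3 000 residues).  These sizes make the full suite run
in seconds while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

- The residue-independence assumption understates uncertainty; no
  cluster-robust errors are provided.
- FASTA↔structure numbering reconciliation is by sequential order plus an
  optional explicit mapping; exotic insertion-code schemes need the
  mapping hook.
- Box–Tidwell-style power transformations and interaction terms are out
  of scope (they are reported not to improve accuracy for these
  descriptors).
- Oligomer status is an input flag per chain; the package does not decide
  biological units.
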