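# Methods

## The prediction problem

Given a p53 mutant with k simultaneous amino-acid substitutions
(k = 1..4) and an active/inactive transactivation label, the analysis
asks two questions: can the label be predicted from a hybrid numeric
representation of the mutant, and which features carry the signal. The
pipeline is encode → mRMR rank → incremental feature selection (IFS) →
jackknifed nearest-neighbor evaluation, each stage usable on its own.

## Feature encoding

Each mutation site contributes a 260-value block computed on the
9-residue window centred on the site (positions site−4 … site+4 of the
wild-type sequence):

| family   | count | definition |
|----------|-------|------------|
| SNP      | 10    | evolutionary gain/loss propensity of the 9 window residues, plus the value of the substituted residue |
| pro-pro  | 10    | protein-interface conservation propensity, same layout |
| AAFactor | 50    | Atchley's five factor scores (polarity, secondary structure, molecular volume, codon diversity, charge) × 9 residues, plus 5 for the substituted residue |
| PSSM     | 180   | 20 conservation probabilities × 9 window positions, from the PSI-BLAST matrix of the wild-type sequence |
| disorder | 9     | per-residue structural disorder score of the window |
| GRANTHAM | 1     | Grantham physicochemical distance between the wild-type and substituted residue |

The k per-site blocks are followed by k−1 inter-site distances (absolute
residue-index differences between consecutive sites) and by 5408
precomputed structure descriptors: V1–V4826 summarize the 2D surface map
of the energy-minimized mutant homology model, V4827–V5408 the 3D
Cα distance-difference map against wild type. Structure features are
*ingested*, never computed here — homology modelling is out of scope.
Totals: 5668, 5929, 6190, 6451 features for k = 1..4.

Conventions worth stating:

- Residue positions are 1-based throughout, matching mutation
  nomenclature (R175H means position 175).
- The per-site "+1"/"+5" counts are realized as the property value of the
  substituted residue (`MUT_SNP`, `MUT_AAFactor-3`, …). PSSM and disorder
  are defined only on wild-type positions and have no such term, which is
  the only reading consistent with the per-family counts above.
- Windows that run past a terminus are padded with `X`; all lookups map
  `X` to 0, PSSM/disorder rows outside the sequence are all-zero. p53
  core-domain mutations never reach a boundary, so this only guards
  degenerate inputs; zero is the least-informative neutral value.
- PSSM columns follow the PSI-BLAST order `A R N D C Q E G H I L K M F P
  S T W Y V`; the suffix in `AA3_PSSM-8-G` is (1-based column index,
  residue). The probability block (integer percentages) of the ASCII
  output is used, divided by 100; whether probability or log-odds is the
  better choice is undetermined, and the reader isolates the decision.
- Feature names form a grammar (`AP{site}.AA{residue}_{family}-{detail}`,
  `DIST1-2`, `V241`) that parses back to (site, residue, family, detail);
  all downstream composition summaries run on names alone.
- The SNP and pro-pro numeric tables are shipped as clearly labeled
  placeholder files (distinct evenly spaced values per residue type):
  the published per-residue values are not redistributed here. Users
  substitute their own two-column TSVs to reproduce them; every
  derivation in this package is insensitive to the specific values, only
  to their being a fixed residue-type lookup.

## mRMR ranking

Features are discretized to 3 states split at mean ± α·sd (α = 0.5,
population sd; a constant column maps to one state). Discretization
thresholds are recorded so a ranking is exactly reproducible. Mutual
information is computed from empirical cell frequencies in nats; the log
base only rescales MI and cannot reorder features.

The greedy ranking selects, in round h with m = h−1 features already
chosen, the feature maximizing relevance − mean redundancy,
`I(f;c) − (1/m)·Σ_g I(f;g)` (the difference form; the quotient variant is
out of scope). Round 1 has no redundancy term. Ties break to the lowest
original column index; since mathematically equal MI values computed in
different summation orders differ at ~1e−16, criteria within 1e−12 of the
round maximum are treated as tied. The ranking is validated against a
brute-force oracle that re-evaluates the criterion from scratch each
round.

## Nearest neighbor, jackknife, MCC

The distance is `D(v₁,v₂) = 1 − ⟨v₁,v₂⟩/(‖v₁‖·‖v₂‖)` ∈ [0,2] — cosine
dissimilarity of whole mutant vectors. It is invariant to positive
rescaling of a *vector* but not of a single feature column, so no
per-feature standardization is applied by default (an explicit
`standardize` flag z-scores the table for users who want it). Zero-norm
vectors are rejected rather than silently assigned. Distance ties break
to the lowest training-sample index.

Jackknife (leave-one-out) evaluation predicts each sample from all
others; the result is unique for a given table. Performance is the
Matthews correlation coefficient of the pooled confusion counts, with the
standard convention MCC = 0 when any marginal factor of the denominator
is zero. MCC is the right summary here because the panels are severely
imbalanced (62:7, 16372:57, 111:63, 31:7 inactive-heavy or mixed).

## Incremental feature selection

IFS evaluates the nested prefixes S_k = top-k ranked features for
k = step, 2·step, …, k_max and reports the curve (k, MCC) plus the
optimal set: the smallest k attaining the maximal MCC (parsimony on
ties). step = 1 by default; k_max is configurable because a full sweep
(all N features × leave-one-out over thousands of samples) is
compute-heavy — scaled runs are reported as such in the run config.

## Synthetic data: what it emulates and what it does not

`generate_table` draws class-conditional Gaussian features at the exact
k-site dimension: `n_informative` features get their active-class mean
shifted by `effect_size` sd (default 2.0, a moderate signal);
`n_redundant` noisy copies per informative feature (sd
`redundancy_noise`) emulate correlated feature blocks; everything else is
independent N(0,1). Presets mirror the four study panels (62/7, 16372/57,
111/63, 31/7); scaling down keeps ≥ 5 active samples so leave-one-out has
same-class neighbors (proportional scaling of the two-site panel to
n ≤ 500 would leave ~2 actives, for which no recovery statement is
meaningful). `generate_mutant_inputs` writes a mutually consistent file
bundle (random 393-residue sequence, mutants whose wild-type letters
match it, PSSM/disorder/structure files) to exercise the full reader +
encoder path.

What passing synthetic tests shows: the ranking, selection and evaluation
machinery recovers planted mean-shift signal under the study's class
imbalances and dimensionalities. What it does not show: anything about
the distribution of real 2D/3D structure descriptors (unknown and not
modelled), epistasis between sites, or label noise in transactivation
assays.

Two properties of the machinery, measured with the generator, deserve
explicit statement because they bound what any user should expect:

- **Redundancy saturation.** When the active class is tiny (scaled
  two-site preset: 5 of 500), every strong informative feature carries
  nearly the same information — pairwise MI ≈ H(label) ≈ relevance — so
  after two or three picks the mRMR criterion of the remaining planted
  features falls to ~0 and weakly relevant noise interleaves. This is the
  redundancy penalty working as designed, not a failure; typical-case
  (median over seeds) recovery is still ≥ 4/5 planted features in the
  top 10.
- **Angular overlap of the cosine metric.** Mean-shifted actives form a
  cone around the all-ones direction; an isotropic inactive vector
  occasionally points into that cone, so even at effect size 6 the
  jackknife MCC on informative-only evaluation is typically 0.9–1.0
  rather than exactly 1.

## Selection optimism

Ranking features and evaluating prefixes on the *same* samples makes the
IFS-optimal MCC an optimistically biased estimate: on a 62 × 5668 table
with purely random features the pipeline happily reports a jackknife
MCC of 1.0 at the optimum, because the ranking stage saw every sample's
label. The jackknife is honest for a *fixed* feature set; it is the
selection step outside the loop that leaks. The effect-size-0 checks in
the test suite therefore evaluate the full (unselected) feature set,
where the expected MCC over seeds is ≈ 0. Users comparing feature sets
should treat the IFS curve as model selection, and validate the chosen
set on held-out data when any is available.

## Numerical and degenerate-input choices

- Natural logs for MI; population sd (ddof = 0) in discretization and
  standardization.
- Discretization of a constant column: single state, equal thresholds.
- MCC zero-denominator → 0; jackknife requires ≥ 2 samples and both
  classes.
- Structure-matrix rows with any missing value (`?`, `NA`, empty) are
  dropped at load with a logged count — these are mutants whose structure
  could not be encoded.
- All randomness flows through one seeded NumPy generator per synthetic
  config; ranking, IFS and jackknife are fully deterministic, so a
  pipeline rerun with the same config and seed is byte-identical.

## Scaling of shipped analyses

The test suite and the acceptance script run at reduced problem sizes
chosen so each stage's behavior is measurable in seconds: preset panels
capped at 500 samples, rankings truncated to the top 30, IFS grids to
k ≤ 30, and small bundles (≤ 62 mutants) for full-pipeline runs. These
sizes are the package's own verification conditions; the code paths are
identical at full scale, and a full-sized two-site panel (16372 × 5929)
is supported through the same readers for users who obtain one.

## Known limitations

- The published SNP (gain/loss) and interface-conservation tables are not
  bundled; the placeholders preserve the pipeline's structure but not
  those two features' biological meaning.
- Headline MCC values published for the real mutant panel are not a
  verification surface here: reproducing them requires the external panel
  itself and the reference ranking program's undocumented discretization
  settings. The readers ingest such a panel unchanged; only the synthetic
  properties above are asserted.
- Single nearest neighbor only; no k > 1, distance weighting, or
  alternative metrics.
- The mRMR implementation is the difference (D − R) criterion; quotient
  variants are not provided.
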