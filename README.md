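# p53act

Predicting the transcriptional activity of multi-site p53 mutants from
hybrid sequence and structure features.

p53 is a 393-residue tumor suppressor; most cancer-associated mutations are
amino-acid substitutions in its DNA-binding core domain, and different
substitutions (and combinations of up to four simultaneous substitutions)
can leave the protein active or abolish transactivation. `p53act`
implements a complete feature-selection + classification analysis for
labeling such mutants active/inactive:

1. **Hybrid encoding.** Each mutation site is described by the 9-residue
   window centred on it (site ± 4 residues) through eight feature families:
   evolutionary gain/loss propensity (SNP), protein-interface conservation
   propensity (pro-pro), the five Atchley physicochemical factors, PSSM
   conservation probabilities (PSI-BLAST), per-residue structural disorder
   (VSL2-style scores), the Grantham distance of the substitution,
   inter-site distances, and 5408 precomputed structure descriptors
   (V1–V4826: 2D surface map of the mutant homology model; V4827–V5408: 3D
   Cα distance-difference map against wild type). The assembled vectors
   have exactly 5668 / 5929 / 6190 / 6451 dimensions for 1 / 2 / 3 / 4
   mutation sites.
2. **mRMR ranking.** Features are ranked greedily by maximum relevance,
   minimum redundancy: round *h* selects the feature maximizing
   `I(f; c) − (1/m) Σ_{g∈selected} I(f; g)`, with mutual information
   computed on 3-state discretized features (split at mean ± 0.5 sd).
3. **IFS.** Incremental feature selection evaluates the nested top-*k*
   prefixes of the ranking and picks the smallest *k* maximizing the
   cross-validated MCC.
4. **Evaluation.** A nearest-neighbor classifier under the cosine-style
   distance `D(v₁,v₂) = 1 − ⟨v₁,v₂⟩/(‖v₁‖‖v₂‖)`, scored by jackknife
   (leave-one-out) cross-validation and the Matthews correlation
   coefficient `MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`,
   which stays informative under the severe class imbalance of p53 mutant
   panels (e.g. 57 active vs 16315 inactive two-site mutants).

A synthetic-data module generates labeled feature tables at the exact
study dimensionalities (with planted informative and redundant features)
and self-consistent input-file bundles, so the whole pipeline is testable
without downloading the external mutant panel. Real data in the supported
dialects (mutant list, FASTA, PSI-BLAST ASCII PSSM, disorder table, V1–V5408
structure matrix) drop straight in.

## Worked example

Simulate a one-site panel with the study's class balance (62 mutants, 7
active) and run the full pipeline:

```bash
p53act simulate --preset one-site --seed 1 --out-dir demo/inputs
p53act run --mutants demo/inputs/mutants.tsv \
           --fasta demo/inputs/wild_type.fasta \
           --pssm demo/inputs/pssm.txt \
           --disorder demo/inputs/disorder.tsv \
           --structure demo/inputs/structure_features.csv \
           --k-sites 1 --kmax 20 --out-dir demo/run
```

prints

```
dataset: 62 mutants x 5668 features (7 active / 55 inactive)

optimal feature set: 12 features, jackknife MCC = 1.0000
family breakdown: 2D structure: 9, 3D structure: 3

top of the mRMR ranking:
    1  V285                         criterion +0.143689
    2  V1572                        criterion +0.085978
    ...
```

Every intermediate (feature table, ranking, IFS curve, optimal set) is
persisted under `demo/run/` together with `report.json`. Note what this
particular run demonstrates: the simulated bundle has *no* planted
label signal, yet the optimum reports MCC = 1.0 — with 62 samples and 5668
features, ranking and evaluating on the same data lets selection bias
manufacture a perfect-looking jackknife score. `docs/methods.md` discusses
this optimism and how the test suite controls for it.

With a genuinely planted signal the pipeline recovers the right features:

```python
from p53act import (SyntheticConfig, generate_table, discretize_table,
                    mrmr_rank, ifs_run)

config = SyntheticConfig(k_sites=1, n_active=15, n_inactive=45,
                         n_informative=5, effect_size=6.0, seed=0)
table, informative = generate_table(config)
ranking = mrmr_rank(discretize_table(table), n_select=30)
print("planted:", sorted(informative))
print("top 10 :", ranking.top(10))
curve = ifs_run(table, ranking, k_max=30)
print(f"IFS optimum: {curve.optimal_k} features, jackknife MCC = {curve.optimal_mcc:.3f}")
```

```
planted: ['V1647', 'V4396', 'V4723', 'V872', 'V882']
top 10 : ['V872', 'V275', 'V882', 'V4396', 'V4723', 'V1647', 'V2056', 'V293', 'V5362', 'V1024']
IFS optimum: 9 features, jackknife MCC = 1.000
```

All five planted features sit in the top 10, and the IFS curve peaks at a
small feature count.

## Layout

- `src/p53act/encoding.py` — feature-space geometry, windows, per-site
  blocks, table assembly, feature-name grammar
- `src/p53act/tables.py`, `src/p53act/data/` — bundled lookup tables
  (Grantham, Atchley factors, wild-type p53 FASTA; SNP/pro-pro files are
  labeled placeholders — see their headers for how to substitute the
  published values)
- `src/p53act/mrmr.py` — discretization, mutual information, greedy mRMR
- `src/p53act/evaluate.py` — cosine NN, jackknife, MCC
- `src/p53act/ifs.py` — IFS curve and feature-family summaries
- `src/p53act/synthetic.py` — generators and the four study presets
- `src/p53act/pipeline.py`, `src/p53act/cli.py` — orchestration and the
  `p53act` command-line interface
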