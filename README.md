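# ppaffinity

Statistical prediction of protein–protein binding affinity from structure,
and analysis of what limits its accuracy.

High-throughput scoring functions predict a complex's affinity
(pKd = −log₁₀ Kd, Kd in molar) from features of the bound structure.
For protein–protein complexes this works markedly worse than for
protein–small-molecule complexes, and much of the gap traces back to the
*training data*: crystal resolution, missing binding-assay metadata and
curation errors in structure–affinity databases. This package implements
the full analysis pipeline needed to quantify those effects:

- **Curation** — PDB parsing into dimer entries (receptor/ligand chain
  groups), with filters for ambiguous or conflicting affinities, multiple
  ligands, multimers, missing coordinates and inter-chain steric clashes;
  every exclusion is logged with a reason.
- **Interface features** — inter-chain interaction counts (hydrogen bonds,
  salt bridges, disulfides, cation–π, aromatic stacking, hydrophobic and
  van der Waals contacts, by documented geometric criteria), Shrake–Rupley
  solvent-accessible surface area and its change on binding (ΔSASA),
  surface hydrophobicity and surface-tension aggregates, and bound/unbound
  RMSD after Kabsch superposition.
- **Scoring model** — a generalized linear model with Gaussian error and
  logarithmic link, E[pKd] = exp(β₀ + Σᵢ βᵢxᵢ), fitted by IRLS; model terms
  (main effects and pairwise interactions, under the marginality
  constraint) are selected by a genetic algorithm minimising
  AIC = 2k − 2 ln L.
- **Evaluation** — repeated leave-one-out cross-validation with pooled r²
  and RMSD; Fisher z for independent correlations, Williams t for dependent
  correlations sharing the observed affinities, Welch t, Mann–Whitney U,
  and a random-subsampling null distribution.
- **Stratification** — resolution/method strata (e.g. the ≤2.5 Å
  high-resolution subset, the NMR subset), 90 %-identity sequence
  clustering (Needleman–Wunsch + single linkage), within-cluster
  resolution-vs-error correlations, and experimental-condition covariates
  (crystallisation T/pH, assay T/pH, assay method one-hot).
- **Synthetic data** — generators reproducing the statistical structure the
  analysis assumes: y = exp(Xβ) + noise tables with resolution-dependent
  feature degradation and per-assay-method offsets, plus toy PDB dimers
  whose interfaces realise exactly a planted set of contacts.

## Worked example

```sh
python examples/resolution_effect.py
```

```
n = 400 complexes, 204 with resolution <= 2.5 A

full mixture          r2 = 0.689   RMSD = 1.37 pKd
high-res stratum      r2 = 0.794   RMSD = 0.78 pKd
random equal subset   r2 = 0.708   RMSD = 1.49 pKd
```

The generator degrades the features of structures solved worse than 2.5 Å.
Training and cross-validating only on the high-resolution stratum improves
pooled leave-one-out r² and RMSD over the full mixture, while a random
subset of the same size does not — the gain comes from data quality, not
sample size. The other scripts in `examples/` demonstrate curation and
featurization, GA/AIC model selection, assay-condition covariates and the
correlation-comparison statistics, e.g.:

```
$ python examples/compare_correlations.py
independent correlations (Fisher z on r = sqrt(r2)):
  r2 = 0.54 (n = 622) vs r2 = 0.68 (n = 205)
  z = 2.86, two-tailed p = 4.21e-03
```

A command-line interface mirrors the pipeline stages
(`ppaffinity curate / featurize / fit / crossval / compare / stratify /
cluster / simulate`); run `ppaffinity --help`.

## Layout

```
src/ppaffinity/   structures, sasa, features, glm, ga, evaluation,
                  stratify, simulate, cli  (+ data/ parameter tables)
examples/         one narrative script per capability
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   model, assumptions, parameter choices, limitations
```
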