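# Methods

## The scoring model

Binding affinity is modelled on the pKd scale (pKd = −log₁₀ Kd, Kd molar;
higher = tighter binding) as a generalized linear model with Gaussian
error and logarithmic link:

    E[pKd] = exp(η),   η = β₀ + Σᵢ βᵢ xᵢ  (+ pairwise products xᵢxⱼ),
    pKd = E[pKd] + ε,  ε ~ N(0, σ²).

The log link keeps fitted affinities positive and lets features act
multiplicatively; the error is additive on the response scale. Fitting is
iteratively reweighted least squares with working weights μ² and working
response η + (y − μ)/μ, started at β₀ = ln(ȳ) and all other coefficients
0, converged when the relative change in the residual sum of squares
falls below 1e-10 (at most 100 iterations; step-halving guards against
overflow of exp(η)). The log-likelihood is evaluated at the MLE with the
dispersion profiled out (σ̂² = RSS/n), and AIC = 2k − 2 ln L counts the
dispersion in k (k = #coefficients + 1). Counting σ² shifts every AIC in
a dataset by the same constant, so it never changes a ranking; it is the
standard convention for Gaussian likelihoods and is stated here because
other implementations differ.

Responses y ≤ 0 are geometrically meaningful (pKd ≤ 0 means Kd ≥ 1 M) and
do not break the log link, which constrains the *mean*, not the data; the
default API still rejects them loudly (they usually indicate a database
error — affinities mis-entered on the wrong scale are a documented hazard
of large structure–affinity databases) with an opt-in `nonpositive="flag"`
mode that fits anyway and records the offending rows.

## Model selection

Candidate models are bit vectors over main effects and (at level 2) all
unordered feature pairs. With marginality enabled, an interaction may
enter only when both parents are present; after every crossover/mutation
the chromosome is repaired by switching on the parents of any active
interaction, so the constraint holds for every evaluated candidate. The
defaults — population 500, budget of 500 distinct candidates evaluated,
single-point crossover p = 0.9, per-bit mutation p = 0.02, elitism 10,
tournament size 3, stop after 20 generations without improvement — are
exposed in `GAConfig`. Population size and the candidate budget are
deliberately independent knobs, because "500 candidate models" can
reasonably mean either. Every candidate is logged with its AIC and the
minimum-AIC candidate is returned. When the entire admissible space fits
inside the candidate budget (e.g. 113 specs for four features at level 2
with marginality), the budget is spent on complete enumeration instead of
evolution — same cost, exact optimum, and it removes the only way a
stochastic search can miss on a small problem; the evolutionary path is
exercised (and tested) on spaces too large to enumerate.

"Support recovery" in the recovery experiments means the truly active
features are *contained* in the selected model. AIC is not a consistent
selector: it admits a spurious extra term whenever that term improves the
deviance by more than 2, which happens with appreciable probability per
inert candidate term regardless of sample size, so exact support equality
is not a property AIC-based selection can promise. Containment of strong
true effects is.

## Cross-validation and accuracy statistics

Evaluation uses repeated single-complex holdouts: each replicate removes
one randomly chosen complex (sampled without replacement until the data
are exhausted, then reshuffled), refits the entire modelling procedure on
the rest and predicts the held-out pKd. Because one point has no
correlation, r² (squared Pearson) and RMSD are computed on the *pooled*
held-out predictions; per-replicate records are retained. SE(r²) uses the
large-sample SE of r with the delta method; SE(RMSD) propagates the SE of
the mean squared error through the square root. A caution discovered in
testing and worth recording: under single-point holdouts the training
*mean* is an exact affine decreasing function of the held-out value, so a
"predict the training mean" baseline pools to r² = 1 (perfectly
anti-correlated), not 0; an information-free baseline must be independent
of the held-out fold.

Two accuracies are compared with:

- **Fisher z** (independent samples):
  z = |atanh r_a − atanh r_b| / √(1/(n_a−3) + 1/(n_b−3)). Correlations
  are conventionally reported as r², so the function accepts r² and takes
  the square root internally. The plain independent-samples formula
  reproduces the printed reference statistic (z = 2.85 for r² 0.54 vs
  0.68 at n 622 vs 205) to within input rounding, so no
  overlap correction is applied by default.
- **Williams t** (two dependent correlations sharing the observed
  affinities), with n − 3 degrees of freedom; inputs are signed
  correlations since the cross-correlation of two prediction sets can be
  negative. Type-I error is calibrated by simulation (10,000 trivariate
  normal datasets, n = 50) to 0.05 ± 0.01.
- **Welch t** and **Mann–Whitney U** for per-replicate error samples;
  U uses exact enumeration for tie-free samples with n_a·n_b ≤ 400 and
  the tie-corrected normal approximation otherwise.
- **Random-subsampling null**: the accuracy distribution over uniform
  equal-size subsets, with the add-one empirical p-value
  (1 + #{null ≥ observed})/(reps + 1), which cannot return p = 0.

## Structural features

Interaction criteria are heavy-atom geometric predicates (crystal
structures typically lack hydrogens), applied to receptor–ligand pairs
with precedence disulfide > salt bridge > hydrogen bond > cation–π >
aromatic > hydrophobic > van der Waals, so each pair counts once:
disulfide SG–SG ≤ 2.5 Å; salt bridge ≤ 4.0 Å between formally charged
side-chain N/O (Lys NZ, Arg NE/NH*, His ND1/NE2 vs Asp OD*, Glu OE*);
hydrogen bond ≤ 3.5 Å between any N/O pair; cation–π ≤ 6.0 Å from a
charged N to an aromatic ring centroid; stacking ≤ 7.0 Å between ring
centroids; hydrophobic ≤ 4.5 Å between side-chain carbons of apolar
residues; van der Waals ≤ r₁ + r₂ + 0.5 Å for anything unclassified.
Ring-mediated classes are counted at ring level and their member atom
pairs excluded from the lower-precedence pairwise classes. All cutoffs
are a versioned, overridable `InteractionCriteria`; the specific numbers
are conventional mid-range values, and tests verify the implementation
against a brute-force classifier rather than the numbers themselves.

SASA is Shrake–Rupley sampling on a deterministic Fibonacci lattice
(default 960 points/atom, probe 1.4 Å, Bondi radii shipped as data); it
is exact for isolated atoms and within 2 % of the analytic spherical-cap
area on two-atom systems. ΔSASA = SASA(complex) − SASA(receptor) −
SASA(ligand) with both sides taken from the complex coordinates (rigid
approximation): never positive beyond sampling tolerance.

A residue is "surface" when its summed heavy-atom SASA exceeds 5 Ų.
Surface hydrophobicity is the mean over surface residues of a tabulated
per-residue score on a [−1, +2] scale (hydrophilic → hydrophobic; the
shipped table is the Kyte–Doolittle index affinely rescaled, with an
additive −0.05 modulation on chain-terminal residues reflecting the
charged free termini). Surface tension is the *sum* over surface residues
of per-atom contributions (per-element defaults with overrides for
charged side-chain atoms, atomic-solvation-parameter magnitudes). Mean vs
sum is deliberate: the hydrophobicity aggregate is size-independent, the
tension aggregate scales with surface extent. Both tables are shipped as
editable data files and are stand-ins of the standard functional form —
scores can be swapped without code changes, and no result in this package
depends on their particular values beyond ordering.

Bound/unbound comparison uses RMSD after optimal least-squares rigid
superposition (Kabsch, proper rotation enforced); degenerate inputs
(< 3 pairs, collinear sets) are rejected.

## Curation rules

A retained entry is a dimer (one chain per binding side unless the
configuration explicitly groups chains) with exactly one consistent
affinity, heavy atoms on both sides, and no inter-group heavy-atom pair
closer than 2.0 Å (well inside any physical non-bonded contact;
configurable). An affinity is ambiguous when duplicate records disagree
by more than 0.5 pKd or any record is an inequality bound. Chains present
in the structure but assigned to neither side mark the complex as having
multiple ligands. Exactly one reason is logged per excluded complex, in a
fixed precedence (missing metadata → ambiguous affinity → multiple
ligands → multimer → missing coordinates → steric clash), so retained +
excluded always partitions the input. Multi-model (NMR) files contribute
only their first model; alternate locations resolve to the
highest-occupancy conformer, ties to first occurrence. Residue numbering
is taken verbatim from the file.

## Stratification

Resolution filters are inclusive (≤ threshold); entries missing the
filtered field are excluded and listed, never imputed — per-analysis
sample sizes therefore shrink, mirroring how condition metadata is
actually distributed in curated affinity sets. Sequence clustering uses
global Needleman–Wunsch alignment (BLOSUM62, gap open −10 / extend −0.5)
with identity = identical positions / alignment length, single-linkage at
the threshold (connected components of the threshold graph), and
lexicographic representatives so the partition is order-independent. A
complex is represented by its chain sequences; within-cluster
resolution-vs-|error| correlations are computed only for clusters of at
least 4 members. The alignment tool and linkage are documented defaults,
not claims about any particular published analysis.

## Synthetic data

The generators encode the minimal structure the analyses presuppose; they
are an emulation of a curated structure–affinity table, not of any real
database. Features: two count-like variables (Poisson(8)/4, Poisson(12)/6)
and two area-like variables (Gamma(2,1)/2). Defaults: n = 500, β₀ = 1.0,
β = (0.3, 0.2, 0, 0) — two active, two inert — σ = 0.2 pKd, giving pKd
values in the familiar 2–14 range. Resolution ~ Uniform[1.5, 3.5] Å. The
resolution effect multiplies a feature-noise SD τ by
1 + γ·max(0, resolution − 2.5): the *latent* predictor uses the degraded
features while the stored table holds the clean draws, so prediction from
the table deteriorates with resolution (equivalent, for difficulty, to
degrading the observed features). The resolution-effect defaults are
γ = 2, τ = 0.3, n = 400. Assay offsets are additive on the pKd scale
(y = exp(η) + ε + δ_method); the assay-effect defaults are δ = +1 for
inhibition, −1 for ITC, 0 otherwise, n = 300. Because the scoring model
is multiplicative and the offsets additive, offsets are estimated from
the method-blind model's residual means per method (centred), which is
consistent when assay method is assigned independently of structure —
individual offsets absorb a shared shift, but contrasts such as
δ̂_inhibition − δ̂_ITC recover the planted value.

Toy dimers place each planted contact in its own slot 20 Å from the next
(beyond every cutoff), with chain bodies 20 Å apart, ring planes
perpendicular to the interface axis so only centroid-based classes fire;
geometry is schematic by design and validates feature bookkeeping, not
energetics. One RNG stream per generated artifact; everything is
bit-reproducible from (config, seed).

What passing on synthetic data does *not* show: real interfaces have
correlated features, non-Gaussian errors, heterogeneous measurement
protocols and curation errors far messier than a single additive offset;
recovery of planted effects here validates the machinery, not predictive
accuracy on real structure–affinity databases.

## Problem sizes and numerical choices

The recovery and phenomenon experiments use 50 seeded replicates at the
generator defaults (n = 500 for recovery, 400 for the resolution effect,
300 for the assay effect), 100-replicate leave-one-out evaluation, a
1000-replicate subsampling control, and 10,000 simulated datasets for the
Williams calibration — sizes chosen so each experiment is statistically
decisive for a directional claim while the whole suite remains a
few-minute desk computation. Ties in altloc occupancy, lexicographic
cluster representatives, and stable sorting in the GA make every
pipeline stage deterministic given its seed.

## Known limitations

- No hydrogen placement or orientation-aware hydrogen-bond geometry;
  criteria are distance-only, heavy-atom based.
- The hydrophobicity and surface-tension tables are documented stand-ins;
  analyses using them should treat the aggregates as relative scores.
- The GLM family is fixed (Gaussian/log); no regularisation, and no
  multiple-testing correction across comparisons (deliberately, matching
  the analysis design this package reproduces — noted, not added).
- ΔSASA uses the rigid approximation (both sides cut from the complex);
  conformational change on binding is visible only through the
  bound/unbound RMSD feature, which requires an apo structure.
- Sequence clustering is O(n²) pairwise alignment; adequate for hundreds
  of complexes, not for database-scale redundancy removal.
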