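# Methods notes

## The model

Peak spectral sensitivity of a cone visual pigment is treated as a linear
function of structural descriptors of its chromophore moiety (the
binding-pocket lysine plus covalently bound 11-*cis* retinal, "LYS+RET",
29 heavy atoms). Per pigment, a trajectory of LYS+RET coordinates is
reduced to seven covariates:

| covariate | meaning | units |
|---|---|---|
| `median_torsion1` | circular median of the C5–C6–C7–C8 torsion (ring linkage) | deg |
| `median_torsion4` | circular median of a polyene-chain torsion | deg |
| `median_torsion14` | circular median of a lysine side-chain torsion | deg |
| `median_torsion15` | circular median of the C7–C6–C5–C18 torsion | deg |
| `median_angle3` | circular median of the CE–NZ–C15 Schiff-base angle | deg |
| `auc_rmsf_ring` | trapezoidal area under the β-ionone-ring RMSF profile | nm·atom |
| `auc_rmsf_lysret` | trapezoidal area under the full LYS+RET RMSF profile | nm·atom |

and λ_max (nm) is modelled as an ordinary least-squares function of a
covariate subset. Subsets are chosen by exhaustive enumeration over all
cardinalities 1..7, retaining the best `nbest` (default 7) per
cardinality by RSS and ranking the retained pool by

    BIC = n·ln(RSS/n) + (k+1)·ln(n),

Gaussian likelihood with additive constants dropped, `k` the number of
slopes. With 7 covariates and `nbest = 7` the retained pool holds
7+7+7+7+7+7+1 = 43 models (cardinality 7 has a single subset). The
selected subset is stress-tested by leave-one-out cross-validation;
the pooled LOO R² is the squared Pearson correlation between held-out
predictions and observed values, with 1 − PRESS/TSS reported alongside
because the two summaries answer slightly different questions.

Two frozen models (torsions in degrees, RMSF areas in nm·atom) are
shipped for reference and prediction: the primary two-term model
(intercept 475.628, slopes −8.720 on `median_torsion15` and +34.925 on
`auc_rmsf_lysret`) and a secondary model built without the cichlid
pigments (intercept 1190.6208, slopes −4.9097 on `median_torsion4` and
+2.9445 on `median_torsion14`).

## Angle descriptors and circular statistics

Dihedrals follow the IUPAC sign convention (looking along the central
bond, clockwise rotation of the far bond is positive) on the branch
(−180°, +180°], computed by the standard two-normal atan2 construction.
The signed dihedral is invariant under rigid motion and under full
reversal of the atom order, and flips sign under mirror reflection;
collinear triples raise an explicit degenerate-geometry error rather
than propagating NaN.

Only two torsions of the descriptor table have canonical atom
quadruples (Torsion 1 = C5–C6–C7–C8 and Torsion 15 = C7–C6–C5–C18).
The remaining thirteen torsions walk the conjugated polyene chain from
the ring to the Schiff base and on down the lysine side chain, and the
four geometric angles sit at sp2 centres along the chain plus the
Schiff-base nitrogen. This default table is an explicit assumption and
every definition can be overridden from a JSON topology file; the CLI
logs the resolved definitions so non-default assumptions are visible in
provenance.

Because torsions are circular, medians are taken after re-branching the
data onto the 360° interval centred on the circular mean; far from the
±180° wrap this reduces exactly to the ordinary median. Mode detection
uses a von Mises kernel density on a 1° circular grid (kernel SD =
`bin_width`, default 8°): local maxima are peaks, minima delimit basins,
frames are assigned to basins, and basins below `min_weight` (default
0.05, small enough to keep a genuine 14 % secondary population and large
enough to drop sampling ripples) are merged into their denser neighbour
until at most `max_modes` (default 2) remain. Mode centre/dispersion are
the circular mean/SD of member frames. This deterministic peak-picking
was chosen over mixture EM: the scientific question is 1-vs-2 modes, not
density estimation. Basin assignment slightly biases weights toward the
narrower component when components overlap heavily; for two components
86/14 at ∓68° the weights are recovered within ±0.03 up to component
circular SDs of roughly 40°, while at a 55° broad component the bias
reaches ~0.05. A two-peak distribution is summarised by the plain
weighted average of its mode centres (weights × centres), the convention
used when reporting a single effective torsion for a bimodal population:
(−68°, 0.86) and (+68°, 0.14) give −48.96° ≈ −49°.

## Superposition and RMSF

Rigid-body motion is removed before fluctuation analysis by weighted
least-squares (Kabsch, batched SVD) superposition, by default iterating
fit-to-mean over all LYS+RET heavy atoms until the mean structure moves
by < 1e-8 nm RMSD (≤ 50 iterations). The absolute orientation of the
converged mean is a gauge choice; all fluctuation statistics are
invariant to it. RMSF is the root of the mean squared 3-D displacement
about the time-mean position, in nm (with nm chosen so the frozen
model's +34.925 slope produces spectral contributions of plausible
magnitude); atoms whose coordinates never change return exactly 0 rather
than rounding residue. Profiles run along a fixed atom order (lysine
backbone → side chain → Schiff base → polyene → ring, methyls beside
their parent atom), and areas are trapezoidal integrals at unit atom
spacing, so a constant profile c over m atoms integrates to c·(m−1).
The ring subset defaults to C1–C6 plus methyls C16–C18 and is
overridable, since "ring heavy atoms" is ambiguous about methyls.

## Synthetic data: what it emulates and what it does not

The generator stands in for production MD output. Frames are built from
internal coordinates by natural-extension (NeRF) chain construction —
main chain from the lysine backbone through the Schiff base to the ring,
methyls as branches, the ring deliberately left unclosed — so that every
named descriptor maps to exactly one placement degree of freedom and a
sampled torsion is realised exactly (second sp2 substituents are placed
at a 180° offset from their sibling's torsion). Descriptor values are
drawn per frame from von Mises distributions or two-component mixtures
(the circular analogue of a Gaussian; mixtures emulate two-peak torsion
populations), then isotropic Gaussian jitter of scale `jitter_scale`
(nm, per coordinate) is added per atom, with optional extra
`ring_jitter_scale` jitter on ring atoms only so ring and whole-moiety
fluctuation are separately controllable. Pure jitter of scale σ gives a
per-atom RMSF of σ√3 (before superposition), which calibrates the
fluctuation machinery; jitter also perturbs extracted torsions, so
round-trip tolerances account for it.

Cohorts receive ground-truth λ_max by pushing each pigment's *extracted*
features (the real pipeline, not the generator inputs) through a
generating linear model — the frozen primary model by default — plus
Gaussian noise of `noise_sd` nm. The packaged demo cohort has 14
pigments sweeping compact→mobile chromophores (jitter 0.008–0.035 nm,
independent ring jitter up to 0.03 nm emulating variable ring–pocket
interaction) with Torsion 15 centres in 0–5°, Torsion 1 near −63°, and
the remaining described descriptors varying independently; generated
λ_max straddle the 495 nm blue/green boundary with several tens of nm of
spread, mirroring the real pigment range. What the generator does *not*
emulate: chemically valid energetics (ideal constant bond lengths and
unsampled angles, no ring closure), autocorrelated dynamics (frames are
i.i.d.), membrane/solvent environment, or any coupling between torsion
state and fluctuation amplitude. Passing tests therefore demonstrate the
correctness of the descriptor → regression machinery under known truth,
not the physical fidelity of any MD protocol.

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; there is no hidden global state, and identical
seeds give bitwise-identical trajectories and cohorts.

## Numerical and design choices

- The RMSF is implemented in the standard root-mean-square form; the
  name, the calibration σ√3 and the profile usage all require the square
  and root even where a source formula might be read without them.
- OLS is solved by SVD (`numpy.linalg.lstsq`), not the normal equations;
  rank-deficient designs raise an error naming the collinear columns,
  and singular subsets inside the enumeration are skipped with a
  warning, never aborting it. R² under zero total sum of squares is
  defined as 0; RSS = 0 maps to a −∞ BIC sentinel with a warning.
- All ranking ties break lexicographically on covariate names, fixing
  determinism.
- LOO folds are ordered by pigment id; a singular fold is marked failed
  and the pooled R² is computed over completed folds with a warning.
- Trajectory readers match atom names case-insensitively; PDB files are
  Ångström on disk and converted to nm, the plain XYZ dialect defaults
  to nm with an Ångström flag.

## Small-sample behaviour of BIC selection

At n = 14, adding one spurious covariate lowers this BIC whenever it
reduces RSS by more than a factor n^(−1/n) ≈ 0.83, which a pure-noise
covariate achieves with probability ≈ 0.18 (the corresponding partial-F
tail with ~10 residual degrees of freedom). With five nuisance
covariates available, the single top-BIC model therefore frequently
carries one spurious term in addition to the true pair, for *any* effect
size — BIC is not selection-consistent at this sample size. The
meaningful selection claims at desk scale, which the test suite asserts
over 100 seeded replicates, are that the top-BIC model contains the
generating pair and that the generating pair is the top-ranked model
among all two-covariate models. Fitted coefficients converge to the
generating values as the response noise shrinks.

## Problem sizes

Tests and examples use cohorts of 14 pigments at 150–400 frames per
trajectory, 10 000-frame series for mode detection, and a 50 000-frame
trajectory for the RMSF calibration — sizes at which every quantity the
package asserts is stable under the seeded generators.

## Known limitations

- Torsions 2–14 and the four geometric angles are assumed definitions;
  analyses of real trajectories should confirm or override them.
- Mode weights are basin counts, biased up to ~0.05 for heavily
  overlapping components (see above); an EM refinement is deliberately
  out of scope.
- The superposition protocol (fit set, reference) is a package choice;
  RMSF values depend on it and should be reported together with it.
- The frozen models carry the units they were printed in (degrees,
  nm·atom); applying them to features computed under other conventions
  is meaningless, so the prediction path never rescales silently.
- No compressed/binary trajectory formats (XTC/TRR/DCD) in this release.
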