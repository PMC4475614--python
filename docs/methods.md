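# Methods

This note documents the statistical and geometric procedures implemented in
`nbsynergy`, the choices made where more than one defensible convention
exists, and what the synthetic-data studies do and do not demonstrate.

## Plate normalisation

A viability plate carries raw 490-nm optical densities (OD) for treated,
vehicle and blank wells. Percent viability at dose *d* is

    response(d) = 100 · (mean OD_treated(d) − mean OD_blank)
                       / (mean OD_vehicle − mean OD_blank)

with the blank term zero when no blank wells exist. Treated wells at dose 0
are folded into the vehicle pool, so the dose-0 anchor is exactly 100 by
construction. A plate whose vehicle mean does not exceed its blank mean is
rejected as degenerate. Normalisation is scale-invariant: multiplying every
OD by a constant leaves responses unchanged. Responses above 100% are kept,
not clipped — clipping would bias the top plateau of the subsequent fit.

## Dose-response model

The fitted model is the normalized log-logistic ("log(inhibitor) vs
normalized response") curve

    Y = 100 / (1 + 10^((X − logIC50) · h)),   X = log10(dose),

with the top plateau fixed at 100 and the bottom at 0, so the predicted
response at the IC50 is exactly 50%. The Hill slope *h* is fitted by
default (`variable_slope=True`) and can be fixed at 1; the variable-slope
model needs at least 4 distinct nonzero doses, the fixed-slope model 3.
Dose-0 points serve only as the normalisation anchor — the model lives on
log dose.

Fitting is bounded least squares (trust-region reflective, analytic
Jacobian) with a deterministic multi-start policy: logIC50 starts at the
dose whose observed response is nearest 50; the slope starts at 1, 0.5 and
2; the lowest-SSE solution wins, ties broken toward |h − 1|. Search bounds
are logIC50 within the observed log-dose range ± 3 decades and h in
[0.05, 10]. There is no randomness in fitting. Optimiser failure is
reported as `converged=False`, never an exception; an all-flat response
vector is likewise reported unconverged.

## IC50 uncertainty

`bootstrap_ic50` uses a residual bootstrap: residuals of the full-data fit
are resampled with replacement, added back to the fitted curve, and each
replicate is refitted starting from the full-data parameters. Two
corrections matter in practice:

* **Shrinkage.** Least-squares residuals understate the error scale;
  resampled residuals are inflated by √(n/(n − p)).
* **Normalisation anchor.** All responses on a plate share the error of
  the vehicle mean they were divided by. When the model knows the vehicle
  anchor's SEM (propagated automatically from the dose-0 point), each
  bootstrap replicate draws a common multiplicative perturbation for the
  whole plate. Because the SEM is itself estimated from few vehicle wells,
  the perturbation is drawn as SEM · t(df = n_vehicle − 1) rather than
  Gaussian. Without this term, intervals are far too narrow: the anchor
  error moves the whole curve coherently and leaves almost no trace in the
  residuals.

Intervals are 2.5/97.5 percentiles of the bootstrap IC50s, widened if
necessary to include the point estimate. Failed refits are dropped and
counted, with a warning beyond 10%. Everything is reproducible given the
seed. On the default synthetic plates (7 doses, 3 replicates, 2% noise)
the measured coverage of the 95% interval is ≈ 92–94% over 200–600
simulated plates, i.e. slightly anti-conservative but above the 90%
working requirement; residual bootstraps on 7-point designs cannot be
expected to be exact.

## Combination index and synergy bands

For the fixed-B/varying-A design, each combination row pairs drug A's IC50
re-measured at a fixed drug-B dose with that B dose. The IC50-equivalent
of a dose is dose / single-agent IC50 (dimensionless, same units), and the
combination index at the 50% effect level is the Loewe-style sum

    CI = e_A + e_B.

CI is computed on unrounded equivalents; 3-decimal half-up rounding is
applied only at report time. (Rounding the addends first can change the
third decimal of the sum, so reports carry the display-rounded unrounded
sum.) The bands are lower-closed/upper-open:

| CI | class |
|---|---|
| < 0.2 | below-scale |
| [0.2, 0.4) | strong synergism |
| [0.4, 0.6) | synergism |
| [0.6, 0.8) | moderate synergism |
| [0.8, 0.9) | slight synergism |
| [0.9, 1.1) | additive |
| [1.1, 1.3] | moderate antagonism |
| > 1.3 | antagonism |

Two conventions required a decision. The published band edges overlap at
their endpoints; this implementation makes every band lower-closed and
upper-open except the top finite band, whose upper edge is closed so that
only CI strictly above 1.3 is antagonism. And the scale stops at 0.2: a CI
below 0.2 is reported as "below-scale" rather than silently promoted to
strong synergism. Both choices are configurable (`RunConfig.ci_bands`).

The isobologram maps each combination to (e_A, e_B); the line of
additivity joins (1, 0) and (0, 1), and a point lies below the line iff
e_A + e_B < 1, which is consistent with the band table relative to 1.

`synergy_table` composes the pipeline: per fixed B dose it fits drug A's
combination IC50, converts to equivalents, sums, and classifies. A failed
fit yields a row flagged `unfit` rather than aborting the table.

## Cohort statistics

Expression values are on the 2log (log base-2) scale and are never
re-transformed. Group associations use the tie-corrected Kruskal-Wallis H
with the chi-square approximation on k − 1 degrees of freedom; two-group
comparisons also use Kruskal-Wallis (equivalent to a rank-sum test up to
the chi-square approximation) rather than switching tests. For very small
samples (total n ≤ 8) an exact permutation p over all label assignments is
computed alongside and reported separately. Unknown annotations ("unknown",
"n.d.", empty) are dropped listwise per test, never imputed.

Correlation significance uses

    t = r / √((1 − r²)/(n − 2)),   df = n − 2,

with a two-sided p. The two-sided choice matches the published cohort
p-values to within the precision allowed by 3-decimal rounding of r (≈10%
relative). |r| = 1 returns the p → 0 limit with a degeneracy flag.

The treated-vs-control viability comparison is a paired t-test, one-tailed
in the direction control > treated. Identical paired vectors give t = 0,
p = 0.5; constant non-zero differences have zero variance and are rejected
as degenerate.

## Consensus binding sites

A pose's contact surface is the set of receptor residues with any heavy
atom within 3.6 Å (Euclidean) of any ligand atom; the boundary is
inclusive. Hydrogens are ignored throughout — crystal structures rarely
resolve them and the 3.6 Å convention is heavy-atom style. Contact
detection uses a k-d tree on the ligand atoms and is exact: tests assert
set equality with an all-pairs oracle on random fixtures.

Conservation scores are computed over the top-K lowest-energy poses
(default K = 50; energy ties broken by input order, deterministically):
score(residue) = fraction of kept poses whose contact surface contains it,
always in [0, 1]. Residues scoring at or above a threshold (default 0.5)
are segmented into sequence-consecutive runs within a chain, bridging gaps
of up to 2 residues; regions are ranked by descending mean score. The
segmentation rule is this package's own plumbing — frequency scoring over
an ensemble does not dictate one — and both parameters are exposed.

Dimer-interface detection lists residue pairs across two chains with any
atom pair within the cutoff, symmetrically. Site comparison reports shared
residues, the Jaccard index (undefined and reported as missing when both
sites are empty) and the Euclidean distance between the two ligands'
unweighted geometric centers.

## Synthetic data

All generators are pure functions of their arguments; the RNG is NumPy's
PCG64 (`default_rng`), pinned by name so fixtures are stable.

* **Plates** use a planted log-logistic truth (default IC50 100, Hill 1,
  seven log-spaced doses, 3 replicates, 3 vehicle wells) with additive
  Gaussian OD noise of 2% of the vehicle baseline — a noise level typical
  of replicate MTS readings. Noise is additive, not proportional; that is
  sufficient for recovery studies and keeps the truth model exact.
* **Combination grids** plant a CI per fixed B dose by construction:
  drug A's true combination IC50 is (CI − b/IC50_B) · IC50_A. The default
  B grid spans 5–25% of the drug-B IC50 so that planted CIs down to ≈0.3
  are realisable at every B dose; a planted CI not exceeding b/IC50_B is
  rejected.
* **Cohorts** draw genes Gaussian on the 2log scale (mean 7, SD 1 —
  typical microarray log-intensity ranges); the target gene is shifted by
  a configurable number of SDs in the older age group (default 1 SD, the
  effect size used for the power study) and the target/partner pair is
  generated bivariate-normal at the target correlation (default r = 0.225,
  the magnitude of the published gene-gene association) via the Cholesky
  construction. MYCN amplification (20%) and INSS stages are assigned
  independently with a 5% unknown fraction.
* **Pose ensembles** place single-atom pseudo-residues on a 5 Å snake
  lattice, plant a contiguous pocket mid-chain, put one ligand atom 3.0 Å
  from each pocket residue, and jitter poses isotropically (default
  0.5 Å), with energies increasing in the jitter magnitude so low-energy
  poses sit closest to the planted site.

What the synthetic studies show — and do not. Passing recovery tests shows
the estimators are correct and calibrated *under the generating model*:
independent Gaussian noise, exact log-logistic truth, clean annotations,
rigid poses. Real plates have edge effects, correlated replicate errors
and occasional outliers; real cohorts have batch structure, probe effects
and non-Gaussian expression; real docking energies are not a clean
function of pose displacement. None of these are simulated, so the
studies validate the machinery, not the published biological numbers.

## Study sizes

The simulation studies use: 100 plates (Hill cycled over 0.5/1/2, 2%
noise) for the IC50-recovery median error; 200 plates × 500 bootstrap
replicates for interval coverage; 200 simulated cohorts of 300 + 300
samples each for the Kruskal-Wallis type-I error and for power at a 1-SD
shift; 50 random 500-atom fixtures for the contact-detection oracle
comparison; and a 60-pose ensemble at 0.5 Å jitter for pocket recovery.
At 200 simulations a proportion near 5% carries a Monte-Carlo standard
error of ≈1.5 percentage points, which bounds how closely the type-I error
can be expected to match its nominal level on any single seed.

## Known limitations

* Only the two-parameter normalized log-logistic family is implemented —
  no 5PL, biphasic or unconstrained-plateau models, no outlier rejection,
  no plate-position correction.
* CI is the simple equivalent-dose sum at one effect level; there is no
  median-effect (Chou-Talalay Dm/m) fitting and no Bliss/HSA/ZIP surface
  models.
* Cohort tools assume preprocessed 2log expression; no microarray
  normalisation, probe mapping, survival analysis or multiple-testing
  correction across cohorts.
* PDB input only (model 1, single altloc), no mmCIF; pose ensembles must
  supply comparable energies — the package consumes docking output, it
  does not dock.
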