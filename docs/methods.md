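# Methods

## Problem and observation model

Electro-/magnetoencephalography (E/MEG) source imaging reconstructs the
primary current density of neural activity from scalp potentials and/or
magnetic fields.  The discretized observation model is

    y = L x + n,        y in R^m,  L in R^(m x 3K),  x in R^(3K),

where `K` source positions each carry three Cartesian dipole components
(`x` is position-major: entry `3i + c` is component `c` of position `i`)
and `n` is zero-mean Gaussian white noise with covariance `sigma^2 I`.
The problem is severely ill-posed and most solvers are depth-biased:
superficial sources dominate minimum-norm-type solutions while deep
(e.g. thalamic) activity is absorbed into superficial surrogates.

## Spherical-head forward model

The simulator uses the classical three-layer concentric-spheres (Ary)
head: radii 87/92/100 mm and conductivities 0.33/0.0042/0.33 S/m for
brain, skull and scalp.  Scalp potentials come from the multilayer-sphere
Legendre expansion.  Per degree `n` the layered conductor multiplies the
infinite-medium dipole harmonic by a transfer factor `T_n` obtained from
a small per-degree linear system (continuity of potential and radial
current at the interfaces, insulating exterior); radii are scaled by the
outer radius so the systems stay well conditioned to degree 100 and
beyond.  For equal conductivities `T_n = (2n+1)/n` exactly, and the
implementation is verified against the closed-form homogeneous-sphere
surface potential to 1e-6 relative error.  Writing the degree-n term
through the Legendre recurrences (`P'` recursion, with the
`n P_n - u P'_n = -P'_{n-1}` identity) keeps every term finite down to a
dipole at the origin.  Electrodes are ideal points in a deterministic
Fibonacci-spiral layout on the upper hemisphere (the reference
experiments publish no coordinates), and columns are average-referenced.

The default series control is degree <= 100 with a 1e-8 relative tail
cut-off, whichever is reached first.  For sources out to 85 mm radius
(`t = b/R <= 0.85`) the worst-case truncation error at degree 100 is of
order 0.1% for the closest electrode-source pairs -- well below the 3%
measurement noise.  Tests that compare against the closed form use
deeper sources and a higher cut-off.

Radial magnetometers sit at the electrode positions scaled by 1.2.  In a
spherically symmetric conductor the volume currents contribute no radial
field, so each MEG lead-field entry is the radial component of the
free-space primary-dipole field, `r_hat . (q x d)/|d|^3` (the constant
mu0/4pi is factored out; entries are in 1/m^2, EEG entries in Ohm/m).
Radial dipoles are exactly silent.  Combined E/MEG stacks the two
systems after multiplying the MEG block by
`c = ||L_EEG||_F / ||L_MEG||_F`.  In the experiment pipeline each
modality receives its own noise (3% of its own maximal clean amplitude,
as each instrument has its own noise floor), the MEG data block is
scaled by the same `c` as its lead field, and the stacked dataset is
max-normalized jointly; the solver's single noise std is the EEG
block's, which equals 3% of the global maximum whenever the EEG block
attains it.  With ideal point electrodes the EEG peak over a shallow
source exceeds the Frobenius-matched MEG maximum by more than an order
of magnitude, so under a homoscedastic noise model the MEG block
carries little effective weight -- a known limitation of this fusion
discussed under limitations.

Measurements: two current dipoles (deep near-thalamic at (7, 0, 5) mm
tilted 68 degrees from radial; superficial near-cortical at
(-50, 7, 71) mm tilted 1 degree -- a best-effort reading of an ambiguous
printed table, overridable per configuration), Gaussian noise with
standard deviation 3% (5% variant) of the maximal clean amplitude, and
the dataset max-normalized to one with `sigma` carried on the normalized
scale.  Source candidates are sampled uniformly in the ball of radius
85 mm (10000 by default), leaving a margin to the brain-compartment
boundary for series accuracy; the nearest candidate to a true dipole is
typically 3-7 mm away at that density, which bounds the attainable
localization accuracy from below.

## Hierarchical model and the IAS optimizer

The prior of `x` is conditionally Gaussian with per-component variances
`theta` drawn from a gamma (G) or inverse-gamma (IG) hyperprior with
shape `beta` and scale `theta0`.  MAP estimation alternates two exact
conditional maximizations (IAS):

    theta_j <- (theta0 + x_j^2/2) / (beta + 3/2)            (IG)
    theta_j <- theta0 (eta/2 + sqrt(eta^2/4 + x_j^2/(2 theta0))),
               eta = beta - 3/2                              (G)
    x <- Theta L^T (L Theta L^T + sigma^2 I)^-1 y

The 3/2 offsets follow from the `theta^(-1/2)` factor of each scalar
Gaussian component; both updates are verified against brute-force scalar
maximization.  Each half-step is exact coordinate descent on the
negative log joint posterior, which is asserted to be monotone in tests.
The x-step uses the m x m data-space system (m <= 204 here, far below
3K) with a symmetric rank-k update and Cholesky solve.

Defaults follow the reference protocol: IG, `beta = 1.5`,
`theta0 = 1e-10`, ten sweeps per resolution level, `sigma` taken from
the simulation truth.  With data max-normalized to one and coarse
coefficients on the amplitude scale of the underlying sources (see the
restriction convention below), `theta0 = 1e-10` lies at the small end of
the workable range: IG-IAS sparsifies wherever the minimum-norm-stage
amplitude exceeds ~sqrt(2 theta0).  A single sweep from a zero initial
guess is a minimum norm estimate with constant variance
`theta0/(beta + 3/2)`; the IG and G iterations tend toward
minimum-support and minimum-current type estimates respectively.

Gamma at `beta = 3/2` needs one guard: its variance update vanishes at
`x = 0`, making the all-zero state a fixed point of the alternating
scheme.  The first sweep's variances are therefore floored at the
hyperprior mean `beta * theta0`, which makes the first step MNE-like;
later sweeps use the exact update.  `theta` is floored at 1e-300
throughout to avoid division overflow.

## Multiresolution decompositions

A decomposition is a nested hierarchy of `L` levels; level `l`
(1 = coarsest) keeps `K_l = round(K s^(l-L))` centers (at least 3,
round-half-even), drawn uniformly without replacement from the next
finer level's centers, the finest level being the full space.  Every
fine position joins its nearest center's subset (ties to the lowest
index).  Defaults `L = 3`, `s = 8` thin 10000 positions to 156 coarse
centers -- comparable to the sensor count, which is what makes a deep
source's broad field pattern detectable before the fine levels restore
resolution.

Restriction convention: a coarse lead-field column is the MEAN of its
member columns, so a coarse coefficient carries the amplitude of the
underlying local current density and estimates keep the same scale on
every level.  This keeps one hyperprior scale valid across levels and
makes the normalized level mean meaningful (below).  The alternative
sum-convention (coefficient = per-member value, columns summed) is
retained behind a flag for diagnostics; under it a coarse coefficient is
~1/s^(L-l) of the source amplitude, which pushes coarse-level IAS below
the IG sparsification threshold at the default `theta0` and bounds the
deep-ROI relative maximum at a few percent -- inconsistent with the
reference results that this package reproduces.

Estimates move between levels by copy-prolongation (each subset value to
all members) and subset-mean restriction (its left inverse, which
preserves constant fields and is adjoint-consistent up to the subset

sizes).

## The RAMUS scan

For each of `D` independently drawn decompositions, IAS runs
coarse-to-fine; initial guesses are chained (level `l` starts from the
level-(l-1) estimate restricted to level l; the first level of
decomposition `k > 1` starts from the previous decomposition's combined
estimate; decomposition 1 starts from zero, making the very first step
an MNE).  The level estimates, prolongated to the fine grid, combine as

    xbar_k = sum_l x_l / sum_l s^(L-l)      (= /73 for L=3, s=8)

-- interpolating a level-l estimate to the fine grid multiplies the
source count by s^(L-l), so the denominator restores the total current
of a source detected identically on all levels -- and the final estimate
is the plain mean of the `xbar_k`.  Averaging over many random
decompositions marginalizes the discretization error of any single
sparse source space (O(D^(-1/2)) by the usual CLT argument), and the
chained initial guesses keep each optimization near the incumbent
optimum so that optimization error does not accumulate.  Deep sources
are typically visible only in the coarse-level terms; superficial
sources survive refinement, which is why the deep relative maximum
saturates around `A_deep / (L * A_sup)` when the deep source is found.

Chaining makes the decomposition sequence a Markov chain; a diagnostic
flag disables it, making the per-decomposition terms independent (and
the result permutation-invariant), at the cost of more frequent local
optima.

## Evaluation

Each reconstruction is scored in two 60 mm diameter spherical ROIs
centred at the true dipole positions: amplitude-weighted center of mass
against the true position; the angle between the vector sum of ROI
moments and the true orientation; log10 of the ratio between the net
ROI moment magnitude and the true amplitude (estimates are first
rescaled by the data normalization factor so this is in source units);
and the relative maximum (max ROI amplitude over the global maximum),
with detection declared strictly above 0.1.  The scalar sum of ROI
amplitudes is exported alongside the vector net moment as a sensitivity
diagnostic.  Case statistics are medians and 5th-95th percentile
intervals (linear interpolation) over independent noise realizations.

Note the center-of-mass measure is conservative for superficial sources:
more than half of a 60 mm ROI around a source at radius 87 mm lies
outside the head, so any spatial spread biases the centroid inward.

When a source goes undetected its ROI holds only diffuse residue whose
center of mass gravitates to the ROI center -- i.e. to the true position
-- so unconditional position errors become spuriously small exactly when
the reconstruction fails.  Position, orientation and amplitude medians
are therefore also reported conditional on the detection criterion;
the reference statistics are effectively conditional as well, since
their detection rates are near 100%.  The detection percentage itself
always refers to all realizations.

## Problem sizes and reproduction

The validation cases (A)-(I) mirror the reference matrix (modality,
sparsity 8 or 5, 100 or 20 decompositions, IG or G hyperprior, deep and
superficial amplitudes 10/0 and 5/7/0, 3% noise, 50 realizations).  The
bundled acceptance script (`scripts/acceptance.py`) re-runs cases (A),
(B), (D) and (H) at the desk-scale protocol -- 25 decompositions and 25
noise realizations on the full 10000-source grid -- and the test suite
replicates the case battery at 25 decompositions and 8 realizations,
sizes chosen so a complete run fits a single workstation CPU session.
Scaled runs are labelled as such in every output table.

## Known limitations

* The forward model is the analytic sphere with point electrodes and an
  average reference, standing in for a finite-element pipeline with a
  complete electrode model; absolute lead-field magnitudes and therefore
  case statistics can differ from FEM-based references at the
  10-30% level, and realistic-anatomy effects are out of scope.
* Point electrodes concentrate the superficial EEG peak that ring
  electrodes (complete electrode model) would average out.  This
  inflates the EEG data maximum relative to the Frobenius-matched MEG
  block, so combined E/MEG adds little deep information here: deep
  localization with E/MEG matches EEG-only instead of improving on it,
  while E/MEG amplitude accuracy degrades (the latter also seen in
  FEM-based references).
* The synthetic data generator shares the lead field with the inverse
  solver (an "inverse crime" in the classical sense), mitigated only by
  the noise model and the dipoles falling between source-grid points;
  real-data performance is not established by these tests.
* Deep-source detection at reduced decomposition counts (D <= 25) is
  stochastic: individual noise realizations can fail to activate the
  deep component even when the full protocol (D = 100) succeeds.
* The gamma-hyperprior branch intentionally reproduces the reference
  behavior (deep activity lost); it is not a recommended operating
  point.
* Exact reference electrode coordinates and the printed dipole table are
  not recoverable from the available text; the defaults are labelled
  assumptions and overridable.
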