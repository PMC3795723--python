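# Methods

## Model

A voxel's diffusion ODF (dODF) is modelled as a nonnegative mixture

    psi_d = f0 * u + sum_i f_i * psi_i,        i = 1..321,

where `u` is the uniform (unit-sum) ODF representing isotropic background
diffusion, and each component dODF `psi_i` is a common single-fiber profile
centered at axis i. The fiber volume fractions f_1..f_321 form the fiber
ODF (fODF); sparsity — most f_i exactly zero — is the estimation target.
All ODFs are discretised on the 321 antipodally-unique vertices of a
frequency-8 geodesic icosahedron (642 vertices; the subdivision places
vertices along great-circle arcs, giving a worst-case nearest-neighbour
spacing of 8.57 deg). The discretisation bounds everything downstream:
no orientation statement below ~8 deg is meaningful.

Assumptions inherited from the model: diffusion is antipodally symmetric;
a single characteristic profile describes every fiber population (regional
variation of the single-fiber response is ignored); fiber dispersion is not
representable (the sparse solution concentrates volume on discrete axes).

## dODF reconstruction

The dODF is the GQI analytic transform of the signals:
`psi_d(u) = sum_rows S_row * sinc(L * sqrt(6 D b_row) * <g_row, u>)` with
free-water diffusivity D = 2.51e-3 mm^2/s and sampling-length ratio
L = 1.25 (default). The transform is linear in the signals and applies
unchanged to shell, grid, and multi-shell schemes, which is why it is the
single reconstruction offered; at b = 1500 s/mm^2 it yields a deliberately
smooth dODF (peak-to-floor contrast ~2.6 for an FA-0.7 fiber), a fact that
shapes several limitations below.

## Component basis

The characteristic dODF is taken from the most anisotropic voxel available,
scored by the ODF-native statistic (max - min)/mean (no tensor fit needed).
In simulation runs it is built from a noise-free pure single-fiber voxel at
the run's maximum FA. The characteristic deliberately contains *no*
isotropic volume: the uniform regressor already models background
diffusion, and a baseline inside the components lets them absorb the
isotropic fraction during the refit (observed as f0 collapsing to zero and
inflated fiber fractions).

Each component is built by collapsing the characteristic onto an axial
profile p(theta) — value versus axis angle from its peak axis, smoothed by
Gaussian radial-basis (Nadaraya-Watson) regression with sigma = 9 deg —
then evaluating p at every axis's angles and normalising to unit sum. The
9-degree width matches the mesh spacing; the profile realisation assumes
the characteristic is axially symmetric. Zero-mean unit-norm versions of
the columns drive the correlation steps.

## Decomposition

Selection and decomposition repeat on the normalised working vector:
pick the most positively correlated component, peel `epsilon * Psi_k`
(epsilon = 0.05), stop when the best correlation is non-positive or 10
distinct components have been selected (the stop is read literally: the
recursion halts as soon as the active set reaches m, even if the next
selection would revisit a member). In practice the active-set cap is the
binding stop: with anticorrelated far-apart components the maximum
correlation decays only asymptotically toward zero, so an iteration cap
(10,000; a warning, not an error) guards the loop. The first step may use
the least-angle fraction `min_i (c_k - c_i)/(1 - G_ik)` — the smallest peel
after which another component ties the winner — which collapses the long
run of repeated selections of the dominant component into one step; it is
applied to the first decomposition only.

Fractions come from ordinary least squares of the *raw* dODF on
`[u | selected raw components]`, followed by pruning: while any fiber
fraction is negative, remove the most negative and refit; if f0 is
negative, pin it to zero, refit, and re-check the fibers, iterating to a
fixed point. The isotropic regressor is the unit-sum uniform ODF u = e/321
rather than a bare all-ones vector, so the fitted intercept is a volume
fraction on the same scale as the unit-sum components (a pure rescaling
with no effect on the sum-normalised output). Fractions are finally scaled
so `f0 + sum f_i` equals the spin-density proxy — the voxel's mean b0
signal — with the unit-sum version retained for all evaluation.

Per-voxel OLS systems are at most 11 columns; the batch path solves them
from precomputed Gram blocks and maintains all voxels' correlations
incrementally (`c <- c - eps * G[:, k]`), making the cost per iteration one
vector update per live voxel. The batch path is tested to replay the
per-voxel reference exactly.

## Simulator

Signals follow the two-tensor-plus-isotropic-compartment model
`S = S0 [f0 exp(-b v'D0 v) + f1 exp(-b v'D1 v) + f2 exp(-b v'D2 v)]` with
axially symmetric tensors of prescribed FA and mean diffusivity (eigenvalue
offset solved numerically so FA is exact) and D0 = MD * I. Rician noise
replaces S by `sqrt((S+n1)^2 + n2^2)`; its SD is anchored to the b0 image,
sigma = S0/SNR_b0. The stock configurations use a 160-direction (or
55-direction) b = 1500 s/mm^2 shell with one b0, f0 = 0.2, first-fiber
fraction 0.50-0.89 of the fiber volume in 40 multiplier steps of 0.01,
crossing angles 18-88.2 deg in 40 steps of 1.8 deg (start + step*k with 40
values; the stated ranges cannot hold both endpoints at the stated step),
FA in {0.4, 0.5, 0.6, 0.7}, b0 SNR 40 (MD 1.0e-3) or 20 (MD 0.5e-3).
Directions come from a spherical-Fibonacci hemisphere lattice — a
deterministic stand-in for an electrostatic-repulsion table, with ~2%
quadrature anisotropy; a q-space grid generator covers DSI-like schemes.

What the simulator does not emulate: spatial structure (each record is an
independent voxel), T2/eddy/motion effects, regional variation of the
single-fiber response, non-Gaussian compartments, and exchange. Passing
tests therefore demonstrate the estimator's behaviour under the stated
mixture model, not performance on scanner data.

## Evaluation protocols

* Two-peak angular error: the two most prominent resolved orientations
  (peaks of the fODF on the mesh, threshold 0.05 of the unit-sum volume)
  are assigned to the two true axes by the pairing minimising total
  deviation; a single resolved fiber counts twice; no resolved fiber scores
  45 deg, the expected error of a random orientation. The same 45-deg
  penalty is used by the sensitivity/specificity matching protocol.
* Fraction recovery: every nonzero fODF component is assigned to the nearer
  true axis and summed per fiber; both fibers of every voxel enter the
  Pearson correlation, grouped by FA. Peak-value-only and
  cluster-to-top-two-peak variants were evaluated and discard too much
  volume (r ~ 0.25-0.6); the pooled assignment is the documented choice.
* Total fiber volume fraction: `sum_i f_i` (f0 excluded); on a synthetic
  slab of constant fiber content it varies less across crossing and
  single-fiber voxels than the tensor-fit FA map, which dips at crossings.
* Tensor FA: standard log-linear least-squares tensor fit (intercept plus
  six tensor elements), eigenvalue FA clipped to [0, 1]; requires at least
  six diffusion-weighted rows spanning gradient space.

## Problem sizes

The study-scale checks run the full 40 x 40 x 4 grid at 10 noise trials per
cell (64,000 voxels, ~30 s on one CPU), a trial count at which the per-FA
correlations are stable to ~0.002 across seeds. Unit and property tests use
single voxels or dozens of voxels.

## Numerical choices

Vertex merging at 1e-6 (distinct vertices are >= 0.07 apart), antipodal
pairing at 1e-9; antipodal representative: first nonzero coordinate
positive; peak ties break to the lower axis index. Degenerate inputs:
a constant dODF short-circuits to an isotropic-only result; a characteristic
without a peak (max/mean < 1 + 1e-6) is rejected. OLS uses lstsq (or
Gram-block solves in the batch path; the systems are <= 11 columns and well
conditioned after pruning). float64 in memory, float32 on disk.

## Known limitations

* **Greedy pruning is not globally optimal.** The most-negative-first
  removal never re-admits a component, whereas the exhaustive-subset (or
  Lawson-Hanson) nonnegative solution can; on random active sets over this
  correlated basis the two differ in residual on roughly a quarter of
  draws. The greedy rule is retained because it is the method's defining
  refit procedure.
* **Broad components limit support identification.** At b = 1500 the
  single-fiber profile is wide (neighbouring components correlate ~0.97),
  so for two mixed components 30-60 deg apart the single most-correlated
  component is often the axis *between* them; the recursion then never
  admits the exact support, and exact index-level recovery of synthetic
  component mixtures fails in roughly half of random draws. Narrowing the
  components to sigma-wide spikes restores exact recovery but destroys the
  fit to real signals (the isotropic term absorbs nearly all volume), so
  the data-matched width is kept.
* **Flank splitting at moderate crossings.** For noise-free FA-0.7
  crossings the refit sometimes splits one fiber's volume onto two axes
  ~15 deg apart flanking it (the near-collinear design makes flank
  solutions fit marginally better); about a third of grid cells at
  crossings >= 45 deg then exceed the 8-deg two-peak error, with the
  median error at 3.3 deg. Exact per-axis response columns fix crossings
  >= 60 deg but not 45 deg, so the residual failures trace to the b = 1500
  reconstruction blur rather than the profile realisation.
* Fraction-recovery correlations at high FA run a few hundredths above the
  mid-0.8 range, reflecting the pooled-assignment estimate; the FA trend is
  monotone as expected.
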