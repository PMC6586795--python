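# Methods

## Exchange model

A peptide of length L has `L − 1 − #prolines(2..L)` exchangeable backbone
amides: the N-terminal amine back-exchanges too fast to retain label and
prolines have no amide hydrogen. (An optional switch also discounts the
second residue, the convention used by some processing software; the
default follows the single-residue rule.) Side-chain exchangeable
hydrogens are treated as fully back-exchanged by detection time, the
standard bottom-up assumption, so they contribute ordinary protium to the
natural isotope distribution.

Under EX2, site i carries deuterium with probability
`p_i(t) = f·(1 − exp(−(k_ch,i/P_i)·t))`, saturating at the labeling
deuterium fraction `f` (default 0.752 — one volume of protonated sample
diluted with four volumes of 94% D₂O buffer). Under EX1 the spectrum is a
two-population mixture: a closed population with weight `exp(−k_op·t)`
seeing only the EX2 background, and an opened population whose
cooperative sites sit at `f`. Closing is treated as instantaneous
exchange upon opening — the closing rate never appears as a simulated
quantity, only through the regime inequalities. EXX adds a nonzero EX2
background in both populations, which makes the low-mass centroid drift.

## Envelope arithmetic

Natural isotopologue distributions are built by exact per-atom
convolution over NIST terrestrial abundances (via pyteomics' element
tables), aggregated per extra nucleon with the probability-weighted mean
mass carried per bin, truncated at cumulative probability 0.999 and
renormalized. Deuteration adds a Poisson-binomial layer computed by exact
dynamic programming over sites; each deuterium adds 1.00628 Da. Mixtures
(EX1/EXX) are mixed at the deuterium-count-layer level *before* the
natural-envelope convolution, which keeps per-bin mean masses — and hence
centroids — exact. All arithmetic is in neutral-mass space; charge enters
only at the m/z rendering and reading boundaries
(`mz = (M + z·1.007276)/z`).

## Synthetic studies

The generator's defaults are the study conditions of the motivating
experiment: states (apo, Na⁺, Na⁺ + DA), exposures 0.25/1/10/60/480 min,
3 replicates, f = 0.752. Back-exchange is a uniform per-site retention
`1 − BE` applied after labeling (real back-exchange is residue-dependent;
only the per-peptide aggregate is observable anyway). Noise defaults:
1% multiplicative Gaussian noise on stick intensities and a 0.02 Da
Gaussian neutral-mass jitter per spectrum — the published work states no
noise model, so these are assumptions chosen to match typical replicate
scatter of Q-TOF HDX data. Intrinsic rates are user-supplied (log-uniform
draws are available); sequence-dependent intrinsic-rate tables are out of
scope. Maximum-labeled controls place every site at `f` times retention,
so a lossless control measures 0% back-exchange. Everything is a
deterministic function of (seed, design, site models); identical inputs
give byte-identical files.

The default cooperative unit of an EX1 site model spans all exchangeable
amides, making the two-population model exactly self-consistent; partial
(including fractional) units are supported and introduce a mild
model-mismatch bias of a few percent in fitted quantities, which is the
same bias real partially-concerted peptides produce. What passing tests
on these synthetics show is that the estimators are correct under the
generating model; they cannot certify behavior under real-data artifacts
the generator omits (overlapping peptides in one spectrum, baseline and
peak-picking errors, charge-state disagreement, carryover).

## Bimodal deconvolution

Observed sticks are assigned to integer extra-nucleon bins (spacing
1.0045 Da, uncritical within ±0.3 Da over a typical envelope), normalized
to unit total intensity — abundances are therefore invariant to global
intensity scaling — and fitted by least squares with the amplitude
profiled out in closed form. The bimodal model
`a·[w·B(N, p_low) + (1−w)·B(N, p_high)] ⊛ natural` is optimized from a
deterministic multi-start grid (p ∈ {0.05, 0.2, 0.4, 0.6, 0.75} pairs,
plus degenerate equal-p starts so the bimodal RSS can never exceed the
unimodal RSS); ties break by lowest RSS, then lowest p_low. Binomial
population shapes are used deliberately — per-population p is a single
free scalar.

Model selection is a nested F-test on RSS with (2, n_points − 4) degrees
of freedom at α = 0.05, with two guards: fewer than five informative
peaks (or no residual df) retains the unimodal model, and a fitted
separation below 2 deuteriums across the cooperative unit
(`p_high − p_low < 2/N`) is rejected as not a credible two-population
spectrum — strongly overlapping mixtures are thereby flagged EXX-prone
rather than over-fitted. A unimodal fit already at numerical perfection
(RSS below 1e−14 of the total power) short-circuits the F-test, which
would otherwise be a 0/0 comparison of rounding errors.

Regime calls: EX1 needs a preferred bimodal model at ≥ 2 exposures with
the low-mass centroid drifting ≤ 1.0 Da across the course; larger drift
is EXX; unimodal throughout is EX2; fit failures or single-time support
give "uncharacterized". The 1.0 Da drift threshold and the 2-deuterium
separation rule are package choices (the underlying experiment reports
these regimes qualitatively); both are configurable.

For the opening-rate fit the low-mass abundance is taken from the
bimodal mixture weight wherever that model is preferred; exposures that
are effectively unimodal (fully closed before, fully opened after the
transition) are imputed 1 or 0 by whichever population median the
unimodal deuteration fraction is closer to.

## Kinetics

`y = exp(−k_op·t)` is fitted to the replicate-mean abundances by
unweighted least squares (replicate means, not pooled replicates, since
the abundance series is defined as the mean curve; SDs are carried but
not used as weights). The 95% CI is the asymptotic linearized standard
error with Student's t at n − 1 df; t½ = ln 2/k_op is reported in
minutes and k_op in s⁻¹. A series that never drops below 0.95 carries no
rate information inside the sampled window and raises a below-detection
error instead of returning a boundary fit.

`m_MAX` is scaled by the labeling fraction by default (so BE = 0
corresponds to the achievable maximum; an unscaled mode exists), and the
correlated-amide count divides the BE-corrected population mass gap by
`f·1.00628` — the mass a fully participating amide actually carries at
75.2% labeling — before reporting the [floor, ceil] bracket of the
replicate-mean value.

## Differential statistics

ΔHDX is reference − perturbed (reference = the less-liganded state), so
positive values mean protection upon binding. The propagated SD combines
the two sample SDs (ddof = 1) in quadrature; the global threshold pools
propagated SDs as their RMS over all peptide × time records — the
literal reading of the pooled-σ prescription; dividing by replicate
counts first would shrink the threshold by √2 and is not done. The
threshold uses n = 3 even when a state has six replicates, following the
procedure's explicit n. No multiple-testing correction is applied across
peptides: the compound rule (two consecutive time points at p < 0.01
plus the magnitude threshold) is the procedure, and under a seeded null
its compound false-call rate measures ≈ 0 (per-test rate ≈ 0.011).
Zero-variance degenerate cases: two constant, equal samples give p = 1,
constant unequal samples p = 0, and the variance gate calls two
zero-variance samples equal by convention.

## Numerical and design choices

* Optimizers: `scipy.optimize.least_squares` (bounded, multi-start) for
  envelope fits, `curve_fit` for the decay; tolerances 1e−14 on the
  envelope fits so noise-free round trips recover parameters to ≤ 1e−4.
* Coordinates are 1-based inclusive everywhere; exposure times are
  minutes in files, seconds internally.
* Residue consolidation: shortest covering peptide wins, ties to the
  later start; uncovered residues are NaN/flagged, never zero-filled,
  and export to PDB with a −1.00 B-factor sentinel.
* Problem sizes in the test and acceptance runs (100 refit envelopes, 200
  decay trials, 20 × (85 × 5 × 3) null replications, 400 model-selection
  trials) were chosen to measure each rate at a few-percent resolution
  while keeping the default suite quick to run.

## Known limitations

* At most two populations; no spectral alignment across charge states,
  no profile-mode peak picking, no ion-mobility or retention modeling.
* The F-test's nominal calibration assumes roughly homoscedastic stick
  noise; strongly intensity-dependent noise inflates its type-I error
  (measured ≈ 2% at the default 1% multiplicative noise, within the 5%
  design point).
* CI widths of the decay fit are asymptotic by default; a seeded residual
  bootstrap is available (`ci_method="bootstrap"`), but neither variant
  is expected to reproduce another fitter's CI widths exactly — the
  asymptotic/profile choice of commercial packages is not documented.
* k_cl and per-site k_ch are never estimated from data — only regime
  inequalities and k_op are identifiable in this design.
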