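# Methods

`dfspec` analyzes single-molecule dynamic force spectroscopy (DFS)
experiments in which a protein-protein bond, held between an AFM tip and
a substrate through two poly(ethylene glycol) (PEG) tethers, is loaded at
constant retraction velocity until it ruptures. It also generates
synthetic retraction curves with full ground truth, so every stage of the
analysis is testable without instrument data.

## Bond model

Dissociation follows the Bell-Evans picture of a single sharp barrier at
distance x_beta (nm) along the pulling coordinate:

    k(F) = k0_off * exp(F * x_beta / kBT).

Under a constant loading rate r (pN/s) the rupture-force density is the
first-passage density of this escape process,

    p(F) = (k(F)/r) * exp[(k0_off*kBT/(x_beta*r)) * (1 - e^{F x_beta/kBT})],

with mode F* = (kBT/x_beta) ln(r x_beta / (k0_off kBT)), clamped at zero
below the rate k0_off*kBT/x_beta where the bond predominantly dissociates
thermally. kBT defaults to 4.114 pN nm (25 C) and is configurable
everywhere.

## Tether model

PEG stretching follows the two-state extended freely jointed chain: each
monomer interconverts between a short helical conformer (0.28 nm) and a
longer planar conformer (0.358 nm) under a force-dependent Boltzmann
weight with zero-force free-energy gap 3 kBT favouring the helical state,
multiplied by the Langevin factor coth(a) - 1/a with a = F L_K / kBT
(Kuhn length 0.7 nm), plus a backbone elasticity of 150 pN/nm per 113-mer
chain. The default geometry is two MW-5000 PEG chains in series
(n = 226 monomers, contour length Lc = 80.9 nm). These constants are
literature-typical values for PEG in aqueous buffer, not fitted
quantities, and every one is a config-overridable default.

## Synthetic data

The simulator solves the series balance z(t) = v t = x_tether(F) + F/k_c
for the force at every sample (dense monotone lookup), integrates the
Bell hazard along the trajectory by the trapezoid rule, and draws the
rupture time against a unit exponential variate; the rupture force is
interpolated within the crossing interval and the trace drops to
baseline afterwards. Gaussian force noise (default SD 5 pN) emulates
the photodiode/thermal noise floor.

Default study conditions: six pulling velocities log-spaced over
100-10,000 nm/s (two decades of loading rate), cantilever stiffness
10 pN/nm (soft lever), 20 kHz sampling, and a curve-class mixture of 6%
specific / 2% nonspecific / 92% empty, matching the few-percent adhesion
frequency at which such experiments are run so that Poisson statistics
guarantee predominantly single-bond events. Nonspecific adhesion is
modelled as short FJC tethers (contour length uniform on 5-40 nm) with
exponential-tailed detachment below 50 pN -- the contaminant population
the contour-length gate must reject. Kinetics datasets
(`kinetics_study_config`) enrich the mixture to 75/5/20 and size the
curve count to a target number of gate-surviving events, since curves
without adhesion carry no kinetic information.

What the generator does not emulate: drift and creep, adhesion
hysteresis, approach-phase mechanics, multiple simultaneous tethers,
baseline tilt, and instrument-specific filtering. Passing tests
therefore demonstrate correctness of the analysis under idealized
single-tether statistics, not robustness to every instrumental artifact.

## Event extraction

1. **Detection.** Baseline (median of the final 10% of the trace) is
   subtracted; a 5-sample moving average is used for detection only.
   The candidate is the largest smoothed drop toward baseline within
   <= 3 samples, required to be preceded by a monotone (within noise)
   rising segment; the index is refined on the raw trace and the full
   drop amplitude must exceed the 15 pN threshold. The rupture force is
   the baseline-subtracted raw sample at the refined index, which is
   unbiased under additive noise.
2. **Tether fit.** The stretch region is fit to the extended FJC with
   the contour length and a distance offset free (total least squares).
   Because the distance axis is the commanded retraction -- its noise is
   far below the force noise -- the anisotropic orthogonal-distance
   objective reduces to regressing force on distance through the
   inverted tether model; this exact-regressor limit avoids the
   contour-length bias that isotropic orthogonal distances acquire by
   rectifying force noise through the curvature of z(F). The offset is
   weakly anchored (2 nm scale; the dialect defines distance zero at
   contact), and the fit window is capped at the analysis threshold
   force so that the estimator's precision -- and hence the acceptance
   probability of the next stage -- is uniform across rupture forces.
3. **Contour-length gate.** The Lc histogram (Freedman-Diaconis bins,
   at least 8) is fit to a Gaussian by least squares on the counts, and
   events within one standard deviation of the center are kept,
   boundary inclusive; specific events sit at the two-tether contour
   length while short-Lc contaminants are rejected. The pipeline applies
   the gate per pulling velocity: the capped tether fits carry a small
   velocity-dependent offset, and a single global band would convert it
   into velocity- and force-dependent acceptance.
4. **Loading rate.** OLS slope of force versus time from 90% of the
   peak force up to rupture (minimum 25 samples). Near rupture the ramp
   is closest to linear and the slope approximates the instantaneous
   rate v/(1/k_c + dx/dF); windows starting lower on the ramp
   underestimate that rate severely (by ~40% at 30% of peak) because
   the tether stiffens continuously.

## Kinetic inference

Events are grouped by k-means on log10 loading rate (k-means++, 50
restarts, k defaulting to the number of pulling velocities); the group
table of mean force, mean loading rate, force SD and count is reported.

For parameter estimation the pipeline fits, by iteratively reweighted
least squares with Tukey bisquare weights (tuning constant 4.685, scale
1.4826 x MAD), the per-group mean AND standard deviation of the
detected rupture force to their exact model counterparts under the
constant-velocity trajectory:

    S(F) = exp( -(1/v) * int_0^F k(f) (1/k_c + dx/dF) df ),

with the resulting density convolved with the Gaussian force read-out
noise, left-censored at the analysis threshold (25 pN -- high enough
that detection is complete above it), and corrected for the half-sample
read-out offset. Three simpler textbook expressions are also available
(`fit_bell_evans`): the modal force F*(r) and the (optionally censored)
constant-rate mean. They are retained because they are the forms usually
quoted, but each leaves percent-level systematic force errors -- the
mean-mode (Gumbel) offset gamma kBT/x_beta if modal F* is fit to mean
forces, the loading-rate variation along the pull, and the detection
censoring -- which the exponential map from force intercept to k0_off
amplifies into factor-level off-rate errors.

By default the estimation groups events by their pulling velocity
(exact metadata) rather than by the k-means labels: grouping on noisy
estimated rates re-sorts events between neighbouring groups in a
force-correlated way (the instantaneous rate rises with the rupture
force), which distorts the means of the edge groups by several pN. The
k-means grouping remains available (`fit_grouping="kmeans"`) and is
always reported.

95% confidence intervals are percentile bootstrap-with-replacement
(default B = 1000): events are resampled within their original groups
(avoiding label switching; re-clustering per replicate is available),
the group statistics recomputed and the model refit.

Simulation calibration at the study scales (six velocities, ~400-1000
accepted events) puts the estimator's intrinsic off-rate uncertainty at
roughly 15-25% relative SD -- cluster-mean DFS estimators extrapolate an
exponential two decades below the slowest loading rate, so single-digit
pN force errors translate into tens of percent in k0_off. This is the
dominant limitation of the method, not of the implementation.

## Adhesion-frequency statistics

The binding probability is the bound fraction of contact trials; its
standard error is bootstrap-with-replacement (resampling a binary
vector is drawn through the exact binomial equivalence). The
nonspecific baseline averages the two control measurements
(functionalized tip vs bare surface and vice versa) with errors
propagated in quadrature over 2. A formal specific-vs-nonspecific
comparison (combined-bootstrap 95% CI on the difference, z statistic)
is provided as an extension of the qualitative bar-chart comparison; at
p-hat = 0 the bootstrap degenerates and the result carries a flag
recommending a rule-of-three bound (~3/n). The Poisson single-bond
fraction lambda e^-lambda / (1 - e^-lambda) with lambda = -ln(1-p)
exceeds 97% for adhesion frequencies below ~5.5%, the design rationale
for the few-percent working point.

## Numerical choices

* Tether inversion by Brent root-find (machine-precision round trips);
  the simulator uses a 4096-point monotone lookup instead.
* Trajectory moments by quadrature on a 750-point force grid to 300 pN;
  the read-out-noise convolution uses a +/-4 SD Gaussian kernel with
  zero-padding at the low-force edge.
* IRLS converges when parameters change by < 1e-8 relative; with three
  or fewer points there is no redundancy for robust reweighting and the
  plain least-squares solution is kept.
* Bell-Evans fits are initialized from the OLS line of F vs ln r (the
  modal model is exactly linear in ln r).
* Gaussian histogram fit failures fall back to the sample mean/SD with
  a flag; fewer than 10 events set the degenerate flag.
* All randomness flows through explicit integer seeds;
  the simulator derives one counter-keyed stream per curve, so per-curve
  reproducibility survives reordering.

## Known limitations

* The loading-rate procedure of the original instrument software is not
  public; the windowed-slope estimator here is a declared substitute and
  is config-exposed.
* Recovered off-rates carry the ~15-25% intrinsic statistical
  uncertainty discussed above; comparisons between bonds (lifetime
  ratios) are more stable because shared biases cancel.
* The trajectory model assumes the template tether parameters are exact;
  mis-specified tether elasticity propagates into both Lc and the
  loading-rate model.
* Multi-step unbinding, worm-like-chain elasticity, multiple-bond
  rupture and heterogeneous-barrier (Dudko-Hummer-Szabo) kinetics are
  out of scope.
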