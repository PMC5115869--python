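# Methods

## The system and the question

A fluorescent cyclic-AMP derivative (fcAMP) binds the cyclic
nucleotide-binding domain (CNBD) of HCN2 pacemaker channels with micromolar
affinity. In zero-mode waveguides, binding of a single ligand is read out as
a binary fluorescence signal: acceptor emission under donor excitation
(smFRET) while the ligand is bound, at a 10 Hz camera rate, until the
acceptor bleaches. The scientific question is the kinetic scheme underlying
these binary traces: how many unbound and bound conformations, and with what
rate constants. The package implements the full chain from simulation of
candidate schemes through trace processing and dwell statistics to global
maximum-likelihood model selection.

## Kinetic schemes and analytic oracles

A scheme is an aggregated continuous-time Markov chain: states carry a
class tag (unbound U*, bound B*), binding transitions scale with ligand
concentration (pseudo-first-order, rates in M⁻¹s⁻¹), conformational
transitions do not (s⁻¹). Seven presets span one binding step (model 1,
U1–B1) to a linear six-state chain (model 7, U3–U2–U1–B1–B2–B3); models 3,
5 and 6 add cyclic connectivity (direct binding to the isomerized bound or
from the isomerized unbound state). Rates are stored per preset; generators
Q(c) are built per concentration with rows summing to zero.

Three closed-form oracles anchor the stochastic machinery: the equilibrium
distribution (null space of Qᵀ), the mean class sojourn (first-passage
solve (−Q_cc)t = 1 averaged over the stationary entry distribution), and
the apparent dissociation constant (root of the analytic occupancy curve at
half its saturating value). Simulation, dwell statistics and likelihood are
all tested against these.

## Synthetic data

The generator emulates the recordings the analysis was designed for:

* exact Gillespie paths started from the stationary distribution;
* frame discretization by **majority vote**: a 100 ms frame is labelled
  bound iff the bound-class occupancy within it is ≥ 0.5, matching a camera
  integrating over the frame (sub-frame excursions are unresolved);
* channel synthesis: before the acceptor bleach, bound frames carry the
  FRET amplitude in I_AD (FRET efficiency treated as 1, so no donor signal);
  after the bleach the signal moves to I_DD; I_AA steps once to background
  at the bleach; I_AD additionally receives 10 % of I_DD (cross-talk); all
  channels carry additive Gaussian noise with σ = amplitude / S/N;
* acceptor bleach times are exponential with mean 30 s (configurable; a
  typical recording lasts about a minute), giving observation windows and
  per-concentration event totals comparable to the study cohort
  (≈ 1000 molecules per concentration at 0.1–10 µM, 60 s windows);
* a multisite mode sums n independent single-site paths (tetramer emulation).

What the generator does **not** model: near-field optics of the waveguide,
camera EM-gain noise, donor blinking, diffusive background beyond the
Gaussian noise floor, and coupling between sites of a tetramer. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated statistical assumptions, not robustness to instrument-specific
artifacts.

The static-heterogeneity alternative (two molecular subpopulations with
single-step kinetics, (τ_u, τ_b) = (2 s, 20 s) and (20 s, 2 s) at 1 µM) is
generated by `static_two_population_models`. The ten-fold spread in both
classes with equal cycle times keeps either population from dominating the
pooled statistics, which is the regime the discrimination diagnostics are
meant for.

## Trace processing

Processing follows the study's corrections and gates, in order: (1) count
acceptor bleach steps in I_AA by penalized least-squares binary
segmentation (BIC-style penalty 3·log n; only single-step molecules pass —
one acceptor means one receptor); (2) subtract 10 % of I_DD from I_AD;
(3) subtract the post-bleach mean, optionally removing a slow exponential
drift (τ ≥ 50 s) by a robust soft-L1 fit; (4) idealize the pre-bleach I_AD
(or, in donor-only mode, the post-bleach I_DD) with a two-state
Gaussian-emission HMM (EM with a percentile-based deterministic start plus
seeded random restarts, Viterbi decoding); (5) compute S/N as idealized
amplitude over the RMS of unbound residuals and reject S/N < 2 (strict:
exactly 2 is kept). A 1-state-vs-2-state BIC comparison guards against
splitting pure noise into two levels; molecules failing it are recorded as
having no events. The human visual-inspection step of the original
workflow is replaced by these two objective gates, with the rejection
reason retained for audit. The cohort S/N distribution is summarized by a
maximum-likelihood gamma fit.

## Dwell-time analysis

Dwells are run lengths of the idealized binary sequence × 0.1 s. Two
censoring rules precede every fit: first/last events per molecule are edge
events (truncated by the window or the bleach) and are excluded, and events
shorter than the 200 ms dead time are excluded, with fitted densities
conditioned on duration > dead time (left truncation, not event merging —
the standard testable choice).

Exponential mixtures are fitted by EM on s = t − dead time with multi-start
and fixed seeds. For frame-quantized dwell tables the default likelihood is
the binned one: s is then a multiple of the frame period Δ and the truncated
exponential mixture becomes a mixture of geometrics,
P(s = mΔ) = (1 − q_i)q_i^m with q_i = e^(−Δ/τ_i), with a closed-form EM
update. This matters: the continuous density is degenerate on the atom of
dwells exactly at the dead time, and a spurious sub-frame component will
latch onto it (we observed 2ΔlogL ≈ 2000 artifacts); the binned likelihood
is bounded and calibrated, so the χ²(2 df) likelihood-ratio test between k
and k+1 components behaves. Continuous treatment remains available for
genuinely continuous durations and reproduces the closed-form shifted
-exponential MLE (τ̂ = mean(t − d) for k = 1). Component counts are chosen
by the LR criterion at p < 0.001 with 2 df (conservative at the mixture
boundary — flagged in reports); 95 % confidence intervals are profile
likelihood over a multiplicative grid.

The binding curve is a weighted least-squares fit of B_max/(1 + K_d/c) to
per-concentration bound-frame fractions (weights = frame counts); the bulk
-saturation mode pins B_max = 1.

Heterogeneity diagnostics: per-molecule mean bound/unbound times (≥ 2
analysis events), a log-binned 2-D histogram, and a modality diagnostic —
the BIC difference between 1- and 2-component Gaussian mixtures on log
per-molecule mean bound times (positive favours bimodal, i.e. static
subpopulations). The bimodal call requires strong BIC evidence (ΔBIC > 6)
**and** separated components (Ashman's D = |μ₁−μ₂|/√((σ₁²+σ₂²)/2) > 2):
at large cohort sizes two overlapping Gaussians also out-fit a merely
skewed unimodal distribution, so ΔBIC alone over-calls bimodality. A
dip-type statistic would serve the same purpose; the GMM form was chosen
because it is standard, available, and calibrated without resampling. The pipeline
computes these diagnostics per concentration: pooling concentrations would
manufacture same-class correlations simply because unbound dwell times
scale with ligand. Dwell correlations are Pearson coefficients of log
durations for (U_i, B_{i+1}), (U_i, U_{i+2}) and (B_i, B_{i+2}) pairs of
strictly adjacent analysis events pooled across molecules, with bootstrap
CIs. A sequential single-pathway scheme predicts no correlations; static
subpopulations induce positive same-class correlations.

Tetramer first-step analysis binarizes occupancy counts at ≥ 1, excludes
events touching frames with ≥ 2 sites occupied, errors if more than 20 % of
bound frames are multiply occupied (the concentration is too high to
isolate the first step), and analyzes the result exactly like monomer
dwells.

## Global likelihood and model selection

The data for model selection are binary traces for many molecules at
several concentrations. The likelihood is a hidden-Markov forward pass over
the scheme's states with deterministic class emissions and per-molecule
initial distribution; edge events are included (edge trimming is a dwell
-analysis policy). Because emissions are deterministic, the forward pass
factorizes over runs of equal labels, and within a run the forward vector
advances by cached powers of a fixed step matrix — a full-cohort likelihood
(4 000 molecules × 600 frames) costs a few thousand small matrix-vector
products, numba-compiled, ≈ 10 ms.

Two observation models are implemented:

* **sampled** — the frame label is the class of the state at the frame
  instant; step matrix expm(QΔ)·diag(mask); initial distribution equilibrium
  conditioned on the first observed class.
* **majority** (default for fitting) — the frame label is the majority
  vote over the frame, as the simulator (and a real camera) produces. The
  pair kernel M_o[i,j] = P(label o, X(t+Δ)=j | X(t)=i) is computed exactly:
  uniformize at rate Λ ≥ max exit rate; given N Poisson(ΛΔ) jumps the
  sojourn cells are Dirichlet(1,…,1), so the bound occupancy with k bound
  cells of N+1 is Beta(k, N+1−k) and P(occupancy ≥ ½) = I_{1/2}(N+1−k, k);
  a dynamic program over (state, bound-cell count) sums jump sequences
  exactly, and marginalizing the label recovers expm(QΔ).

The distinction is not cosmetic. Majority voting erases sub-frame sojourns
(a sojourn of length ℓ < Δ/2 never wins a frame; ℓ ∈ [Δ/2, Δ] survives
with probability ℓ/Δ), so fitting majority-vote data with the sampled
-state kernel biases fast rates 7–11 % low — at the edge of the 10 %
recovery requirement. With the exact majority kernel, refits of the
generating schemes at 1000 molecules/concentration recover all Table rates
to within ≈ 2–6 %. The kernel was validated against brute-force
occupancy-bridge Monte Carlo (agreement within MC error with rates scaled
×20). A first-order missed-event correction of the sampled kernel
(excursions shorter than a dead time ≥ Δ absorbed into the flanking class)
is retained as an option; a dwell-density (MIL-style) likelihood variant
was prototyped and rejected — it was substantially more biased on
majority-vote data.

Optimization is over log₁₀ rates (bounds 10²–10⁹ M⁻¹s⁻¹ for binding,
10⁻⁴–10³ s⁻¹ otherwise) with seeded multi-start: starts drawn log-uniform
in practical windows (10⁴–10⁷ M⁻¹s⁻¹, 10⁻²–10¹ s⁻¹), a coarse L-BFGS-B
pass on all starts, and full refinement (relative logL tolerance 1e-8) of
the best two. Ties break to the lexicographically smallest log-parameter
vector. AIC = 2k − 2logL; rankings attach ΔAIC with ties broken toward
fewer parameters. The resimulation check draws a cohort matched in
molecule count, concentrations and window lengths from the fitted model and
compares dwell distributions per class/concentration by two-sample KS.

## Problem sizes and runtime

The verification experiments use: rate recovery at 1000 molecules ×
5 concentrations × 60 s (the study-cohort scale; 1–3 min per scheme on one
CPU); AIC ranking over 20 replicates of 60 molecules × 3 concentrations
(enough that ΔAIC margins exceed the 10-unit threshold by an order of
magnitude); heterogeneity cohorts of 150–1000 molecules × 120 s; oracle
checks at 10⁶ simulated seconds. The pipeline default
(`RunConfig.n_per_conc = 100`) is sized for an interactive run of all
stages in a few minutes; `n_per_conc = 1000` reproduces the study scale.

## Known limitations

* The exact majority kernel treats frames as conditionally independent
  given boundary states, which is exact for the likelihood of one trace but
  assumes frame boundaries align with the path's time origin (true for the
  simulator, and the natural convention for camera data).
* Dwell-level mixture time constants inherit a small residual bias from
  merged sub-frame excursions; the global fit, which models them, does not.
* χ²(2) for the component LR test is conservative at the mixture boundary.
* Within-class state labels of a fitted scheme are identifiable only
  through topology; for linear chains the roles are fixed, but near
  -degenerate cyclic schemes (e.g. the square with a near-zero second
  binding pathway) sit at the identifiability boundary and their recovery
  is not claimed.
* Missed-event correction is first order; it degrades for dead times long
  relative to the fastest within-class exchange.
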