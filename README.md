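# zmwbind

Single-molecule ligand-binding kinetics from zero-mode-waveguide smFRET
recordings: simulation of multi-state binding schemes, trace idealization,
dead-time-aware dwell-time statistics, and global maximum-likelihood
kinetic model selection.

## The problem

Cyclic AMP regulates HCN pacemaker channels by binding their cyclic
nucleotide-binding domain (CNBD) with micromolar affinity. In zero-mode
waveguides, individual binding events of a fluorescent cAMP derivative
appear as a binary smFRET signal at 10 Hz: acceptor emission while the
ligand is bound, until the acceptor bleaches. The analysis question is the
kinetic scheme behind those binary traces — how many unbound (U*) and
bound (B*) conformations, connected how, with what rate constants.

The package implements the full analysis chain for this class of data:

* `zmwbind.models` — candidate schemes (seven presets from a single
  binding step U1–B1 to a six-state chain U3–U2–U1–B1–B2–B3), generator
  matrices Q(c) with pseudo-first-order binding (k_on·[ligand]), and
  analytic oracles (equilibrium occupancy, mean class sojourns by
  first-passage solve, apparent K_d).
* `zmwbind.simulate` — exact CTMC paths, majority-vote frame
  discretization at 100 ms, and synthesis of the four alternating-
  excitation channels (I_DD, I_AD, I_AA, I_DA) with acceptor bleaching,
  10 % cross-talk and Gaussian noise at a set S/N.
* `zmwbind.process` — bleach-step counting (single step required),
  cross-talk and baseline correction, two-level HMM idealization, and the
  S/N ≥ 2 quality gate.
* `zmwbind.dwells` — censored dwell tables (200 ms dead time, edge events
  removed), left-truncated exponential-mixture MLE with χ²(2 df)
  component-count selection, binding curves B_max/(1+K_d/c), per-molecule
  heterogeneity and dwell-correlation diagnostics.
* `zmwbind.fit` — global hidden-Markov likelihood of all molecules across
  all concentrations (exact majority-vote observation kernels), log-rate
  multi-start optimization, AIC ranking, and resimulation checks.
* `zmwbind.pipeline` / `zmwbind.cli` — seeded end-to-end orchestration
  (`zmwbind all --seed 7`), plain TSV/JSON artifacts, figures.

The numbered scripts under `analysis/` run the study end to end:
`01_simulate_cohort.py` → `02_process_traces.py` → `03_dwell_analysis.py`
→ `04_model_selection.py` → `05_figures.py`, writing everything under
`results/run/`.

## The statistics at the core

A scheme is an aggregated Markov model: hidden states are conformations,
the observation is only the class (bound/unbound) of the occupied state.
For an idealized trace o₁…o_T at concentration c the likelihood is a
forward pass with per-frame kernel M(o): because a camera frame reports the
majority class over the frame, the package computes
M(o)ᵢⱼ = P(majority label o, X(t+Δ)=j | X(t)=i) exactly (by uniformization:
with k bound sojourn cells of N+1 in a frame, the bound occupancy is
Beta(k, N+1−k), so P(occ ≥ ½) is a regularized incomplete beta). Models are
ranked by AIC = 2k − 2 ln L over the pooled cohort. Dwell-time mixtures are
left-truncated at the 200 ms dead time and, for frame-quantized dwells,
binned — the truncated exponential mixture becomes a geometric mixture with
q_i = e^(−Δ/τ_i). Component counts use the likelihood-ratio test on a χ²
distribution with two degrees of freedom.

## Worked example

A small seeded run of the first three stages (120 molecules per
concentration at 0.1–10 µM, model-4 ground truth):

```bash
$ python analysis/01_simulate_cohort.py --seed 7
wrote 600 molecule traces at 5 concentrations to results/run/traces

$ python analysis/02_process_traces.py --seed 7
accepted 323/600 molecules (277 rejected by bleach/idealization/SNR gates)

$ python analysis/03_dwell_analysis.py --seed 7
unbound: biexponential 0.67s(77%), 5.61s(23%); mono-vs-bi p = 3.54e-108
bound: biexponential 0.61s(52%), 4.34s(48%); mono-vs-bi p = 2.87e-55
binding curve: Bmax = 0.95, Kd = 1.57 uM
1 uM: per-molecule distribution unimodal (delta-BIC -10.6); dwell
correlations {'U_i,B_i+1': 0.085, 'U_i,U_i+2': 0.081, 'B_i,B_i+2': -0.261}
10 uM: per-molecule distribution unimodal (delta-BIC -8.6); dwell
correlations {'U_i,B_i+1': 0.084, 'U_i,U_i+2': -0.062, 'B_i,B_i+2': 0.075}
```

(the run also prints the 0.1, 0.3 and 3 µM rows, which rest on far fewer
event pairs at this demonstration scale). Reading this: unbound and bound
dwell distributions each need two exponential components (monoexponential
fits are rejected at p ≪ 0.001) — the kinetic signature of an isomerization
on each side of the binding step. The per-molecule means are unimodally
distributed between the two time constants and successive dwells show no
strong correlations, so the two components reflect every molecule
interconverting between modes (dynamic heterogeneity), not two static
subpopulations. The bound probability saturates with an apparent K_d of
1.6 µM, near the analytic half-saturation of the generating scheme
(1.98 µM; the frame-majority discretization trims brief bound visits, so
occupancy-based K_d estimates at this scale sit slightly low). Stage 4
then ranks the candidate schemes by AIC; on such cohorts the four-state
chain wins and the six-state chain adds nothing (see
`results/run/model_ranking.tsv`).

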