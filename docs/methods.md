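# Methods

## The system and the observable

RNA G-quadruplexes (rG4s) fold through partially structured intermediates:
with two of four G-tracts engaged the molecule is a G-hairpin, with three a
G-triplex, and with all four a quadruplex stabilized by K⁺ coordinated
between quartet layers. In the smFRET geometry modeled here, a Cy3/Cy5 pair
flanks the G-rich segment, so compaction raises the proximity ratio
E = I_A/(I_D + I_A). The four folding states map onto four FRET levels;
the defaults use 0.32 (ssRNA), 0.50 (G-hairpin), 0.74 (G-triplex) and 0.92
(G4) with emission s.d. 0.06, the values reported for a three-layer plant
rG4 and its G4-disabled mutant (`ATRG3_MEANS`, `RG4_MEANS` in
`rg4fret.synthetic`). All analyses work on the raw proximity ratio after
background subtraction; no gamma or donor-leakage correction is applied, so
fitted centers are on the same scale as published proximity-ratio
histograms.

## Synthetic data model

A molecule's conformation evolves as a discrete-time Markov chain at the
camera frame interval (default 0.1 s). The default topology is a
birth–death chain: only adjacent states on the folding pathway
interconvert, which is also what the transition density plots of such
constructs show. Per-frame step probabilities default to 0.025 in each
direction (self-probability 0.95 for interior states), giving mean dwell
times of a few seconds — dynamics clearly resolvable at 10 frames/s. The
chain starts at its stationary law by default so equilibrium properties
(occupancies, detailed balance) hold from frame zero.

**Emission.** Given the state, an apparent efficiency E* is drawn from a
Gaussian truncated to [0, 1]; the acceptor channel receives
`total_intensity * E*` and the donor `total_intensity * (1 − E*)`, each
plus a constant background (default 20 counts) and additive Gaussian noise
(default s.d. 30 counts at `total_intensity` = 1000). Truncation rather
than clipping avoids point masses at the boundaries; the Gaussian emission
matches the Gaussian assumptions of the downstream HMM and mixture fits by
construction, which is a deliberate simplification (see Limitations).

**Photobleaching** is single-step and irreversible per channel with
geometric waiting times (default per-frame probability 0.002 per dye, i.e.
a mean photobleaching lifetime of 50 s). After an acceptor bleach the
acceptor falls to background and the donor rises to the full intensity;
after a donor bleach both channels fall to background. Blinking is not
simulated by default, emulating an oxygen-scavenging imaging buffer.

**K⁺ dependence.** The folding (forward) step probabilities are scaled by
a Hill factor `c^h / (c^h + K_half^h)` (defaults h = 1, K_half = 40 mM,
floored at 1e-3 so the chain stays irreducible at 0 mM). With the default
forward/backward asymmetry (0.03/0.01 at saturation) the stationary
G4 occupancy rises monotonically from ~0 at 0 mM to ~0.6 at 150 mM. This
is a qualitative stand-in that reproduces the direction and monotonicity of
the K⁺-driven shift; no kinetic rates for the real constructs are published,
so none of the simulator's rates should be read as estimates of them.
Two-layer constructs can be emulated by raising `K_half`, reflecting their
need for higher K⁺.

**Helicase unwinding mode** (`unwinding_model`) zeroes the folding steps
and activates faster unfolding steps (default 0.05/frame), starting from
the equilibrium occupancy of the base condition — a caricature of
ATP-driven, translocation-based unwinding in which refolding cannot keep
up. It produces the expected signature: the folded population drains and
the unfolded population grows over the recording.

**Seeding.** Each trace's generator is seeded by `(master_seed, index)`, so
trace *i* is identical regardless of how many molecules are simulated, and
identical (config, seed) pairs reproduce datasets bit-for-bit.

## Trace QC

1. **Bleach detection** is a binary-segmentation change-point scan with
   flanking windows (default 5 frames) and a robust noise estimate from
   median successive differences (threshold z = 5). Conformational
   transitions move intensity *between* channels while conserving the sum,
   so they must not be flagged; the two bleach signatures used are a
   collapse of the summed intensity (donor bleach) and a collapse of the
   apparent efficiency below 0.15 with conserved total (acceptor bleach).
2. **Background** is subtracted per trace as the median of the
   post-donor-bleach segment when one exists (both dyes dark there), else a
   configured constant (default 20, the simulator's default baseline).
   Without this correction the proximity ratio is compressed toward 0.5 —
   with the default counts, a true 0.74 state reads 0.731 raw.
3. **Acceptance.** Traces are truncated at the first bleach; rejected when
   a channel shows more than one bleach step (multiple fluorophores), when
   fewer than 30 usable frames remain, when no frame clears the intensity
   floor (10% of the nominal total), or when E < 0.15 for more than half
   of the retained frames. The last rule removes molecules without an
   active FRET pair — e.g. an acceptor that bleached within the first few
   frames, before the change-point scan has a pre-bleach window to compare
   against. Such donor-only traces otherwise masquerade as an extra
   near-zero FRET state and corrupt state-count selection.
4. **Histogram selection.** Each accepted molecule contributes its
   earliest 30–50 usable frames, capping per-molecule influence on the
   population histogram. Earliest-frame selection is deterministic and
   independent of any downstream fit.

## Hidden Markov modeling

A single K-state Gaussian-emission HMM is shared by all accepted traces of
a condition (the conformational states of one construct under one buffer
are common across molecules); per-trace fitting is available by calling
`baum_welch_fit` on a single trace. The forward/backward recursions use
per-frame scaling plus a per-frame max-shift of the emission densities, so
traces of arbitrary length cannot underflow, and are vectorized across
traces. Baum–Welch stops when the log-likelihood improves by less than
`tol` (default 1e-4) or at `max_iter` (200); the implementation verifies
the EM monotonicity guarantee on every run and raises if it is violated
beyond 1e-8 relative. Initialization places means at evenly spaced
quantiles of the pooled observations with sticky transitions
(self-probability 0.95); restarts (default 10) jitter the means under the
run's seed, and the best final likelihood wins. Emission s.d.s are floored
at 0.01 FRET units to prevent variance collapse; a state whose
responsibility mass vanishes is re-seeded at a random observation a limited
number of times. The returned model is always canonically ordered by
ascending mean, so state indices coincide with the folding pathway.

The number of states is chosen by BIC = −2·LL + p·ln(n) with
p = K² + 2K − 1 free parameters (K(K−1) transitions, K−1 initial
probabilities, K means, K s.d.s) and n the pooled frame count. BIC is a
deliberate, fully specified replacement for the variational-Bayes
idealizers often used interactively in this field; on the simulator's
conditions it recovers the generating state count reliably
(tests exercise 20 replicates per configuration).

Viterbi decoding breaks ties toward the lower state index. Idealized traces
are run-length encoded into segments; rare invalid frames inside an
accepted range are filled by nearest-valid interpolation before decoding so
segments stay contiguous.

## Population decomposition and fractions

The pooled selected frames are decomposed into K Gaussian components by
maximum-likelihood EM on the raw samples (not on binned counts — binning
discards information; a weighted least-squares fit to the binned histogram
is available as `method="binned-lsq"` for parity with curve-fitting
workflows, and the two agree on centers to within a bin width). Component
s.d.s are bounded to [0.01, 0.15] so a single broad component cannot
swallow the histogram, and centers can be anchored within ±0.05 of the HMM
state means (`center_anchors`), which stabilizes four-component fits when
one state is sparsely occupied; an anchored component whose weight
collapses is parked at its anchor with ~zero area rather than deleted, so
fractions remain comparable across conditions. Histograms use 0.02-wide
bins on [0, 1], fine enough to resolve peaks separated by ≥ 0.08.

State fractions are peak-area ratios: fraction_i = area_i / Σ areas. The
lowest-center component is the unfolded (ssRNA) pool and the highest the
well-folded pool; intermediates are reported individually rather than
folded into either pool. Confidence intervals come from a molecule-level
bootstrap (resample molecules with replacement, pool, refit from the point
estimate, 200 replicates by default): resampling molecules rather than
frames respects the strong within-molecule correlation of a sticky chain.
Condition comparisons (e.g. before/after helicase + ATP) difference the
canonical, ascending-center components and bootstrap the difference the
same way.

## Transition density plots

TDP coordinates are the fitted state means of the flanking segments, not
raw pre/post frame values, so transitions cluster crisply at state
coordinates. The density is a 50×50 histogram on [0,1]² with optional
Gaussian kernel smoothing (default bandwidth 0.02 FRET units). The
transition-count matrix has a zero diagonal by construction; the
detailed-balance diagnostic z_ij = (n_ij − n_ji)/√(n_ij + n_ji) should be
within ±3 for every populated pair at equilibrium, because a stationary
birth–death chain is time-reversible. Systematic |z| > 3 indicates a
non-equilibrium condition (e.g. active unwinding) or decoding artifacts.

## MST dose-response

Fnorm is the hot-window/cold-window fluorescence ratio in per-mil, with the
vendor-style default windows: cold = 1 s before laser-on, hot = final 1 s
of the 30 s laser-on period (5 s laser-off precedes the pulse). Fnorm is
invariant to overall intensity scaling. Binding curves (Fnorm vs protein
concentration at fixed labeled-substrate concentration) are fit with a Hill
model, baseline + amplitude·cʰ/(EC50ʰ + cʰ), by Levenberg–Marquardt from
multiple EC50 starts spread log-uniformly over the tested range; the Hill
coefficient can be fixed to 1 for mass-action behavior. EC50 confidence
intervals are residual bootstraps (200 replicates). Fits flag
`no_binding_signal` when the amplitude is within twice the residual RMSE
and `ec50_outside_range` when the estimate leaves the tested span.
Substrates are ranked by ascending EC50 (descending affinity); pairs whose
EC50 CIs overlap are flagged indistinguishable.

## Problem sizes used in the automated checks

The headline recovery experiments run the published scale (300 molecules ×
500 frames). Replicated checks (state-count selection, bootstrap-coverage,
Monte-Carlo EC50 calibration) use smaller per-replicate datasets —
50–80 molecules and 80–200 frames — chosen so the full suite completes
comfortably while keeping the state separations, noise levels and QC
identical to the full protocol.

## Limitations

- The emission model is Gaussian by construction, matching the estimators'
  assumptions; real proximity-ratio noise is a ratio distribution with
  E-dependent width plus shot noise, acceptor blinking and spectral
  cross-talk. Passing recovery tests therefore demonstrates correctness of
  the estimators, not robustness to every real-data artifact.
- Kinetic rates, the K⁺→rate mapping, and the unwinding mode are
  qualitative stand-ins; only their structural properties (monotonicity,
  reversibility, direction of population shift) are meaningful.
- Dual-labeling stoichiometry artifacts (molecules carrying two same-color
  dyes) are not simulated; such molecules are FRET-invisible in real
  recordings and the dark-acceptor QC rule removes their closest synthetic
  analogue.
- No dwell-time/rate-constant estimation and no thermodynamic (ΔG, Hill)
  fitting of the K⁺ titration is provided; fractions are reported as peak
  areas only.
- MST traces are modeled as single-exponential depletion; capillary-scan
  QC, temperature-jump analysis and Kd-level thermodynamics are out of
  scope.
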