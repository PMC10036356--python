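# Methods

`mucorheo` analyzes the rheology of native human airway mucus recovered
from endotracheal tubes (ETT): electrolyte quality control and pooling
of individual samples, passive particle-tracking microrheology (PTMR)
of the pooled gels, bulk oscillatory-sweep analysis, and the
concentration scaling of complex viscosity.  Because raw videos and
rheometer traces for this sample type are rarely shareable, the package
carries a first-class synthetic-data module that generates every input
with known ground truth; the measurement chain is validated by
recovering what the generator put in.

## Tonicity QC and pooling

Each ETT sample is characterized by its volume (µL), % solids (w/w) and
Na⁺/K⁺ concentrations (mM).  Derived quantities:

- **fold concentration** = Na / Na_ref, with Na_ref = 120 mM by default.
  The reference is not a measured constant; it is the value against
  which the bundled characterization tables' fold-concentration columns
  are internally consistent (Na/120 reproduces every printed cell to
  ±0.01), and it is configurable.
- **fold concentration with K** = (Na + K)/(Na_ref + K_ref), K_ref = 15
  mM.  Published usage of this column is inconsistent, so the
  convention is configurable and nothing downstream depends on it.
- **2(Na + K)** — the standard surrogate for total electrolyte
  concentration under monovalent-anion charge balance.

A sample is *isotonic* when its fold concentration lies in
[0.85, 1.25]; the window is the tightest round interval that separates
the characterized isotonic cohort (folds 0.86–1.01) from the
non-isotonic one (0.81, 0.83, 1.30).  Exclusion rules (contamination
flags, volume < 100 µL, Na + K < 70 mM) are applied in a fixed priority
order — flags, then volume, then tonicity — so the reported exclusion
reason is deterministic.  Note that curated sample tables may already
be post-selection; re-applying the volume rule to such a table can
exclude a listed sample, so the thresholds are configurable
(`TonicityReference`).

Pooling is modeled as ideal volume-weighted mixing,
c_pool = Σ cᵢvᵢ / Σ vᵢ.  `optimize_mixture` splits candidates into a
low-Na and a high-Na side, gives each side a common aliquot volume, and
scans the one-dimensional family of high/low volume ratios on a
deterministic log grid (bisection refinement; ties broken toward equal
aliquots) to minimize |pooled fold − 1|.  Infeasible constraints raise
rather than silently clipping.  `salt_addition_plan` converts a
concentration deficit to NaCl/KCl masses via
mass = Δc · V · MW (MW 58.44 and 74.55 g/mol); the solid-volume change
from dissolved salt (<0.5% at these masses) is neglected and the output
says so.  Salt can only be added — normalizing a hypertonic pool is
directed to mixing or dilution, and `dilution_plan` uses solids
conservation (v₀ + v_add)·c_target = v₀·c₀.

## Fluid model and trajectory generator

The synthetic material is a **critical gel**: G*(ω) = S·(iω)^α, hence
|G*| = S ω^α and a frequency-flat loss tangent tan δ = tan(πα/2).  The
default α = 0.1856 gives tan δ = 0.300, the hydrogel-like signature
reported for salt-normalized ETT mucus; a Maxwell fluid was rejected
because its tan δ is strongly frequency-dependent, contradicting the
flat loss tangent those sweeps show.  The model is parameterized by
|η*| at 1 Hz (ω₀ = 2π rad/s): S = η₁·ω₀^(1−α).  α = 1 recovers a
Newtonian fluid with D = k_BT/(6πηa).

A bead of radius a (default 0.5 µm, i.e. 1 µm diameter tracers) in such
a gel performs fractional Brownian motion with

    MSD₂D(τ) = 4 D_α τ^α,   4 D_α = 2 k_B T / (3 π a S Γ(1+α)),

exactly the relation the GSER inversion below assumes, so the chain has
closed-form ground truth.  Temperature defaults to 298.15 K
(configurable; the assay is run at room temperature).

Per-axis increments are fractional Gaussian noise with Hurst index α/2,
synthesized by the exact Hosking (Durbin–Levinson innovation)
recursion.  The O(n²) cost is acceptable at the default 1,200 frames
(60 fps); exactness at any n lets small-n covariance tests compare
against a direct Cholesky factorization of the analytic covariance
matrix.  (The source video format is quoted both as 30 s × 60 fps and
as 1,200 frames at 60 fps; the generator defaults to 1,200 frames and
both are supported.)  Localization noise is added post hoc as i.i.d.
Gaussian per frame and axis, producing the standard +4σ² MSD offset
that `static_error_correction` removes.  All generators are pure
functions of (parameters, seed).

**Population mixtures.**  Near the entanglement concentration (~2%
solids) real per-bead PTMR distributions are bimodal — a low- and a
high-viscosity phase.  `simulate_population_mixture` assigns each bead
a component by weighted draw and additionally draws each bead's η
log-normally around its component value (default spread 0.25 decades,
log₁₀ s.d.).  The within-component dispersion reflects the broad
per-bead spread real distributions show within a phase; an idealized
generator with zero within-phase spread makes the empirical median of a
50/50 population a knife-edge statistic (it collapses onto whichever
mode holds the middle order statistic), which is an artifact of the
idealization rather than a property of the assay.  Ground-truth labels
and per-bead η are recorded in the output metadata.

**Rendering.**  Videos are synthesized as integrated 2-D Gaussian spots
(σ = 1.3 px) on a constant background with optional Poisson noise,
16-bit grayscale, 0.1625 µm/px (a typical ×40 air objective).
`peak_counts` is the expected central-pixel count of a pixel-centered
spot.  Out-of-field beads are an error naming the offending tracks.
Not modeled: 3-D defocus, bead–bead hydrodynamics, photobleaching.

**Macro sweeps.**  Frequency sweeps are the analytic critical-gel
moduli; strain sweeps plateau below a critical strain (default 2%) and
decay as a power law above it, with G′ decaying faster than G″ so the
loss tangent rises — ordinary strain thinning.  Technical replicates,
when present in input tables, are averaged arithmetically per grid
point.

**Synthetic cohorts.**  Sample tables draw Na per tonicity class
(hypo ~ N(66, 15), iso ~ N(113, 7), hyper ~ N(155, 10) mM, truncated
positive — class centers mirroring the characterized cohorts),
K ~ N(13, 5) mM, log-normal volumes around 400 µL, and
% solids ~ N(5, 1.5) truncated to [1.5, 10] — the ~5% solids typical of
ETT mucus, which sits at disease-like concentration.

## Tracking

A Crocker–Grier-style chain, re-implemented here:

1. **Band-pass**: Gaussian smooth (σ = noise scale) minus boxcar
   background (width = feature diameter), clipped at zero.  Sub-pixel
   localization assumes band-passed input; residual background under
   the centroid mask biases positions toward the mask center.
2. **Localization**: grayscale-dilation local maxima above an adaptive
   candidate threshold (the larger of 20% of the frame maximum and
   median + 10 scaled-MAD — chosen to survive both raw and zero-clipped
   band-passed frames), refined by an iterative brightness-weighted
   centroid in a circular mask (radius = diameter//2, default 7 px for
   1 µm beads at 0.1625 µm/px).  Duplicate plateau peaks are merged
   keeping the brightest.  On noiseless renders the bias is < 0.05 px;
   at peak SNR ≥ 10 the RMSE is < 0.2 px.
3. **Linking**: greedy nearest-neighbor assignment in order of
   increasing distance (ties to the lower track id), each detection
   used once, with up to `memory` skipped frames.  Global optimal
   assignment was deliberately not used: at PTMR bead densities the
   greedy solution coincides with it, and the linker is documented as
   swappable.
4. **Filtering and drift**: tracks shorter than 60 frames (1 s at
   60 fps) are dropped by default; drift is the cumulative per-frame
   ensemble-mean *displacement* (not position, so staggered track
   starts do not bias it), interpolated across frames with no shared
   bead, and subtracted.  Correction is idempotent and exactly cancels
   a uniform drift.

Pixel convention everywhere: pixel centers at integer coordinates,
origin top-left, x = column.

## Microrheology (MSD → GSER)

Per-track MSD uses the overlapping-pair time average
MSD(kΔt) = ⟨|r(i+k) − r(i)|²⟩ᵢ with lags capped at 1/3 of the track
duration (longer lags have too few independent pairs); pair counts are
recorded and gap frames are excluded pairwise.  Ensembles are
pair-count-weighted means on the shared lag grid — no interpolation.

The inversion is Mason's local power-law GSER:

    |G*(ω)| = 2 k_B T / (3 π a · MSD₂D(1/ω) · Γ[1 + α(1/ω)]),
    G′ = |G*| cos(πα/2),  G″ = |G*| sin(πα/2),  |η*| = |G*|/ω,

with α(τ) the local log-log slope by centered differences (one-sided at
the ends, clipped to [0, 1] with a warning).  The 2/(3π) prefactor
contains the 3/2 conversion from 2-D MSD to the 3-D relation.  Because
integer-frame lag grids are nearly linear in time, adjacent long lags
sit ~1% apart in log τ and finite differences there amplify estimator
noise; `subsample_loglog` (default 8 points/decade) restricts curves to
an approximately log-uniform lag subset before inversion, the standard
preparation for this estimator.  Lag-to-frequency uses ω = 1/τ; queries
in Hz use ω = 2πf by default, with the ω = f reading exposed
(`convention='rad'`) since reported "1 Hz" values are ambiguous between
the two.

Per-bead distributions invert each track separately and evaluate |η*|
at the query frequency by log-log interpolation (no extrapolation —
out-of-range queries raise).  Bimodality is assessed by a 2-component
Gaussian EM fit on log₁₀ η with deterministic initialization at the
25th/75th percentiles, a 200-iteration cap, and is declared when the
minor weight is ≥ 0.2 and the mode separation ≥ 0.5 decades.  The
thresholds are package choices — source reports of bimodality are
qualitative — and are arguments, not constants.  Fits are refused below
10 beads.

Static-error calibration in the full video chain follows the fixed-bead
control: immobilized beads are rendered with the same imaging
parameters, tracked, and the per-axis noise σ read off the flat MSD
plateau (MSD = 4σ²); live MSDs are then corrected by −4σ².  Lags driven
to ≤ 0 by the correction are noise-dominated, floored at 1e-12 µm² and
flagged.

## Macrorheology and cross-scale comparison

The linear viscoelastic regime (LVR) of a strain sweep is the
low-strain-anchored interval where both moduli stay within ±10%
(configurable) of their medians over the three lowest strains; the rule
reproduces an "LVR at ≥ 1% strain" verdict on plateau-then-decay data
and is invariant to rescaling both moduli.  tan δ = G″/G′ with a +∞
sentinel at G′ = 0; max tan δ < 1 over a sweep yields a gel verdict.
Bulk |η*|(ω) = √(G′² + G″²)/ω.

`cross_scale_compare` reports m = PTMR median |η*|(f), b = bulk |η*|(f)
(log-log interpolated), the fold-ratio max(m/b, b/m), and a pass flag
against a stated bound (default 2, the agreement bound used for
heterogeneous low-concentration samples; default comparison frequency
1 Hz).  For a mixture, the matched bulk sweep is generated from the
mixture's *effective* model — weight-averaged α and log-mean η — the
effective-medium compromise between the series (harmonic) and parallel
(arithmetic) coupling bounds of a well-mixed biphasic gel.

## Scaling and statistics

The concentration law is η* = η_ref (c/c_ref)^γ, fit by OLS of ln η on
ln c; γ is the slope, with a t-based 95% CI (degenerate at n = 2).  The
default generator law uses c_ref = 2% solids, η_ref = 0.05 Pa·s at
1 Hz, γ = 3.9 — the entanglement-regime exponent reported for this
mucus type.  Scaling fits use the per-sample *median* per-bead |η*| at
1 Hz as the concentration point, the robust choice given heterogeneous
distributions.

The Wilcoxon rank-sum test is exact by full enumeration of rank
assignments when the pooled sample is ≤ 12 without ties (the cutoff
balances fidelity against the C(n, n_x) enumeration cost), otherwise a
normal approximation with tie and continuity corrections; the method
used is reported.  The exact two-sided p doubles the smaller tail,
capped at 1.  At n = 8 per group the corrected approximation has an
exact null rejection rate of 0.0379 at α = 0.05 — mildly conservative,
inside the [0.03, 0.07] calibration band.  Kruskal–Wallis uses the
tie-corrected H against χ²(k−1); for two groups without continuity
correction it coincides with the rank-sum approximation exactly, which
the tests exploit as a consistency identity.  Verdicts default to
α = 0.05 and p-values are reported raw (no multiple-testing
correction, matching source practice).

## Pipeline, seeds, problem sizes

`run_pipeline` chains QC → pooling → (synthetic) PTMR per concentration
→ matched macro sweeps → scaling fit → group tests into one
JSON-serializable report with provenance (version, master seed, config
hash).  Per-stage seeds are SHA-256 hashes of (master seed, stage
name) reduced below 2³¹, so any stage can be re-run independently and
the whole report is byte-identical for a fixed configuration.

Demonstration and validation runs use deliberately modest sizes —
300–600 frames, 12–150 beads, fields of a few hundred pixels — chosen
so the statistical tolerances quoted above hold with margin while a
full validation sweep stays fast; all sizes are configuration, not
constants.

## Known limitations

- The generator's critical gel has a single power law at all
  frequencies; real mucus shows curvature in G*(ω) outside the decade
  probed here.  Passing recovery tests therefore demonstrate estimator
  correctness, not that real mucus is a critical gel.
- Localization noise is Gaussian and bead-independent; motion blur,
  defocus and bead polydispersity are not modeled, so real static-error
  corrections will be rougher than the synthetic ones.
- The linker does not disambiguate crossing tracks beyond gap memory;
  at high bead density or large displacements per frame it will split
  or swap tracks (the per-bead median downstream is robust to
  occasional splits).
- Mixing is ideal and instantaneous: no osmotic water flux, pH effects
  or mucin biochemistry, and added salt is assumed fully dissolved.
- The effective-medium bulk model for mixtures is a modeling choice;
  real bulk rheometry of a biphasic gel can sit anywhere between the
  series and parallel bounds depending on microstructure.
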