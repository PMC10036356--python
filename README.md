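# mucorheo

Analysis pipeline for the rheology of native human airway mucus
recovered from endotracheal tubes (ETT) — a practical source of real
airway mucus for laboratories studying muco-obstructive lung disease.
ETT samples are often non-isotonic (evaporation, salivary dilution), and
salt content changes mucus biophysics, so usable pools must first be
normalized to physiological tonicity.  `mucorheo` covers the full
workflow:

- **Tonicity QC and pooling** (`sample_qc`): classify samples by fold
  concentration Na/Na_ref, apply inclusion rules, and plan isotonic
  pools either by optimally mixing hypo- and hypertonic samples or by
  direct NaCl/KCl addition (mass = Δc·V·MW), plus PBS dilution to target
  % solids.  The characterization tables of three reference cohorts
  (isotonic ISO, mixed MIX, salt-corrected ADD) ship in
  `mucorheo.datasets`.
- **Particle-tracking microrheology** (`tracking`, `microrheology`):
  band-pass filtering, sub-pixel bead localization, trajectory linking,
  drift correction; time-averaged MSD and Mason's local power-law
  generalized Stokes–Einstein inversion

      |G*(ω)| = 2k_BT / (3πa · MSD₂D(1/ω) · Γ[1+α]),
      G′ = |G*|cos(πα/2),  G″ = |G*|sin(πα/2),  |η*| = |G*|/ω,

  with per-bead |η*| distributions and a Gaussian-mixture bimodality
  test on log₁₀η.
- **Bulk sweep analysis** (`macrorheology`): linear-viscoelastic-regime
  detection in strain sweeps, tan δ gel verdicts, bulk |η*|(ω), and the
  cross-scale PTMR-vs-bulk comparison at 1 Hz.
- **Scaling and statistics** (`scaling_stats`): log-log fits of the
  concentration power law η* ∼ c^γ, exact-enumeration Wilcoxon rank-sum
  and tie-corrected Kruskal–Wallis tests.
- **Synthetic data** (`synthetic_data`): critical-gel fluids
  (tan δ = tan(πα/2), frequency-flat), exact fractional-Brownian bead
  trajectories via the Hosking recursion, rendered 16-bit microscopy
  stacks, macro sweep tables and tonicity cohorts — all pure functions
  of (parameters, seed), so the measurement chain is validated by
  recovering known ground truth.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Pool the non-isotonic reference cohort into an isotonic stock, then
measure a synthetic gel by PTMR:

```python
from mucorheo.datasets import mix_cohort
from mucorheo.sample_qc import TonicityReference, classify_tonicity, optimize_mixture
from mucorheo.synthetic_data import FluidModel, TrajectoryParams, simulate_fbm_tracks
from mucorheo.microrheology import GserConfig, per_bead_eta_distribution

ref = TonicityReference()
for s in mix_cohort():
    print(f"{s.sample_id}: Na {s.na_mM:.2f} mM -> {classify_tonicity(s, ref)}")

recipe = optimize_mixture(mix_cohort(), ref)
for sid, v in recipe.entries:
    print(f"  {sid}: {v:.1f} uL")
print(f"pooled Na {recipe.expected_na_mM:.2f} mM, K {recipe.expected_k_mM:.2f} mM")

gel = FluidModel(alpha=0.1856, eta_1hz=0.05)   # critical gel, tan(delta) = 0.300
params = TrajectoryParams(n_beads=100, n_frames=600, localization_sigma_um=0.02)
tracks = simulate_fbm_tracks(gel, params, seed=7)
dist = per_bead_eta_distribution(tracks, GserConfig(static_error_sigma_um=0.02), f_hz=1.0)
print(f"PTMR median |eta*|(1 Hz) = {dist.median:.4f} Pa s  (truth 0.0500)")
print(f"IQR [{dist.q25:.4f}, {dist.q75:.4f}], bimodal: {dist.bimodal}")
```

prints

```
MIX-1: Na 99.67 mM -> hypotonic
MIX-2: Na 97.14 mM -> hypotonic
MIX-3: Na 155.49 mM -> hypertonic
  MIX-1: 205.4 uL
  MIX-2: 205.4 uL
  MIX-3: 250.0 uL
pooled Na 120.00 mM, K 12.97 mM
PTMR median |eta*|(1 Hz) = 0.0502 Pa s  (truth 0.0500)
IQR [0.0472, 0.0531], bimodal: False
```

The optimizer takes 205.4 µL of each hypotonic sample against 250 µL of
the hypertonic one, landing the pool exactly on the 120 mM sodium
reference (equal 250 µL aliquots would give 117.4 mM — also isotonic).
The PTMR chain then inverts 100 simulated bead tracks back to the
fluid's programmed viscosity within half a percent; a homogeneous
sample is correctly called unimodal.

A command-line layer mirrors the library:

```sh
mucorheo simulate tracks --seed 3 --n 50 --out tracks.csv
mucorheo ptmr --tracks tracks.csv --static-sigma-um 0.02 --out ptmr.json
mucorheo qc --samples table.csv --out qc.json
mucorheo run --seed 1 --out report.json     # full synthetic pipeline
```

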