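# bir2sim

Simulation and analysis toolkit for studying how pathogenic missense
variants destabilize the BIR2 domain of XIAP (residues 163–234) and abolish
its interaction with RIP2 kinase — the molecular defect behind
XIAP-deficient inflammatory bowel disease.

The package has two arms that mirror the two experimental windows onto the
problem:

* **an FCCS arm** — dual-color fluorescence cross-correlation spectroscopy
  quantifies co-diffusion of a GFP-tagged bait and an RFP-tagged prey in
  live cells. `bir2sim` synthesizes two-channel confocal intensity traces
  from Brownian emitters with a known bound fraction, estimates
  auto-/cross-correlation functions, fits the 3D diffusion model and forms
  the relative cross-correlation amplitude (RCA) that proxies the bound
  fraction;
* **a structural arm** — a coarse-grained Gō-type model of a BIR2-like
  fold with temperature replica-exchange Langevin dynamics. Eight variants
  (R166I, R166K, W173G, G188E, L189P, V198M, L207P, H220Y) are encoded as
  contact perturbations in four mechanism classes (hydrophobic-core
  collapse, inter-helix hydrogen-bond loss, spatial rearrangement,
  Zn-finger loss), and trajectory statistics (subset RMSD, RMSF,
  hydrogen-bond occupancy, secondary structure, β-segment separation)
  recover each planted mechanism.

## The statistics at the core

Fluctuation correlation of intensity traces *I<sub>i</sub>*, *I<sub>j</sub>*:

    G_x(τ) = 1 + ⟨δI_i(t) · δI_j(t+τ)⟩ / (⟨I_i⟩⟨I_j⟩),   δI = I − ⟨I⟩

fitted with the multi-component 3D-diffusion model for a Gaussian
detection volume of lateral radius w₀ and axial half-length z₀ = s·w₀:

    G(τ) = 1 + (1/N) Σ_i F_i (1 + τ/τ_i)⁻¹ (1 + τ/(s²τ_i))⁻¹ᐟ²

optionally times a triplet factor 1 + T/(1−T)·e^(−τ/τ_T). The interaction
statistic is the relative cross-correlation amplitude

    RCA = [G_c(0) − 1] / [G_r(0) − 1]

(red-channel denominator by default; the green variant is one flag away),
taken from fitted amplitudes, never from noisy first-lag points.

The structural arm propagates a one-bead-per-residue structure-based model
(harmonic bonds, 12-10 native-contact wells, repulsive non-native core,
harmonic CCHC Zn restraints) with BAOAB Langevin dynamics (γ = 2.0) over
an eight-rung temperature ladder (300.00–325.00 K), attempting Metropolis
neighbour swaps — accept with min(1, exp[(β_m−β_n)(E_m−E_n)]) — on
alternating pairs. Production ensembles are the 300 K rung with the first
half discarded.

## Worked example

Simulate a half-bound mixture and recover the bound fraction via RCA:

```python
from bir2sim import fccs_sim, fcs

species = [fccs_sim.SpeciesSpec("green_only", 25, 25.0, brightness=4.0),
           fccs_sim.SpeciesSpec("red_only", 25, 25.0, brightness=4.0),
           fccs_sim.SpeciesSpec("dual", 25, 25.0, brightness=4.0)]
volume = fccs_sim.DetectionVolume(w0=0.25, s=5.0)
green, red, truth = fccs_sim.simulate_traces(
    species, volume, box_size=3.0, duration=1.5, dt=2e-5, seed=11)
result = fcs.analyze_fccs(green, red, s_fixed=5.0, seed=11)
print(f"planted bound fraction : {truth.bound_fraction_green:.2f}")
print(f"fitted amplitudes      : gg={result.amp_gg:.3f} "
      f"rr={result.amp_rr:.3f} rg={result.amp_rg:.3f}")
print(f"RCA                    : {result.rca:.3f}")
```

prints

```
planted bound fraction : 0.50
fitted amplitudes      : gg=1.160 rr=1.389 rg=0.606
RCA                    : 0.436
```

Half of the green-labelled emitters co-diffuse with red ones, and the
cross-correlation amplitude relative to the red auto-correlation recovers
that fraction to within the single-measurement noise.

The full variant study (9 systems × 3 seeds, REMD plus the FCCS arm,
~5 min on one CPU) runs from the shell:

```sh
bir2 run --out bir2_report
```

and writes `report.json` / `report.csv` / `summary.txt` with, per variant:
hydrophobic-core RMSD (median and Q90), RMSF over the 174–182 / 192–198 /
205–215 regions, 166↔185 hydrogen-bond occupancy, the 198–200 ↔ 206–208
β-segment distance, the 205–215 loop gyration radius, and the RCA. In the
default study the wild type keeps a packed core (core-RMSD Q90 ≈ 0.7 Å),
a ~79% 166↔185 bond occupancy and RCA ≈ 0.63, while every variant shows
its planted defect (e.g. W173G core Q90 ≈ 2.2 Å; R166K occupancy ≈ 56%;
H220Y elevated loop RMSF; G188E widened β-hairpin; all variant RCAs below
the wild type's, most near 0).

Individual stages are exposed as `bir2 simulate-fccs`, `bir2 fit-fcs`,
`bir2 run-remd` and `bir2 analyze-traj`; trajectories are plain
multi-model PDB (or XYZ), correlation data columnar text, reports JSON/CSV.

## Layout

| module                | contents                                                        |
|-----------------------|-----------------------------------------------------------------|
| `bir2sim.fcs`         | correlation estimator, diffusion model, fitting, RCA, text I/O  |
| `bir2sim.fccs_sim`    | Brownian-emitter two-channel synthetic measurements             |
| `bir2sim.cg_remd`     | Gō model, variants, Langevin + replica exchange, reference fold |
| `bir2sim.traj_metrics`| Kabsch, RMSD/RMSF, H-bonds, secondary structure, distances      |
| `bir2sim.pipeline`    | orchestration, selections fixture, catalog, report              |
| `bir2sim.cli`         | `bir2` command group                                            |

See `docs/methods.md` for the models, assumptions, parameter choices and
known limitations.
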