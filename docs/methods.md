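# Methods

## Scope and philosophy

`bir2sim` re-implements, at desk scale, the computational machinery used to
characterize how non-synonymous XIAP BIR2 variants lose the RIP2
interaction: the FCCS mathematics that quantify protein–protein
association in live cells, and the molecular-simulation statistics that
attribute each variant's destabilization to one of four structural
mechanisms. Wet-lab assays, all-atom force-field simulation of the real
protein, and binding free-energy estimation are out of scope. Both data
generators are first-class, tested code: they plant known ground truth
(bound fractions; mechanism-specific contact perturbations) so that every
analysis can be validated against construction rather than against
unavailable experimental data.

## FCCS arm

### Estimator

`fcs.estimate_correlation` computes the direct fluctuation correlation
G(τ) = 1 + ⟨δI_i(t)δI_j(t+τ)⟩/(⟨I_i⟩⟨I_j⟩) over every valid time origin,
with δI taken about the full-trace mean. Lags must be integer multiples of
the sampling interval; the default grid is quasi-logarithmic (multi-tau
style: 16 consecutive multiples, then spacing doubling per octave, 8
points each). The direct O(n·n_lags) form was chosen over FFT or cascaded
multi-tau estimators because it is exact and verifiable against a
brute-force double loop; at trace lengths up to ~10⁶ samples it is far
from the bottleneck. A zero-mean trace is a degenerate input and raises.

### Model and fitting

`fcs.evaluate_correlation_model` evaluates the 1–3-component 3D diffusion
model for a Gaussian detection volume; the triplet term uses the standard
multiplicative factor 1 + T/(1−T)e^(−τ/τ_T) applied to the diffusion sum —
the literature's usual convention, adopted here as an explicit assumption
since only the diffusion part of the model is written out in most
descriptions.

`fcs.fit_correlation` is weighted least squares (lmfit/Levenberg–
Marquardt) with: fractions on the simplex via stick-breaking, positive
diffusion times, optional fixed structural parameter s (the calibrated-
instrument case; s is only weakly identifiable from a single curve),
moment-based initialisation (amplitude from G(0)−1, time scale from the
half-decay lag) and five multiplicatively jittered restarts under a fixed
seed, tie-broken by residual norm. Non-convergence is flagged in the
result, never silent; a curve that never exceeds 1 returns an explicit
amplitude-zero fit with a warning.

One representational choice matters: `FCSModelParams` carries an optional
explicit `amplitude` (zero-lag excess) overriding 1/N. A cross-correlation
curve of non-interacting species has zero expected excess, and an unbiased
fitted amplitude must be free to go slightly negative; a positive-N
parameterisation would rectify the noise and bias the negative control
upward. Auto-correlation fits keep the 1/N form.

### RCA

`fcs.relative_cross_amplitude` forms RCA = [G_c(0)−1]/[G_r(0)−1] from
fitted amplitudes (red-channel denominator by default, green exposed as an
option — reports in this field vary between the two). The reported RCA is
clipped to [−0.1, 1.5] with the raw ratio retained. The bound-fraction
estimate is the bare amplitude ratio; overlap-volume and crosstalk
corrections are deliberately not applied because the measurement model
here has perfectly co-registered volumes and no crosstalk (both
configurable for robustness studies).

`fcs.analyze_fccs` bundles the chain used by the pipeline: fit gg and rr
with one component; fit rg with the diffusion time pinned to the mean of
the two auto times and a sign-free amplitude. Pinning the cross time is
what makes the near-zero-amplitude fit well-posed.

### Synthetic measurements

`fccs_sim.simulate_traces` diffuses point emitters (green-only, red-only,
dual) by independent Gaussian steps (per-axis σ = √(2DΔt)) in a periodic
cubic box and reads out each channel as the brightness-weighted sum of a
3D Gaussian detection profile exp(−2r_xy²/w0² − 2z²/z0²). Defaults used by
the pipeline: w0 = 0.25 µm, s = 5, D = 25 µm²/s (τ_D = w0²/4D = 625 µs,
GFP-like cytosolic diffusion), brightness 4 (arbitrary units — instrument
photon rates are not modelled), box 3 µm (12·w0), Δt = 20 µs, 1.5 s
traces. Periodic wrapping keeps concentration constant, emulating a large
cytosolic pool. Shot noise is optional and off by default so estimator
tests are deterministic given the particle paths; every entry point takes
an explicit seed that is recorded in the ground truth.

What the generator does *not* emulate: photophysics (blinking, bleaching),
spectral crosstalk, cell-boundary confinement, vesicle artifacts, detector
afterpulsing. Passing tests therefore demonstrate the correctness of the
estimator–model–RCA chain on ideal diffusing mixtures, not robustness to
those instrumental effects.

A note on the mean-intensity check: the time-averaged intensity equals
count × brightness × (π/2)^{3/2} w0² z0 / V_box — the integral of the
detection profile — which is the conventional effective volume
π^{3/2} w0² z0 divided by 2^{3/2}. Tests use the physically correct
integral.

## Structural arm

### Reference fold

The paper-scale system (a crystallographic BIR2 structure in explicit
water) is replaced by a packaged *synthetic* BIR2-like fold: 72 beads,
one per residue, ids 163–234. `cg_remd.build_reference_fold` produces it
deterministically as the minimiser of a design cost — bonds at 3.8 Å,
soft excluded volume, harmonic pair targets, a right-handed chirality
bias on helix windows, weak compaction — encoding the topology the
analyses need: helices 163–168 and 181–186 in contact through the
166↔185 pair; a 198–200/206–208 β-hairpin closed by the 201–204 turn; the
11 hydrophobic-core residues (F170, W173, A177, L179, L184, A187, L189,
V198, L207, W210, A216) mutually clustered; the CCHC quartet (C200, C203,
H220, C227) within coordination range; loops 174–182 and 205–215 anchored
to the body. It is labelled synthetic throughout and is not derived from
any deposited coordinates.

### Potential and variants

`build_cg_model` turns a reference geometry into a structure-based (Gō)
model: native contacts are all bead pairs with |i−j| ≥ 2 within 7.0 Å,
each a 12-10 well ε[5(r0/r)¹² − 6(r0/r)¹⁰] at its native distance with
ε = 0.8 kcal/mol; non-native pairs repel as (4.0 Å/r)¹²; consecutive beads
are harmonic (k = 20 kcal/mol/Å²); quartet pairs are excluded from the
contact list and held instead by harmonic Zn restraints (k = 5) so that
losing the Zn genuinely loosens the pocket. The 166↔185 contact is
deepened 2× — it is the surrogate for a specific inter-helix hydrogen
bond and carries more of the interface than generic packing. ε and the
cutoff were chosen during generator construction to put the wild type in
a marginally stable regime at 300 K (core fluctuating but packed), which
is what lets single-residue perturbations express measurable contrasts;
deep in the folded regime all variants look wild-type at desk scale.

Variant perturbations (`apply_variant`, pure function):

* **core_collapse** (W173G, L189P, V198M, L207P): delete every native
  contact of the mutated residue.
* **helix_hbond_loss** (R166I, R166K): delete exactly the 166↔185
  contact.
* **rearrangement** (G188E): weaken (×0.25) contacts involving 187–189
  and the whole 198–208 hairpin. The wider footprint follows the
  mechanism's cascade — the bulky charged side chain pushes the turn
  open, which releases the strands and the V198/L207 packing on them —
  rather than only the turn itself.
* **zn_loss** (H220Y): remove all Zn restraints *and* the quartet
  residues' packing contacts, implementing the lifted spatial
  restriction radiating from the β-structure near C203 and the helix
  near position 220.

C203Y and G204del are carried in the catalog as previously characterized
Zn-finger variants and excluded from the default simulated set.

### Dynamics and replica exchange

Langevin dynamics uses the BAOAB splitting with γ = 2.0 per reduced time
unit and bead mass 1; energies are kcal/mol, lengths Å, temperatures
Kelvin (k_B = 0.0019872 kcal/mol/K). The default step 0.02 and the
exchange default of one attempt per 5000 steps are the reduced-unit
counterparts of a 2 fs step with exchanges every 10 ps. The desk-scale
pipeline shortens the exchange interval to 200 steps so that runs of
2×10⁴ steps still mix across the ladder; the ladder temperatures
(300.00, 303.72, 307.48, 311.26, 315.08, 318.93, 322.82, 325.00 K) are
kept verbatim. Exchange attempts sweep alternating even/odd neighbour
pairs; acceptance is Metropolis, min(1, exp[(β_m−β_n)(E_m−E_n)]), with
velocity rescaling by √(T_new/T_old) on success and per-pair bookkeeping.
Ensembles are collected per rung (continuous temperature); the analysis
ensemble is the 300 K rung with the first half discarded as
equilibration. Constant volume, no barostat: the pressure coupling of the
original protocol has no meaning for a vacuum bead model and is a
deliberate omission.

Run lengths: the pipeline default is 2×10⁴ steps × 8 replicas per system
and seed (three seeds, nine systems), chosen as the scale at which the
planted contrasts separate cleanly while the whole study stays in the
minutes range on a single core. The inner force loop is a numba kernel;
everything else is numpy.

### Trajectory metrics

* **Superposition** — closed-form Kabsch (SVD with determinant
  correction, reflections excluded); degenerate/collinear fits raise.
* **Subset RMSD** — each frame fitted to the *initial* reference over the
  full domain, measured over the named subset (both selections are
  explicit so fit-on-subset is one argument away).
* **RMSF** — frames aligned to frame 0, then once to the mean structure;
  RMSF about the final mean. Mean-structure reference is the common
  convention; the initial-frame alternative differs only in drifting
  ensembles.
* **H-bond occupancy** — geometric criterion (≤3.6 Å, ≥135°
  donor–H–acceptor, acceptors C/O/N/F/S) with the distance measured
  hydrogen-to-acceptor by default and a donor-heavy-atom option, since
  the H-to-acceptor convention, though stated, is unusual. For bead
  ensembles a distance-only surrogate on the 166↔185 pair applies; the
  default cutoff 6.2 Å sits between the native bead distance (5.5 Å) and
  the separated state, and is an explicit parameter everywhere.
* **Secondary structure** — virtual Cα geometry: bend angle at the
  residue and the pseudo-dihedral of four consecutive beads
  (helix: θ ∈ [75°, 108°], φ ∈ [25°, 100°]; sheet: θ ∈ [100°, 155°],
  |φ| ≥ 120°; else coil; termini and chain-break flanks coil). Full
  DSSP is out of scope for bead models; thresholds were set from ideal
  helix (θ ≈ 91°, φ ≈ +50°) and extended-strand (θ ≈ 148°, φ = 180°)
  geometry with generous margins.
* **Segment distance / loop gyration** — unweighted centroid distance
  between the β-segments; the "loop widening" readout is implemented as
  the 205–215 radius of gyration and labelled an interpretation.

## Pipeline and report

`pipeline.run_pipeline` runs WT + 8 variants over 3 seeds (REMD + metrics
+ one FCCS measurement per seed whose planted bound fraction encodes the
interaction phenotype: WT 0.70, R166I/R166K 0.30, others 0.05), aggregates
seeds by median (robust at n = 3), and emits a validated report (pydantic
model; the packaged JSON schema in `data/report_schema.json` is generated
from it) as JSON, tidy CSV and a text summary. Reruns with the same
config and seeds are byte-identical; the config digest is recorded in the
report. Residue selections ship as a versioned YAML fixture validated
against the 163–234 range.

## Numerical choices and degenerate inputs

* Fit restarts are seeded; ties broken by residual norm.
* A single-rung ladder degrades to plain Langevin (documented, not an
  error); identical rung temperatures accept every swap.
* Non-finite energies raise naming the offending term; non-finite
  coordinates are rejected before stepping.
* Zero-lag points are allowed on correlation curves so the measured
  G(0) = 1 + var/mean² can be carried explicitly.
* Uniform fit weights by default; an optional lag-bin-count weighting
  approximates the heavier averaging of long-lag bins on quasi-log grids.

## Known limitations

* The coarse-grained ensembles are a stand-in: absolute RMSD/RMSF values
  and occupancies are not comparable to all-atom, explicit-solvent
  numbers; only the planted qualitative orderings are meaningful.
* Per-rung-pair acceptance profiles are not calibrated to any target;
  only aggregate bookkeeping is checked.
* The bead-pair hydrogen-bond surrogate cannot express angular
  dependence; the geometric criterion applies only to all-atom input.
* The FCCS arm's brightness units are arbitrary; no calibration to
  instrument photon counts is attempted, and the N_c/N_g estimate is the
  bare amplitude ratio without overlap-volume correction.
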