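"""Synthetic two-channel FCCS measurements with known ground truth.

Point emitters perform independent Brownian motion in a periodic cubic box
containing two co-registered (optionally offset) 3D Gaussian detection
volumes, one per spectral channel.  Channel intensity at each time step is
the brightness-weighted sum of the Gaussian detection profile evaluated at
every emitter of that channel; dual-labelled emitters contribute to both
channels and are the sole source of true cross-correlation.  This stands in
for live-cell confocal measurements of GFP/RFP-labelled proteins: the
bound fraction planted in the species table is the quantity the RCA
statistic estimates downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from bir2sim.fcs import IntensityTrace

__all__ = [
    "DetectionVolume",
    "SpeciesSpec",
    "SimGroundTruth",
    "simulate_traces",
    "expected_tau_d",
    "effective_volume",
]

LABELS = ("green_only", "red_only", "dual")


@dataclass(frozen=True)
class DetectionVolume:
    """3D Gaussian confocal detection volume.

    w0 is the lateral 1/e^2 radius in micrometres; the axial half-length is
    z0 = s * w0 with structural parameter s >= 1.  ``offsets`` holds a
    per-channel centre displacement (micrometres) for misregistration
    studies; both default to the origin.
    """

    w0: float
    s: float = 5.0
    offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.w0 > 0:
            raise ValueError("w0 must be positive")
        if not self.s >= 1:
            raise ValueError("structural parameter must be >= 1")
        offs = {ch: np.zeros(3) for ch in ("green", "red")}
        for ch, off in self.offsets.items():
            offs[ch] = np.asarray(off, dtype=float)
        object.__setattr__(self, "offsets", offs)

    @property
    def z0(self) -> float:
        return self.s * self.w0


def effective_volume(volume: DetectionVolume) -> float:
    """Effective confocal volume pi^{3/2} w0^2 z0 in cubic micrometres."""
    return math.pi ** 1.5 * volume.w0 ** 2 * volume.z0


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing emitter population.

    ``brightness`` is photons/s at the volume centre, applied to the
    channel(s) the label emits in (both for ``dual``).
    """

    label: str
    count: int
    diffusion_coefficient: float
    brightness: float = 1.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not self.diffusion_coefficient >= 0:
            raise ValueError("diffusion coefficient must be >= 0")

    @property
    def channels(self) -> tuple:
        return {"green_only": ("green",), "red_only": ("red",),
                "dual": ("green", "red")}[self.label]


@dataclass(frozen=True)
class SimGroundTruth:
    """Planted truth for a simulated measurement.

    ``n_green`` / ``n_red`` are the expected numbers of green- and
    red-labelled particles (dual included) inside one effective volume;
    ``n_dual`` counts dual-labelled ones.  ``tau_d`` maps each species
    label to its expected diffusion time w0^2/(4D).
    """

    n_green: float
    n_red: float
    n_dual: float
    tau_d: dict
    seed: int

    def __post_init__(self):
        if self.n_dual > min(self.n_green, self.n_red) + 1e-12:
            raise ValueError("dual count cannot exceed either labelled total")

    @property
    def bound_fraction_green(self) -> float:
        return self.n_dual / self.n_green if self.n_green else 0.0

    @property
    def bound_fraction_red(self) -> float:
        return self.n_dual / self.n_red if self.n_red else 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_green": self.n_green, "n_red": self.n_red,
                       "n_dual": self.n_dual, "tau_d": self.tau_d,
                       "seed": self.seed}, fh, indent=2)


def expected_tau_d(volume: DetectionVolume, diffusion_coefficient: float) -> float:
    """Lateral diffusion time w0^2 / (4 D) in seconds."""
    if not diffusion_coefficient > 0:
        raise ValueError("diffusion coefficient must be positive")
    return volume.w0 ** 2 / (4.0 * diffusion_coefficient)


def simulate_traces(species: list, volume: DetectionVolume, box_size: float,
                    duration: float, dt: float, seed: int,
                    shot_noise: bool = False,
                    initial_positions: dict | None = None):
    """Simulate a two-channel FCCS measurement.

    Parameters
    ----------
    species : list of SpeciesSpec
    volume : DetectionVolume
    box_size : float
        Edge of the periodic cubic box (micrometres), >= 10 w0.
    duration, dt : float
        Trace length and sampling interval in seconds.
    seed : int
        Seeds particle placement, Brownian steps and shot noise.
    shot_noise : bool
        Apply Poisson counting noise (photons per bin) to each channel.
        Off by default so estimator tests are deterministic given paths.
    initial_positions : dict, optional
        Map species index -> (count, 3) array overriding the uniform
        random placement (used for pinned-emitter tests).

    Returns
    -------
    (IntensityTrace green, IntensityTrace red, SimGroundTruth)
    """
    if box_size < 10 * volume.w0:
        raise ValueError("box_size must be at least 10 * w0")
    n_steps = int(round(duration / dt))
    if n_steps < 2:
        raise ValueError("duration must cover at least 2 samples")
    for sp in species:
        if math.sqrt(2.0 * sp.diffusion_coefficient * dt) >= volume.w0 / 5.0:
            raise ValueError(
                f"species {sp.label!r}: RMS step "
                f"{math.sqrt(2 * sp.diffusion_coefficient * dt):.3g} um "
                f">= w0/5; reduce dt")

    rng = np.random.default_rng(seed)
    half = box_size / 2.0
    green = np.zeros(n_steps)
    red = np.zeros(n_steps)

    for isp, sp in enumerate(species):
        if sp.count == 0:
            continue
        if initial_positions and isp in initial_positions:
            pos = np.array(initial_positions[isp], dtype=float)
        else:
            pos = rng.uniform(-half, half, size=(sp.count, 3))
        sigma = math.sqrt(2.0 * sp.diffusion_coefficient * dt)
        # chunked path generation keeps memory bounded at long durations
        chunk = max(1, min(n_steps, int(2e7 / max(sp.count, 1))))
        t0 = 0
        while t0 < n_steps:
            t1 = min(t0 + chunk, n_steps)
            if sigma > 0:
                steps = rng.normal(0.0, sigma, size=(t1 - t0, sp.count, 3))
                steps[0] += pos
                paths = np.cumsum(steps, axis=0)
            else:
                paths = np.broadcast_to(pos, (t1 - t0, sp.count, 3))
            paths = (paths + half) % box_size - half
            for ch in sp.channels:
                off = volume.offsets[ch]
                rel = paths - off
                w = np.exp(-2.0 * (rel[..., 0] ** 2 + rel[..., 1] ** 2)
                           / volume.w0 ** 2
                           - 2.0 * rel[..., 2] ** 2 / volume.z0 ** 2)
                target = green if ch == "green" else red
                target[t0:t1] += sp.brightness * w.sum(axis=1)
            pos = paths[-1].copy()
            t0 = t1

    if shot_noise:
        green = rng.poisson(np.clip(green, 0, None) * dt) / dt
        red = rng.poisson(np.clip(red, 0, None) * dt) / dt

    veff = effective_volume(volume)
    vbox = box_size ** 3
    n_g = sum(sp.count for sp in species if "green" in sp.channels) * veff / vbox
    n_r = sum(sp.count for sp in species if "red" in sp.channels) * veff / vbox
    n_c = sum(sp.count for sp in species if sp.label == "dual") * veff / vbox
    tau_d = {sp.label: (expected_tau_d(volume, sp.diffusion_coefficient)
                        if sp.diffusion_coefficient > 0 else math.inf)
             for sp in species}
    truth = SimGroundTruth(n_green=n_g, n_red=n_r, n_dual=n_c,
                           tau_d=tau_d, seed=seed)
    return (IntensityTrace("green", dt, green),
            IntensityTrace("red", dt, red),
            truth)
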