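"""End-to-end orchestration: WT + variant simulations, trajectory metrics,
the FCCS interaction arm, and the variant mechanism report.

The default configuration runs the nine structural systems (wild type plus
eight pathogenic variants) through replica-exchange Langevin dynamics at
desk scale, computes the mechanism metrics on the 300 K production
ensembles, simulates a per-variant FCCS measurement whose planted bound
fraction mirrors the live-cell interaction data, and aggregates everything
into a :class:`VariantReport` (JSON + tidy CSV + text summary).
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pydantic
import yaml

from bir2sim import fccs_sim, fcs
from bir2sim import cg_remd as cg
from bir2sim import traj_metrics as tm

__all__ = [
    "VariantCatalogEntry",
    "VariantCatalog",
    "PipelineConfig",
    "RemdConfig",
    "FccsConfig",
    "VariantMetrics",
    "VariantReport",
    "load_selections",
    "default_catalog",
    "fccs_arm",
    "run_variant",
    "run_pipeline",
    "write_report",
    "validate_report",
    "report_schema",
]

log = logging.getLogger("bir2sim.pipeline")


# ---------------------------------------------------------------------------
# selections fixture


def load_selections(path=None) -> dict:
    """Load named residue selections from the packaged fixture (or a file).

    Returns a dict name -> :class:`~bir2sim.traj_metrics.ResidueSelection`;
    every id is validated against the BIR2 domain range.
    """
    if path is None:
        src = importlib.resources.files("bir2sim").joinpath(
            "data/selections.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    lo, hi = raw.get("domain_range", cg.RESIDUE_RANGE)
    out: dict = {}
    for name, body in raw["selections"].items():
        if isinstance(body, dict) and "range" in body:
            a, b = body["range"]
            ids = tuple(range(a, b + 1))
        elif isinstance(body, dict) and "union" in body:
            ids = tuple(i for part in body["union"]
                        for i in out[part].residue_ids)
        else:
            ids = tuple(body)
        bad = [i for i in ids if not lo <= i <= hi]
        if bad:
            raise ValueError(
                f"selection {name!r}: residues {bad} outside {lo}-{hi}")
        out[name] = tm.ResidueSelection(name, ids)
    return out


def get_selection(selections: dict, name: str) -> tm.ResidueSelection:
    try:
        return selections[name]
    except KeyError:
        raise KeyError(f"unknown selection {name!r}; available: "
                       f"{sorted(selections)}") from None


# ---------------------------------------------------------------------------
# variant catalog


@dataclass(frozen=True)
class VariantCatalogEntry:
    spec: cg.VariantSpec
    simulated: bool
    # planted bound fraction for the FCCS arm (fraction of green-labelled
    # protein co-diffusing with the red-labelled partner)
    bound_fraction: float


@dataclass(frozen=True)
class VariantCatalog:
    """WT + the eight simulated variants, plus the two previously
    characterized Zn-finger variants excluded from the default set."""

    entries: dict

    def __post_init__(self):
        simulated = [n for n, e in self.entries.items()
                     if e.simulated and n != "WT"]
        if len(simulated) != 8 or "WT" not in self.entries:
            raise ValueError("catalog must hold WT plus exactly 8 simulated "
                             "variants")

    def simulated_names(self) -> list:
        return ["WT"] + [n for n in cg.SIMULATED_VARIANTS
                         if self.entries[n].simulated]


def default_catalog() -> VariantCatalog:
    """The study catalog.

    Bound fractions mirror the interaction phenotypes: WT binds strongly,
    R166I/R166K retain partial binding, the remaining variants bind only
    marginally; C203Y and G204del are carried as previously characterized
    (not simulated by default).
    """
    bf = {"WT": 0.7, "R166I": 0.3, "R166K": 0.3}
    entries = {}
    for name in cg.KNOWN_VARIANTS:
        entries[name] = VariantCatalogEntry(
            spec=cg.variant_spec(name),
            simulated=name not in ("C203Y", "G204del"),
            bound_fraction=bf.get(name, 0.05))
    return VariantCatalog(entries=entries)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RemdConfig:
    n_steps: int = 20000
    stride: int = 50
    exchange_interval: int = 200
    temperatures: tuple = cg.DEFAULT_LADDER_K
    timestep: float = 0.02
    friction: float = 2.0


@dataclass(frozen=True)
class FccsConfig:
    n_labeled: int = 60          # green-labelled and red-labelled totals
    diffusion_coefficient: float = 25.0   # um^2/s
    brightness: float = 4.0
    w0: float = 0.25             # um
    s: float = 5.0
    box_size: float = 3.0        # um
    duration: float = 1.5        # s
    dt: float = 2e-5             # s


@dataclass(frozen=True)
class PipelineConfig:
    seeds: tuple = (11, 12, 13)
    remd: RemdConfig = field(default_factory=RemdConfig)
    fccs: FccsConfig = field(default_factory=FccsConfig)
    hbond_surrogate_cutoff: float = 6.2   # Angstrom, 166<->185 bead pair
    save_trajectories: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "remd" in kwargs:
            kwargs["remd"] = RemdConfig(**{
                **kwargs["remd"],
                **({"temperatures": tuple(kwargs["remd"]["temperatures"])}
                   if "temperatures" in kwargs["remd"] else {})})
        if "fccs" in kwargs:
            kwargs["fccs"] = FccsConfig(**kwargs["fccs"])
        if "seeds" in kwargs:
            kwargs["seeds"] = tuple(kwargs["seeds"])
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report schema


class VariantMetrics(pydantic.BaseModel):
    name: str
    mechanism: str | None
    core_rmsd_median: float
    core_rmsd_q90: float
    rmsf_174_182: float
    rmsf_192_198: float
    rmsf_205_215: float
    hbond_166_185_occupancy: float
    beta_segment_distance: float
    loop_205_215_gyration: float
    rca: float


class VariantReport(pydantic.BaseModel):
    package_version: str
    config_digest: str
    seeds: list[int]
    n_steps: int
    variants: dict[str, VariantMetrics]

    def to_frame(self) -> pd.DataFrame:
        rows = [m.model_dump() for m in self.variants.values()]
        return pd.DataFrame(rows).set_index("name")


def report_schema() -> dict:
    """The packaged JSON schema the report validates against."""
    src = importlib.resources.files("bir2sim").joinpath(
        "data/report_schema.json")
    return json.loads(src.read_text())


def validate_report(data: dict) -> VariantReport:
    """Validate a report dict against the report model; raises on mismatch."""
    return VariantReport.model_validate(data)


# ---------------------------------------------------------------------------
# pipeline


def _structural_metrics(ens: tm.Trajectory, reference, selections,
                        hbond_cutoff: float) -> dict:
    domain = selections["domain"]
    core = selections["hydrophobic_core"]
    rmsd = tm.subset_rmsd(ens, reference, domain, core)
    out = {
        "core_rmsd_median": float(np.median(rmsd)),
        "core_rmsd_q90": float(np.quantile(rmsd, 0.9)),
    }
    fl = tm.rmsf(ens, domain)
    for key, sel in (("rmsf_174_182", "loop_174_182"),
                     ("rmsf_192_198", "region_192_198"),
                     ("rmsf_205_215", "loop_205_215")):
        out[key] = float(fl.loc[list(selections[sel].residue_ids)].mean())
    occ, _ = tm.hbond_occupancy(ens, *cg.HELIX_HBOND_PAIR,
                                surrogate_cutoff=hbond_cutoff)
    out["hbond_166_185_occupancy"] = float(occ)
    out["beta_segment_distance"] = float(tm.segment_distance(
        ens, selections["beta_198_200"], selections["beta_206_208"]).mean())
    out["loop_205_215_gyration"] = float(tm.radius_of_gyration(
        ens, selections["loop_205_215"]).mean())
    return out


def fccs_arm(bound_fraction: float, config: FccsConfig, seed: int) -> float:
    """One simulated FCCS measurement -> RCA for a planted bound fraction."""
    n = config.n_labeled
    n_dual = int(round(bound_fraction * n))
    species = []
    if n - n_dual:
        species.append(fccs_sim.SpeciesSpec(
            "green_only", n - n_dual, config.diffusion_coefficient,
            config.brightness))
        species.append(fccs_sim.SpeciesSpec(
            "red_only", n - n_dual, config.diffusion_coefficient,
            config.brightness))
    if n_dual:
        species.append(fccs_sim.SpeciesSpec(
            "dual", n_dual, config.diffusion_coefficient, config.brightness))
    volume = fccs_sim.DetectionVolume(w0=config.w0, s=config.s)
    green, red, _ = fccs_sim.simulate_traces(
        species, volume, config.box_size, config.duration, config.dt, seed)
    result = fcs.analyze_fccs(green, red, s_fixed=config.s, seed=seed)
    return result.rca


def run_variant(name: str, catalog: VariantCatalog, config: PipelineConfig,
                selections: dict, base_model: cg.CGModel,
                outdir=None) -> VariantMetrics:
    """Simulate one system over all seeds and aggregate metrics by median."""
    entry = catalog.entries[name]
    model = cg.apply_variant(base_model, entry.spec)
    rc = config.remd
    per_seed: list = []
    rcas: list = []
    for seed in config.seeds:
        t0 = time.perf_counter()
        ladder = cg.ReplicaLadder(temperatures=rc.temperatures,
                                  exchange_interval=rc.exchange_interval)
        params = cg.LangevinParams(friction=rc.friction,
                                   timestep=rc.timestep, seed=seed)
        res = cg.run_remd(model, ladder, params, rc.n_steps, stride=rc.stride)
        ens = res.analysis_ensemble()
        per_seed.append(_structural_metrics(
            ens, base_model.coords_ref, selections,
            config.hbond_surrogate_cutoff))
        rcas.append(fccs_arm(entry.bound_fraction, config.fccs, seed))
        if outdir is not None and config.save_trajectories:
            tm.write_pdb_trajectory(
                ens, f"{outdir}/{name}_seed{seed}_300K.pdb")
        log.info("variant=%s seed=%d remd+metrics %.1fs acceptance=%.1f%%",
                 name, seed, time.perf_counter() - t0,
                 res.ladder.acceptance_rate())
    agg = {k: float(np.median([m[k] for m in per_seed]))
           for k in per_seed[0]}
    return VariantMetrics(name=name, mechanism=entry.spec.mechanism,
                          rca=float(np.median(rcas)), **agg)


def run_pipeline(config: PipelineConfig | None = None, outdir=None,
                 catalog: VariantCatalog | None = None,
                 variants: list | None = None) -> VariantReport:
    """Run the full study: structural + FCCS arms for WT and all variants.

    Deterministic given ``config.seeds``; when ``outdir`` is given the
    report is written as ``report.json``, ``report.csv`` and
    ``summary.txt`` (byte-identical across reruns with the same config).
    """
    from bir2sim import __version__

    config = config or PipelineConfig()
    catalog = catalog or default_catalog()
    selections = load_selections()
    names = variants if variants is not None else catalog.simulated_names()
    base_model = cg.bir2_reference_model()

    metrics = {}
    for name in names:
        metrics[name] = run_variant(name, catalog, config, selections,
                                    base_model, outdir=outdir)
    report = VariantReport(package_version=__version__,
                           config_digest=config.digest(),
                           seeds=list(config.seeds),
                           n_steps=config.remd.n_steps,
                           variants=metrics)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: VariantReport, outdir) -> None:
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n")
    frame = report.to_frame()
    frame.to_csv(out / "report.csv", float_format="%.10g")
    lines = [
        "BIR2 variant mechanism report",
        f"seeds={report.seeds} n_steps={report.n_steps} "
        f"config={report.config_digest}",
        "",
        frame.round(3).to_string(),
    ]
    wt = report.variants.get("WT")
    if wt is not None:
        lines += ["", "contrasts vs WT:"]
        for name, m in report.variants.items():
            if name == "WT":
                continue
            flags = []
            if m.core_rmsd_q90 > wt.core_rmsd_q90:
                flags.append("core-RMSD Q90 up")
            if m.hbond_166_185_occupancy < wt.hbond_166_185_occupancy:
                flags.append("166-185 occupancy down")
            if m.rca < wt.rca:
                flags.append("RCA down")
            lines.append(f"  {name}: {', '.join(flags) or 'none'}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
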