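"""Fluorescence (cross-)correlation spectroscopy mathematics.

The fluctuation auto-/cross-correlation of two intensity traces is

    G_x(tau) = 1 + <dI_i(t) dI_j(t+tau)> / (<I_i> <I_j>),   dI = I - <I>,

estimated directly over all valid time origins.  Correlation curves are
fitted with the standard multi-component 3D-diffusion model for a Gaussian
detection volume of lateral radius w0 and axial half-length z0 = s*w0,

    G(tau) = 1 + (1/N) sum_i F_i (1 + tau/tau_i)^-1 (1 + tau/(s^2 tau_i))^-1/2,

optionally multiplied by a triplet-blinking factor
1 + T/(1-T) * exp(-tau/tau_T).  The interaction statistic is the relative
cross-correlation amplitude RCA = [G_c(0)-1]/[G_r(0)-1], a proxy for the
bound fraction of green-labelled molecules co-diffusing with red ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "FCSModelParams",
    "FitResult",
    "FccsResult",
    "FCSError",
    "DegenerateTraceError",
    "UndefinedRCAError",
    "default_lag_grid",
    "estimate_correlation",
    "evaluate_correlation_model",
    "fit_correlation",
    "relative_cross_amplitude",
    "analyze_fccs",
    "read_curve",
    "write_curve",
    "read_trace",
    "write_trace",
]

CHANNELS = ("green", "red")
PAIRS = ("gg", "rr", "rg")


class FCSError(ValueError):
    """Base class for FCS domain errors."""


class DegenerateTraceError(FCSError):
    """Raised when a trace cannot support fluctuation correlation (zero mean)."""


class UndefinedRCAError(FCSError):
    """Raised when the RCA denominator amplitude is non-positive."""


@dataclass(frozen=True)
class IntensityTrace:
    """A single-channel fluorescence intensity time series.

    Parameters
    ----------
    channel : {'green', 'red'}
    sample_interval : float
        Sampling interval in seconds.
    values : ndarray
        Non-negative intensities in arbitrary units, length >= 2.
    """

    channel: str
    sample_interval: float
    values: np.ndarray

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise FCSError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not self.sample_interval > 0:
            raise FCSError("sample_interval must be positive")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise FCSError("trace needs at least 2 samples")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise FCSError("intensities must be finite and non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def duration(self) -> float:
        return self.sample_interval * len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class CorrelationCurve:
    """G(tau) for one channel pair ('gg', 'rr' or 'rg')."""

    pair: str
    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if self.pair not in PAIRS:
            raise FCSError(f"pair must be one of {PAIRS}, got {self.pair!r}")
        lags = np.asarray(self.lags, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if lags.shape != vals.shape or lags.ndim != 1:
            raise FCSError("lags and values must be 1-D and the same length")
        # strictly increasing; a zero first lag is allowed so that the
        # measured G(0) = 1 + var/mean^2 point can be carried explicitly
        if np.any(lags < 0) or np.any(np.diff(lags) <= 0):
            raise FCSError("lags must be strictly increasing and >= 0")
        if not np.all(np.isfinite(vals)):
            raise FCSError("correlation values must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class FCSModelParams:
    """Parameters of the multi-component diffusion model.

    ``components`` is a list of ``(fraction, diffusion_time_seconds)``
    tuples; fractions sum to one.  ``amplitude`` is the zero-lag excess
    G(0) - 1.  When ``amplitude`` is None it equals 1/n_particles; an
    explicit value (possibly zero or negative) is used for fitted
    cross-correlation curves, whose zero-lag excess is not constrained to
    the positive 1/N form when the two labels are independent.
    """

    n_particles: float
    components: tuple
    structural_parameter: float
    triplet: tuple | None = None  # (triplet_fraction, triplet_time)
    amplitude: float | None = None

    def __post_init__(self):
        comps = tuple((float(f), float(t)) for f, t in self.components)
        if not 1 <= len(comps) <= 3:
            raise FCSError("1 to 3 diffusing components required")
        fracs = np.array([f for f, _ in comps])
        taus = np.array([t for _, t in comps])
        if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
            raise FCSError("component fractions must be >= 0 and sum to 1")
        if np.any(taus <= 0):
            raise FCSError("diffusion times must be positive")
        if self.amplitude is None and not self.n_particles > 0:
            raise FCSError("n_particles must be positive")
        if not self.structural_parameter > 0:
            raise FCSError("structural parameter must be positive")
        if self.triplet is not None:
            tf, tt = self.triplet
            if not (0 <= tf < 1) or not tt > 0:
                raise FCSError("triplet fraction in [0,1) and triplet time > 0 required")
            object.__setattr__(self, "triplet", (float(tf), float(tt)))
        object.__setattr__(self, "components", comps)

    @property
    def zero_lag_excess(self) -> float:
        """G(0) - 1: the explicit amplitude if set, else 1/N."""
        if self.amplitude is not None:
            return float(self.amplitude)
        return 1.0 / self.n_particles


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_correlation`."""

    params: FCSModelParams
    residual_norm: float
    converged: bool
    message: str = ""
    n_eval: int = 0


@dataclass(frozen=True)
class FccsResult:
    """RCA and amplitude bookkeeping for one gg/rr/rg triple.

    ``rca`` is clipped to [-0.1, 1.5] for reporting; ``rca_raw`` keeps the
    unclipped ratio.  ``bound_fraction_estimate`` is the simple amplitude
    ratio N_c/N_denominator; no overlap-volume correction is applied.
    """

    amp_gg: float
    amp_rr: float
    amp_rg: float
    rca: float
    rca_raw: float
    bound_fraction_estimate: float
    denominator: str = "red"


# ---------------------------------------------------------------------------
# correlation estimation


def default_lag_grid(sample_interval: float, duration: float,
                     points_per_octave: int = 8) -> np.ndarray:
    """Quasi-logarithmic (multi-tau style) lag grid in seconds.

    Lags are integer multiples of the sample interval: consecutive
    multiples up to ``2 * points_per_octave``, then the spacing doubles
    every octave, up to half of the trace duration.
    """
    if not 0 < sample_interval < duration:
        raise FCSError("need 0 < sample_interval < duration")
    max_idx = int(duration / sample_interval) // 2
    idx: list[int] = list(range(1, min(2 * points_per_octave, max_idx) + 1))
    spacing = 2
    while idx and idx[-1] + spacing <= max_idx:
        start = idx[-1]
        for k in range(1, points_per_octave + 1):
            nxt = start + k * spacing
            if nxt > max_idx:
                break
            idx.append(nxt)
        spacing *= 2
    return np.asarray(idx, dtype=float) * sample_interval


def estimate_correlation(trace_i: IntensityTrace, trace_j: IntensityTrace,
                         lags: np.ndarray | None = None) -> CorrelationCurve:
    """Direct fluctuation correlation estimator.

    Computes ``1 + <dI_i(t) dI_j(t+tau)> / (<I_i><I_j>)`` averaging over
    every valid time origin.  Identical traces give the auto-correlation.
    Lags must be positive integer multiples of the (shared) sample
    interval and shorter than the trace; lag 0 is permitted when passed
    explicitly.
    """
    if len(trace_i.values) != len(trace_j.values):
        raise FCSError("traces must have equal length")
    if not math.isclose(trace_i.sample_interval, trace_j.sample_interval,
                        rel_tol=1e-12):
        raise FCSError("traces must share a sample interval")
    dt = trace_i.sample_interval
    n = len(trace_i.values)
    mi, mj = trace_i.mean, trace_j.mean
    if mi <= 0 or mj <= 0:
        raise DegenerateTraceError("zero-mean trace: fluctuation correlation undefined")
    if lags is None:
        lags = default_lag_grid(dt, trace_i.duration)
    lags = np.asarray(lags, dtype=float)

    di = trace_i.values - mi
    dj = trace_j.values - mj
    out = np.empty(len(lags))
    for m, lag in enumerate(lags):
        k = lag / dt
        ki = int(round(k))
        if abs(k - ki) > 1e-6 or ki < 0 or ki >= n:
            raise FCSError(
                f"lag {lag} is not an integer multiple of the sample interval "
                f"within the trace duration")
        seg = di[: n - ki] * dj[ki:] if ki else di * dj
        out[m] = 1.0 + seg.mean() / (mi * mj)

    pair = _infer_pair(trace_i.channel, trace_j.channel)
    return CorrelationCurve(pair=pair, lags=lags, values=out)


def _infer_pair(chan_i: str, chan_j: str) -> str:
    if chan_i == chan_j:
        return "gg" if chan_i == "green" else "rr"
    return "rg"


# ---------------------------------------------------------------------------
# model evaluation


def evaluate_correlation_model(params: FCSModelParams,
                               lags: np.ndarray,
                               pair: str = "gg") -> CorrelationCurve:
    """Exact evaluation of the diffusion model at the given lags."""
    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0):
        raise FCSError("lags must be non-negative")
    excess = _model_excess(lags, params)
    return CorrelationCurve(pair=pair, lags=lags, values=1.0 + excess)


def _model_excess(tau: np.ndarray, params: FCSModelParams) -> np.ndarray:
    s2 = params.structural_parameter ** 2
    g = np.zeros_like(tau, dtype=float)
    for frac, tau_d in params.components:
        g += frac / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (s2 * tau_d)))
    g *= params.zero_lag_excess
    if params.triplet is not None:
        tf, tt = params.triplet
        g *= 1.0 + tf / (1.0 - tf) * np.exp(-tau / tt)
    return g


# ---------------------------------------------------------------------------
# fitting


def _moment_init(curve: CorrelationCurve) -> tuple[float, float]:
    """Amplitude and diffusion-time starting guesses from the curve shape."""
    g0 = float(np.max(curve.values[: max(3, len(curve) // 10)])) - 1.0
    if g0 <= 0:
        g0 = max(float(curve.values[0]) - 1.0, 1e-6)
    half = 1.0 + 0.5 * g0
    below = np.nonzero(curve.values <= half)[0]
    tau_half = float(curve.lags[below[0]]) if below.size else float(curve.lags[-1])
    return g0, tau_half


def fit_correlation(curve: CorrelationCurve,
                    n_components: int = 1,
                    with_triplet: bool = False,
                    s_fixed: float | None = None,
                    fixed_times: tuple | None = None,
                    allow_negative_amplitude: bool = False,
                    weighting: str = "uniform",
                    n_restarts: int = 5,
                    seed: int = 0) -> FitResult:
    """Weighted least-squares fit of the diffusion model to a curve.

    Fractions are constrained to the simplex via stick-breaking and
    diffusion times are kept positive.  ``s_fixed`` pins the structural
    parameter (the calibrated-instrument case).  ``fixed_times`` pins the
    diffusion times (used when transferring the auto-correlation time
    scale to a noisy cross-correlation curve).  With
    ``allow_negative_amplitude`` the zero-lag excess may go negative,
    which an 1/N parameterisation cannot express; the returned params then
    carry the explicit ``amplitude``.

    Initialisation is moment-based (amplitude from G(0)-1, time scale from
    the half-decay lag) with ``n_restarts`` multiplicatively jittered
    restarts; the best residual norm wins.  Non-convergence is flagged,
    never silent.
    """
    if n_components not in (1, 2, 3):
        raise FCSError("n_components must be 1, 2 or 3")
    n_free = 1 + n_components + (n_components - 1) + (2 if with_triplet else 0) \
        + (0 if s_fixed else 1)
    if len(curve) < 4 * n_free:
        raise FCSError(
            f"curve has {len(curve)} points; need >= {4 * n_free} for "
            f"{n_free} free parameters")

    if weighting == "uniform":
        w = np.ones(len(curve))
    elif weighting == "bincount":
        # quasi-log grids average more products per bin at long lags
        w = np.sqrt(np.concatenate(([curve.lags[0]], np.diff(curve.lags)))
                    / curve.lags[0])
    else:
        raise FCSError("weighting must be 'uniform' or 'bincount'")

    if float(np.max(curve.values)) <= 1.0 and not allow_negative_amplitude:
        warnings.warn("curve never exceeds 1: returning amplitude-zero fit",
                      stacklevel=2)
        params = FCSModelParams(
            n_particles=np.inf, amplitude=0.0,
            components=((1.0, 1e-3),) * 1,
            structural_parameter=s_fixed or 5.0)
        resid = float(np.linalg.norm((curve.values - 1.0) * w))
        return FitResult(params=params, residual_norm=resid, converged=True,
                         message="amplitude-zero curve")

    g0, tau_half = _moment_init(curve)
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    for trial in range(max(1, n_restarts)):
        jit = (lambda: 1.0) if trial == 0 else (lambda: rng.lognormal(0.0, 0.4))
        p = lmfit.Parameters()
        amp0 = g0 * jit()
        if allow_negative_amplitude:
            p.add("amp", value=amp0, min=-10 * abs(g0) - 1.0, max=10 * abs(g0) + 1.0)
        else:
            p.add("amp", value=max(amp0, 1e-8), min=1e-12)
        spread = (1.0,) if n_components == 1 else \
                 (0.3, 3.0) if n_components == 2 else (0.1, 1.0, 10.0)
        for i in range(n_components):
            t0 = (fixed_times[i] if fixed_times is not None
                  else tau_half * spread[i] * jit())
            p.add(f"tau{i}", value=t0, min=curve.lags[0] * 1e-3,
                  max=curve.lags[-1] * 1e3, vary=fixed_times is None)
        for i in range(n_components - 1):
            p.add(f"stick{i}", value=0.5 * (1.0 + 0.2 * (jit() - 1.0)),
                  min=1e-6, max=1.0 - 1e-6)
        p.add("s", value=s_fixed if s_fixed else 5.0, min=0.3, max=50.0,
              vary=s_fixed is None)
        if with_triplet:
            p.add("trip_f", value=0.1, min=0.0, max=0.8)
            p.add("trip_tau", value=curve.lags[0] * 3, min=curve.lags[0] * 1e-2,
                  max=curve.lags[-1])

        def resid_fn(pars):
            return (_params_to_model(pars, n_components, with_triplet,
                                     curve.lags) - (curve.values - 1.0)) * w

        try:
            mini = lmfit.minimize(resid_fn, p, method="leastsq")
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            cand = FitResult(params=_freeze(p, n_components, with_triplet),
                             residual_norm=np.inf, converged=False,
                             message=f"optimizer failure: {exc}")
        else:
            cand = FitResult(
                params=_freeze(mini.params, n_components, with_triplet),
                residual_norm=float(np.linalg.norm(mini.residual)),
                converged=bool(mini.success),
                message=str(mini.message),
                n_eval=int(mini.nfev))
        if best is None or (cand.converged and not best.converged) or (
                cand.converged == best.converged
                and cand.residual_norm < best.residual_norm):
            best = cand
    assert best is not None
    return best


def _stick_fractions(sticks: list[float]) -> list[float]:
    fracs, remaining = [], 1.0
    for q in sticks:
        fracs.append(remaining * q)
        remaining *= 1.0 - q
    fracs.append(remaining)
    return fracs


def _params_to_model(pars, n_components, with_triplet, lags):
    sticks = [pars[f"stick{i}"].value for i in range(n_components - 1)]
    fracs = _stick_fractions(sticks)
    amp = pars["amp"].value
    s2 = pars["s"].value ** 2
    g = np.zeros_like(lags)
    for i in range(n_components):
        tau_d = pars[f"tau{i}"].value
        g += fracs[i] / ((1.0 + lags / tau_d) * np.sqrt(1.0 + lags / (s2 * tau_d)))
    g *= amp
    if with_triplet:
        tf, tt = pars["trip_f"].value, pars["trip_tau"].value
        g *= 1.0 + tf / (1.0 - tf) * np.exp(-lags / tt)
    return g


def _freeze(pars, n_components, with_triplet) -> FCSModelParams:
    sticks = [pars[f"stick{i}"].value for i in range(n_components - 1)]
    fracs = _stick_fractions(sticks)
    fracs = [f / sum(fracs) for f in fracs]
    comps = tuple((fracs[i], pars[f"tau{i}"].value) for i in range(n_components))
    amp = float(pars["amp"].value)
    triplet = ((pars["trip_f"].value, pars["trip_tau"].value)
               if with_triplet else None)
    n_particles = 1.0 / amp if amp > 0 else np.inf
    return FCSModelParams(n_particles=n_particles, components=comps,
                          structural_parameter=float(pars["s"].value),
                          triplet=triplet,
                          amplitude=None if amp > 0 else amp)


# ---------------------------------------------------------------------------
# RCA


def relative_cross_amplitude(fit_gg: FCSModelParams,
                             fit_rr: FCSModelParams,
                             fit_rg: FCSModelParams,
                             denominator: str = "red") -> FccsResult:
    """Relative cross-correlation amplitude [G_c(0)-1]/[G_x(0)-1].

    The default denominator is the red-channel auto-correlation amplitude;
    ``denominator='green'`` selects the green-channel variant.  Amplitudes
    are the fitted zero-lag excesses, never raw first-lag points.
    """
    amp_gg = fit_gg.zero_lag_excess
    amp_rr = fit_rr.zero_lag_excess
    amp_rg = fit_rg.zero_lag_excess
    den = amp_rr if denominator == "red" else amp_gg
    if denominator not in ("red", "green"):
        raise FCSError("denominator must be 'red' or 'green'")
    if den <= 0:
        raise UndefinedRCAError(
            f"{denominator}-channel amplitude {den:.3g} <= 0: RCA undefined")
    raw = amp_rg / den
    return FccsResult(amp_gg=amp_gg, amp_rr=amp_rr, amp_rg=amp_rg,
                      rca=float(np.clip(raw, -0.1, 1.5)), rca_raw=raw,
                      bound_fraction_estimate=raw, denominator=denominator)


def analyze_fccs(green: IntensityTrace, red: IntensityTrace,
                 lags: np.ndarray | None = None,
                 s_fixed: float | None = 5.0,
                 denominator: str = "red",
                 seed: int = 0) -> FccsResult:
    """Full estimator -> fit -> RCA chain for one two-channel measurement.

    Auto-correlations are fitted with a one-component model.  The
    cross-correlation is fitted with the diffusion times pinned to the
    mean of the two auto-correlation times and a sign-free amplitude, so
    that a non-interacting pair yields an unbiased near-zero amplitude.
    """
    if lags is None:
        lags = default_lag_grid(green.sample_interval, green.duration)
    c_gg = estimate_correlation(green, green, lags)
    c_rr = estimate_correlation(red, red, lags)
    c_rg = estimate_correlation(red, green, lags)
    f_gg = fit_correlation(c_gg, 1, s_fixed=s_fixed, seed=seed)
    f_rr = fit_correlation(c_rr, 1, s_fixed=s_fixed, seed=seed)
    tau_cross = 0.5 * (f_gg.params.components[0][1] + f_rr.params.components[0][1])
    f_rg = fit_correlation(c_rg, 1, s_fixed=s_fixed, fixed_times=(tau_cross,),
                           allow_negative_amplitude=True, seed=seed)
    return relative_cross_amplitude(f_gg.params, f_rr.params, f_rg.params,
                                    denominator=denominator)


# ---------------------------------------------------------------------------
# text I/O (bit-exact round trips via repr-precision floats)


def write_curve(curve: CorrelationCurve, path) -> None:
    """Write a curve as columnar text: lag_seconds, G_value, pair."""
    with open(path, "w") as fh:
        fh.write("lag_seconds\tG_value\tpair\n")
        for lag, val in zip(curve.lags, curve.values):
            fh.write(f"{float(lag)!r}\t{float(val)!r}\t{curve.pair}\n")


def read_curve(path) -> CorrelationCurve:
    lags, vals, pair = [], [], None
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["lag_seconds", "G_value", "pair"]:
            raise FCSError(f"unrecognised curve header in {path}")
        for line in fh:
            a, b, p = line.split()
            lags.append(float(a))
            vals.append(float(b))
            pair = p
    if pair is None:
        raise FCSError(f"no data rows in {path}")
    return CorrelationCurve(pair=pair, lags=np.array(lags), values=np.array(vals))


def write_trace(trace: IntensityTrace, path) -> None:
    """Two-column text (time, intensity); channel and interval in the header."""
    with open(path, "w") as fh:
        fh.write(f"# channel: {trace.channel}\n")
        fh.write(f"# sample_interval: {trace.sample_interval!r}\n")
        fh.write("time_seconds\tintensity\n")
        for k, v in enumerate(trace.values):
            fh.write(f"{float(k * trace.sample_interval)!r}\t{float(v)!r}\n")


def read_trace(path) -> IntensityTrace:
    channel = interval = None
    vals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# channel:"):
                channel = line.split(":", 1)[1].strip()
            elif line.startswith("# sample_interval:"):
                interval = float(line.split(":", 1)[1])
            elif line[0].isdigit() or line[0] in "-+.":
                vals.append(float(line.split()[1]))
    if channel is None or interval is None:
        raise FCSError(f"missing trace header in {path}")
    return IntensityTrace(channel=channel, sample_interval=interval,
                          values=np.array(vals))
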