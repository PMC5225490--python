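"""Distance profiles, trough statistics, decay/propagation fits, comparisons.

An st-LFP map is reduced to a 1-D distance profile by averaging traces over
all electrodes at the same Manhattan distance from the trigger neuron
(isotropy assumed).  Per distance, the trough — the global minimum within a
peri-spike window, by default [-10, 15] ms — gives an amplitude and a
latency.  Trough depth versus distance is fitted with A exp(-x/lambda) + C
(space constant lambda); trough latency versus distance is fitted with a
line whose inverse slope is the propagation speed in m/s (mm/ms and m/s are
the same unit).  Group comparisons use a neuron-resampling bootstrap and a
Wald z-test on fitted space constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DataError, EmptyResultError, FitError, GeometryError
from .geometry import ArrayGeometry, distance_shells
from .stlfp import StLfpMap

__all__ = [
    "DistanceProfile",
    "ExpDecayFit",
    "PropagationFit",
    "distance_profile",
    "population_average",
    "find_trough",
    "fit_exp_decay",
    "fit_propagation",
    "bootstrap_difference",
    "compare_space_constants",
]

#: peri-spike search window for the trough, ms relative to spike onset
TROUGH_WINDOW_MS = (-10.0, 15.0)


@dataclass
class DistanceProfile:
    """Per-distance averaged traces with trough statistics.

    For single-unit profiles ``n_neurons`` is 1 and ``sem`` is None; for
    population profiles ``sem`` is the across-neuron s.e.m. of the traces.
    """

    distances_mm: np.ndarray
    traces: np.ndarray
    lag_axis_ms: np.ndarray
    n_electrodes: np.ndarray
    trough_amp: np.ndarray
    trough_latency_ms: np.ndarray
    n_neurons: int = 1
    n_spikes: int = 0
    cell_type: str = "unknown"
    whitened: bool = False
    sem: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distances_mm) <= 0):
            raise DataError("distances must be strictly increasing")


@dataclass
class ExpDecayFit:
    """A exp(-x/lambda) + C fit of trough depth versus distance."""

    A: float
    lambda_mm: float
    C: float
    sd_A: float
    sd_lambda: float
    sd_C: float
    rss: float
    unreliable: bool = False


@dataclass
class PropagationFit:
    """Linear latency-versus-distance fit; speed is the inverse slope."""

    speed_m_per_s: float
    slope_ms_per_mm: float
    intercept_ms: float
    r_squared: float
    speed_defined: bool = True


def find_trough(
    trace: np.ndarray,
    lag_axis_ms: np.ndarray,
    window_ms: tuple[float, float] = TROUGH_WINDOW_MS,
) -> tuple[float, float]:
    """Global minimum of a trace within a closed lag window.

    Returns ``(amplitude, latency_ms)``; ties break toward the earliest lag.
    """
    lo, hi = window_ms
    mask = (lag_axis_ms >= lo) & (lag_axis_ms <= hi)
    if not mask.any():
        raise DataError("trough window does not overlap the lag axis")
    seg = np.asarray(trace, dtype=float)[mask]
    if np.all(np.isnan(seg)):
        raise DataError("trace is all-NaN inside the trough window")
    k = int(np.nanargmin(seg))  # first occurrence = earliest lag
    lags = lag_axis_ms[mask]
    return float(seg[k]), float(lags[k])


def distance_profile(
    stlfp_map: StLfpMap,
    geometry: ArrayGeometry,
    trigger_channel: int,
    max_mm: float = 3.2,
    trough_window_ms: tuple[float, float] = TROUGH_WINDOW_MS,
) -> DistanceProfile:
    """Average an st-LFP map over equidistant electrodes.

    Shells are Manhattan-distance multiples of the grid spacing up to
    ``max_mm``; empty shells (all members dead or absent from the map) are
    omitted.  Troughs are extracted from the shell-averaged traces, matching
    the analysis order used for population statistics.
    """
    shells = distance_shells(geometry, trigger_channel, max_mm)
    available = set(stlfp_map.channels)
    dists, traces, counts = [], [], []
    for d, members in shells.items():
        chans = sorted(members & available)
        if not chans:
            continue
        rows = [stlfp_map.channels.index(ch) for ch in chans]
        dists.append(d)
        traces.append(stlfp_map.traces[rows].mean(axis=0))
        counts.append(len(chans))
    if not dists:
        raise GeometryError("no distance shell has any available channel")
    traces = np.asarray(traces)
    amp, lat = zip(
        *(find_trough(tr, stlfp_map.lag_axis_ms, trough_window_ms) for tr in traces)
    )
    return DistanceProfile(
        distances_mm=np.asarray(dists),
        traces=traces,
        lag_axis_ms=stlfp_map.lag_axis_ms.copy(),
        n_electrodes=np.asarray(counts),
        trough_amp=np.asarray(amp),
        trough_latency_ms=np.asarray(lat),
        n_neurons=1,
        n_spikes=stlfp_map.n_spikes_used,
        whitened=stlfp_map.whitened,
        meta={"trigger_unit": stlfp_map.trigger_unit, "trigger_channel": trigger_channel},
    )


def population_average(
    profiles: list[DistanceProfile],
    min_spikes: int = 1000,
    cell_type: str | None = None,
    trough_window_ms: tuple[float, float] = TROUGH_WINDOW_MS,
) -> DistanceProfile:
    """Average single-unit distance profiles across neurons.

    Only neurons with more than ``min_spikes`` spikes (and matching
    ``cell_type``, if given) qualify.  Averaging is done per distance over
    the distances common to all qualifying profiles; the across-neuron
    s.e.m. is retained for confidence bands, and troughs are re-extracted
    from the averaged traces.
    """
    chosen = [
        p
        for p in profiles
        if p.n_spikes > min_spikes and (cell_type is None or p.cell_type == cell_type)
    ]
    if not chosen:
        raise EmptyResultError(
            f"no profile passes min_spikes={min_spikes}"
            + (f" with cell_type={cell_type!r}" if cell_type else "")
        )
    common = set(np.round(chosen[0].distances_mm, 9))
    for p in chosen[1:]:
        common &= set(np.round(p.distances_mm, 9))
    if not common:
        raise EmptyResultError("qualifying profiles share no common distance")
    dists = np.asarray(sorted(common))
    stack = []
    for p in chosen:
        idx = [int(np.argmin(np.abs(p.distances_mm - d))) for d in dists]
        stack.append(p.traces[idx])
    stack = np.asarray(stack)  # (neurons, distances, lags)
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        if stack.shape[0] >= 2
        else None
    )
    amp, lat = zip(
        *(find_trough(tr, chosen[0].lag_axis_ms, trough_window_ms) for tr in mean)
    )
    return DistanceProfile(
        distances_mm=dists,
        traces=mean,
        lag_axis_ms=chosen[0].lag_axis_ms.copy(),
        n_electrodes=np.sum([p.n_electrodes[: len(dists)] for p in chosen], axis=0),
        trough_amp=np.asarray(amp),
        trough_latency_ms=np.asarray(lat),
        n_neurons=len(chosen),
        n_spikes=int(sum(p.n_spikes for p in chosen)),
        cell_type=cell_type or "mixed",
        whitened=chosen[0].whitened,
        sem=sem,
    )


def _exp_model(x: np.ndarray, a: float, lam: float, c: float) -> np.ndarray:
    return a * np.exp(-x / lam) + c


def fit_exp_decay(
    distances_mm: np.ndarray,
    trough_amplitudes: np.ndarray,
    lambda_unreliable_mm: float = 10.0,
) -> ExpDecayFit:
    """Nonlinear least-squares fit of A exp(-x/lambda) + C to trough depth.

    Fitted on absolute trough depth (positive numbers) so A and C stay
    positive regardless of polarity.  Parameter SDs come from the fit
    covariance.  A space constant beyond ``lambda_unreliable_mm`` (or a
    singular covariance) flags the fit unreliable.
    """
    x = np.asarray(distances_mm, dtype=float)
    y = np.abs(np.asarray(trough_amplitudes, dtype=float))
    if x.size < 4:
        raise FitError("need at least 4 distance points for a 3-parameter fit")
    a0 = y[0] - y[-1]
    if a0 <= 0:  # non-decaying data: seed A at a small positive value
        a0 = 0.1 * max(y.max(), 1e-12)
    p0 = (a0, 0.5, y[-1])
    try:
        popt, pcov = optimize.curve_fit(
            _exp_model,
            x,
            y,
            p0=p0,
            bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as e:
        raise FitError(f"exponential decay fit failed: {e}")
    resid = y - _exp_model(x, *popt)
    with np.errstate(invalid="ignore"):
        sds = np.sqrt(np.diag(pcov))
    # unreliable when lambda runs away, the covariance is singular, or the
    # exponential term contributes nothing at the nearest measured distance
    # (constant data: the optimiser hides the decay below x_min and lambda
    # is unidentified)
    scale = max(float(np.max(y)), 1e-12)
    decay_at_xmin = popt[0] * np.exp(-x.min() / popt[1])
    unreliable = bool(
        popt[1] > lambda_unreliable_mm
        or not np.all(np.isfinite(sds))
        or decay_at_xmin <= 1e-6 * scale
    )
    return ExpDecayFit(
        A=float(popt[0]),
        lambda_mm=float(popt[1]),
        C=float(popt[2]),
        sd_A=float(sds[0]),
        sd_lambda=float(sds[1]),
        sd_C=float(sds[2]),
        rss=float(resid @ resid),
        unreliable=unreliable,
    )


def fit_propagation(
    distances_mm: np.ndarray,
    trough_latencies_ms: np.ndarray,
    min_slope_ms_per_mm: float = 1e-6,
) -> PropagationFit:
    """Ordinary least squares of trough latency on distance.

    speed = 1/slope, read in m/s (a slope in ms/mm inverts to mm/ms = m/s).
    A non-positive or near-zero slope leaves the speed undefined
    (``speed_defined=False``) — latency decreasing with distance cannot be a
    propagating wave.
    """
    x = np.asarray(distances_mm, dtype=float)
    y = np.asarray(trough_latencies_ms, dtype=float)
    if np.unique(x).size < 3:
        raise FitError("need at least 3 distinct distances")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    defined = slope > min_slope_ms_per_mm
    return PropagationFit(
        speed_m_per_s=float(1.0 / slope) if defined else float("nan"),
        slope_ms_per_mm=slope,
        intercept_ms=float(res.intercept),
        r_squared=float(res.rvalue**2),
        speed_defined=defined,
    )


def bootstrap_difference(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> float:
    """Two-sided bootstrap p-value for a difference of group means.

    Neurons (not spikes) are the resampling unit: each bootstrap replicate
    resamples both groups with replacement and recomputes the mean
    difference.  p = 2 min(P(d* <= 0), P(d* >= 0)) with a +1 correction;
    deterministic given ``seed``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise EmptyResultError("each group needs at least 3 neurons")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    p_le = (1 + np.sum(diffs <= 0)) / (n_boot + 1)
    p_ge = (1 + np.sum(diffs >= 0)) / (n_boot + 1)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def compare_space_constants(fit_a: ExpDecayFit, fit_b: ExpDecayFit) -> float:
    """Wald z-test on two fitted space constants.

    z = (lambda_A - lambda_B) / sqrt(sd_A^2 + sd_B^2), two-sided p from the
    normal reference.  Refuses unreliable fits.
    """
    if fit_a.unreliable or fit_b.unreliable:
        raise FitError(
            "cannot compare space constants: at least one fit is flagged "
            "unreliable (lambda at bound or singular covariance)"
        )
    denom = np.hypot(fit_a.sd_lambda, fit_b.sd_lambda)
    if denom == 0:
        return 1.0 if fit_a.lambda_mm == fit_b.lambda_mm else 0.0
    z = (fit_a.lambda_mm - fit_b.lambda_mm) / denom
    return float(2.0 * stats.norm.sf(abs(z)))
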