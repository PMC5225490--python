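"""Synthetic Utah-array sessions from an explicit linear forward model.

The LFP is modelled as a sum of spike-triggered unitary kernels plus
spatially correlated background, finally smeared by instantaneous spatial
mixing (volume conduction):

    LFP_i(t) = sum_units sum_spikes K_i(t - t_spike)  +  B_i(t),
    observed = M . LFP              (Gaussian mixing of width vc_width_mm)

The unitary kernel of a unit on channel i at Manhattan distance x is

    K_i(t) = polarity . amp0 . exp(-(x - spacing)/lambda_u)
             . h(t - synaptic_delay - x/axonal_speed),      x <= r_max,

with h a unit-peak biexponential (exp(-t/tau_d) - exp(-t/tau_r)).  The
background is an AR(1)-in-time Gaussian field with Gaussian spatial
covariance.  Each unit's firing rate is modulated by a slow drive — the
background field at the unit's own electrode, smoothed and standardised —
with gain ``common_drive_gain``, so spikes co-vary with the surrounding
population activity and the spike-locked background E[B | spike] decays
with distance on the field's correlation length: broad, non-causal and
non-local st-LFP structure, which is what spatial whitening removes.
Everything is deterministic given the master seed, and the generative
parameters are exported as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .geometry import ArrayGeometry, electrode_distance_mm, utah_geometry
from .session import RecordingSession, SpikeUnit

__all__ = [
    "UnitaryKernelSpec",
    "BackgroundSpec",
    "SyntheticGroundTruth",
    "biexponential",
    "build_kernel",
    "simulate_session",
    "generate_waveforms",
    "default_scenario",
    "propagation_scenario",
]


@dataclass(frozen=True)
class UnitaryKernelSpec:
    """Generative parameters of one unit's post-synaptic (unitary) kernel.

    ``amp0`` is the kernel amplitude at the nearest shell (one grid step from
    the source); the spatial profile decays as exp(-(x - spacing)/lambda_u)
    and is cut hard at ``r_max_mm``.  Time constants give an IPSC/EPSC-like
    biexponential; the onset at distance x is delayed by
    ``synaptic_delay_ms + x / axonal_speed_m_s`` (mm / (m/s) = ms).
    """

    polarity: str = "negative"
    amp0: float = 10.0
    lambda_u_mm: float = 0.3
    r_max_mm: float = 0.8
    tau_rise_ms: float = 0.8
    tau_decay_ms: float = 4.0
    synaptic_delay_ms: float = 0.5
    axonal_speed_m_s: float = 0.2

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ParameterError("polarity must be 'negative' or 'positive'")
        if not (self.tau_rise_ms < self.tau_decay_ms):
            raise ParameterError("tau_rise must be < tau_decay")
        if not (0 < self.lambda_u_mm <= self.r_max_mm):
            raise ParameterError("need r_max >= lambda_u > 0")
        if self.axonal_speed_m_s <= 0:
            raise ParameterError("axonal_speed must be > 0")


@dataclass(frozen=True)
class BackgroundSpec:
    """Ongoing-background parameters.

    ``common_drive_gain`` couples each unit's firing rate to its slow local
    drive (the background field at the unit's electrode, smoothed over
    ``drive_tau_s``), creating spike-LFP correlations that are not caused by
    the spike itself and that are shared between nearby units through the
    field's spatial correlation.  ``white_noise_sigma`` is an independent
    per-electrode sensor-noise floor; besides being realistic it keeps the
    spatial covariance numerically full rank.
    """

    sigma: float = 30.0
    spatial_corr_mm: float = 1.0
    temporal_ar1: float = 0.95
    common_drive_gain: float = 0.5
    drive_tau_s: float = 0.02
    white_noise_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.temporal_ar1 < 1):
            raise ParameterError("temporal_ar1 must be in [0, 1)")
        if self.sigma < 0 or self.white_noise_sigma < 0:
            raise ParameterError("noise amplitudes must be >= 0")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to reproduce and score a synthetic session."""

    kernel_specs: dict[str, UnitaryKernelSpec]
    true_types: dict[str, str]
    source_channels: dict[str, int]
    rates_hz: dict[str, float]
    background: BackgroundSpec
    vc_width_mm: float
    fs_hz: float
    seed: int
    meta: dict = field(default_factory=dict)


def biexponential(t_ms: np.ndarray, tau_rise_ms: float, tau_decay_ms: float) -> np.ndarray:
    """Unit-peak biexponential exp(-t/tau_d) - exp(-t/tau_r), zero for t < 0.

    The analytic peak time is ln(tau_d/tau_r) * tau_r tau_d / (tau_d - tau_r).
    """
    t = np.asarray(t_ms, dtype=float)
    h = np.where(t >= 0, np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms), 0.0)
    t_peak = (
        np.log(tau_decay_ms / tau_rise_ms)
        * tau_rise_ms
        * tau_decay_ms
        / (tau_decay_ms - tau_rise_ms)
    )
    peak = np.exp(-t_peak / tau_decay_ms) - np.exp(-t_peak / tau_rise_ms)
    return h / peak


def build_kernel(
    spec: UnitaryKernelSpec,
    geometry: ArrayGeometry,
    source_channel: int,
    fs_hz: float,
    duration_ms: float,
) -> np.ndarray:
    """Unitary kernel matrix (live channels x samples) for one source unit.

    Channels beyond ``r_max_mm`` (and the source channel itself — the spike
    artifact is not modelled) get all-zero rows.
    """
    max_delay = spec.synaptic_delay_ms + spec.r_max_mm / spec.axonal_speed_m_s
    if duration_ms < max_delay + 5 * spec.tau_decay_ms:
        raise ParameterError(
            f"kernel duration {duration_ms} ms truncates the response; need at "
            f"least {max_delay + 5 * spec.tau_decay_ms:.1f} ms"
        )
    n = int(round(duration_ms * fs_hz / 1000.0))
    t = np.arange(n) / fs_hz * 1000.0
    sign = -1.0 if spec.polarity == "negative" else 1.0
    live = geometry.live_channels
    k = np.zeros((len(live), n))
    for row, ch in enumerate(live):
        if ch == source_channel:
            continue
        x = electrode_distance_mm(geometry, source_channel, ch)
        if x > spec.r_max_mm + 1e-9:
            continue
        amp = spec.amp0 * np.exp(-(x - geometry.spacing_mm) / spec.lambda_u_mm)
        delay = spec.synaptic_delay_ms + x / spec.axonal_speed_m_s
        k[row] = sign * amp * biexponential(t - delay, spec.tau_rise_ms, spec.tau_decay_ms)
    return k


def _spatial_factor(
    geometry: ArrayGeometry, corr_mm: float, jitter: float = 1e-9
) -> np.ndarray:
    """Cholesky factor of the Gaussian spatial covariance over live channels."""
    live = geometry.live_channels
    xy = np.array(
        [np.array(geometry.position(ch)) * geometry.spacing_mm for ch in live]
    )
    d = cdist(xy, xy)
    if corr_mm <= 0:
        cov = np.eye(len(live))
    else:
        cov = np.exp(-(d**2) / (2.0 * corr_mm**2))
    return np.linalg.cholesky(cov + jitter * np.eye(len(live)))


def _mixing_matrix(geometry: ArrayGeometry, vc_width_mm: float) -> np.ndarray | None:
    """Row-normalised Gaussian spatial mixing (volume conduction)."""
    if vc_width_mm <= 0:
        return None
    live = geometry.live_channels
    xy = np.array(
        [np.array(geometry.position(ch)) * geometry.spacing_mm for ch in live]
    )
    d = cdist(xy, xy)
    m = np.exp(-(d**2) / (2.0 * vc_width_mm**2))
    return m / m.sum(axis=1, keepdims=True)


def _ar1_field(
    rng: np.random.Generator,
    chol: np.ndarray,
    n_samples: int,
    ar1: float,
    sigma: float,
) -> np.ndarray:
    """Stationary AR(1)-in-time field with given spatial Cholesky factor."""
    n_ch = chol.shape[0]
    innov = chol @ rng.standard_normal((n_ch, n_samples))
    scale = sigma * np.sqrt(1.0 - ar1**2)
    # start from the stationary distribution (no burn-in needed)
    x_init = sigma * (chol @ rng.standard_normal(n_ch))
    out, _ = sp_signal.lfilter(
        [1.0], [1.0, -ar1], scale * innov, axis=1, zi=(ar1 * x_init)[:, None]
    )
    return out


def simulate_session(
    kernel_specs: list[UnitaryKernelSpec],
    unit_types: list[str],
    duration_s: float = 150.0,
    geometry: ArrayGeometry | None = None,
    background: BackgroundSpec | None = None,
    rates_hz: float | list[float] = 10.0,
    vc_width_mm: float = 0.2,
    seed: int = 0,
    fs_hz: float = 1250.0,
    waveform_fs_hz: float = 30000.0,
    label_units: bool = False,
) -> tuple[RecordingSession, SyntheticGroundTruth]:
    """Generate a session with known ground truth.

    One unit per kernel spec; ``unit_types`` gives the true FS/RS identity
    (units are emitted with label "unknown" so that waveform classification
    is exercised downstream).

    Spike trains are inhomogeneous Poisson with rate
    ``rates_hz * exp(-g z_i(t) - g^2/2)`` where ``g`` is the common-drive
    gain and ``z_i`` is the unit's slow drive: the background field at the
    unit's own electrode, smoothed over ``drive_tau_s`` and standardised.
    Units therefore fire preferentially when their local field is negative
    (depolarised, active states), nearby units share drive through the
    field's spatial correlation, and the spike-locked background component
    E[B | spike] decays with distance on the field's correlation length —
    broad, non-causal and non-local, exactly the structure spatial
    whitening is meant to remove.  Deterministic given ``seed``.
    """
    if len(kernel_specs) != len(unit_types):
        raise ParameterError("kernel_specs and unit_types must have equal length")
    geometry = geometry or utah_geometry()
    background = background or BackgroundSpec()
    n_units = len(kernel_specs)
    if np.isscalar(rates_hz):
        rates = [float(rates_hz)] * n_units
    else:
        rates = [float(r) for r in rates_hz]
    ss = np.random.SeedSequence(seed)
    # child order: background, placement, waveforms, spare, then one per unit
    children = ss.spawn(4 + n_units)
    n_samples = int(round(duration_s * fs_hz))
    dt = 1.0 / fs_hz
    g = background.common_drive_gain

    # spatially correlated AR(1) background field (the ongoing LFP)
    live = geometry.live_channels
    if background.sigma > 0:
        rng_bg = np.random.default_rng(children[0])
        chol = _spatial_factor(geometry, background.spatial_corr_mm)
        lfp = _ar1_field(
            rng_bg, chol, n_samples, background.temporal_ar1, background.sigma
        )
    else:
        lfp = np.zeros((len(live), n_samples))

    rng_place = np.random.default_rng(children[1])
    # place sources away from the array edge when the grid allows it
    for margin in (2, 1, 0):
        interior = [
            ch
            for ch in live
            if margin <= geometry.position(ch)[0] < geometry.n_rows - margin
            and margin <= geometry.position(ch)[1] < geometry.n_cols - margin
        ]
        if len(interior) >= n_units:
            break
    if len(interior) < n_units:
        raise ParameterError("more units than live channels to place them on")
    sources = rng_place.choice(interior, size=n_units, replace=False)
    row_of = {ch: k for k, ch in enumerate(live)}

    # per-unit slow drive: smoothed, standardised local background
    a_z = float(np.exp(-dt / background.drive_tau_s))

    def local_drive(src_ch: int) -> np.ndarray:
        b = lfp[row_of[src_ch]]
        s = sp_signal.lfilter([1.0 - a_z], [1.0, -a_z], b)
        sd = s.std()
        return s / sd if sd > 0 else np.zeros_like(s)

    units: list[SpikeUnit] = []
    spike_indices: dict[str, np.ndarray] = {}
    kernel_blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i, (spec, rate) in enumerate(zip(kernel_specs, rates)):
        rng_u = np.random.default_rng(children[4 + i])
        if background.sigma > 0 and g > 0:
            z_i = local_drive(int(sources[i]))
            lam = rate * np.exp(-g * z_i - 0.5 * g**2)
        else:
            lam = np.full(n_samples, rate)
        p = np.clip(lam * dt, 0.0, 1.0)
        spikes = np.flatnonzero(rng_u.random(n_samples) < p)
        if spikes.size < 100:
            warnings.warn(
                f"unit u{i}: only {spikes.size} spikes; st-LFP will be noisy",
                stacklevel=2,
            )
        spike_indices[f"u{i}"] = spikes
        max_delay = spec.synaptic_delay_ms + spec.r_max_mm / spec.axonal_speed_m_s
        kern_ms = max_delay + 8 * spec.tau_decay_ms
        kern = build_kernel(spec, geometry, int(sources[i]), fs_hz, kern_ms)
        nz = np.flatnonzero(np.any(kern != 0.0, axis=1))
        kernel_blocks.append((spikes, nz, kern))

    # add the unitary kernels only after every spike train is drawn, so the
    # spike generation sees the background field alone (linear model)
    for spikes, nz, kern in kernel_blocks:
        klen = kern.shape[1]
        for s in spikes:
            end = min(s + klen, n_samples)
            lfp[nz, s:end] += kern[nz, : end - s]

    mixing = _mixing_matrix(geometry, vc_width_mm)
    if mixing is not None:
        lfp = mixing @ lfp

    # per-electrode sensor noise enters after volume conduction
    if background.white_noise_sigma > 0:
        rng_wn = np.random.default_rng(children[3])
        lfp = lfp + background.white_noise_sigma * rng_wn.standard_normal(lfp.shape)

    # mean waveforms matching the true types
    n_fs = sum(1 for t in unit_types if t == "FS")
    n_rs = n_units - n_fs
    # the waveform generator wants >= 4 templates; draw spares and discard
    wavs = generate_waveforms(
        max(n_fs, 2), max(n_rs, 2), waveform_fs_hz, seed=children[2]
    )
    fs_wavs = [w for w, t in wavs if t == "FS"]
    rs_wavs = [w for w, t in wavs if t == "RS"]
    i_fs = i_rs = 0
    for i, typ in enumerate(unit_types):
        uid = f"u{i}"
        if typ == "FS":
            wav = fs_wavs[i_fs]
            i_fs += 1
        else:
            wav = rs_wavs[i_rs]
            i_rs += 1
        units.append(
            SpikeUnit(
                unit_id=uid,
                channel=int(sources[i]),
                spike_times_s=spike_indices[uid] / fs_hz,
                mean_waveform=wav,
                waveform_fs_hz=waveform_fs_hz,
                label=typ if label_units else "unknown",
            )
        )

    session = RecordingSession(
        lfp=lfp, fs_hz=fs_hz, units=units, geometry=geometry
    )
    truth = SyntheticGroundTruth(
        kernel_specs={f"u{i}": s for i, s in enumerate(kernel_specs)},
        true_types={f"u{i}": t for i, t in enumerate(unit_types)},
        source_channels={f"u{i}": int(sources[i]) for i in range(n_units)},
        rates_hz={f"u{i}": rates[i] for i in range(n_units)},
        background=background,
        vc_width_mm=vc_width_mm,
        fs_hz=fs_hz,
        seed=seed,
        meta={"duration_s": duration_s},
    )
    return session, truth


# waveform template parameters: (neg tau_r, neg tau_d, pos tau_r, pos tau_d,
# pos delay ms, pos/neg amplitude ratio); values give negative half-widths
# near 0.17 ms (FS) and 0.35 ms (RS) at 30 kHz
_WAVE_PARAMS = {
    "FS": (0.04, 0.12, 0.15, 0.45, 0.25, 0.35),
    "RS": (0.09, 0.28, 0.35, 1.0, 0.55, 0.45),
}


def _wave_template(
    params: tuple[float, ...], fs_hz: float, amp: float = 100.0, dur_ms: float = 2.5
) -> np.ndarray:
    tr_n, td_n, tr_p, td_p, delay_p, ratio = params
    t = np.arange(int(round(dur_ms * fs_hz / 1000.0))) / fs_hz * 1000.0
    t0 = 0.3  # onset offset so the trough is interior
    w = -amp * biexponential(t - t0, tr_n, td_n)
    w += ratio * amp * biexponential(t - t0 - delay_p, tr_p, td_p)
    return w


def generate_waveforms(
    n_fs: int,
    n_rs: int,
    fs_hz: float = 30000.0,
    seed: int | np.random.SeedSequence | None = 0,
    jitter: float = 0.08,
) -> list[tuple[np.ndarray, str]]:
    """Biexponential biphasic mean-waveform templates with known types.

    FS templates are narrow (negative half-width ~0.15-0.2 ms), RS broad
    (~0.3-0.4 ms); ``jitter`` is the multiplicative SD applied independently
    to every shape parameter.  Deterministic given ``seed``.
    """
    if n_fs + n_rs < 4:
        raise ParameterError("need at least 4 waveforms in total")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, str]] = []
    for typ, n in (("FS", n_fs), ("RS", n_rs)):
        base = np.array(_WAVE_PARAMS[typ])
        for _ in range(n):
            params = base * (1.0 + jitter * rng.standard_normal(base.size))
            params = np.maximum(params, 0.01)
            if params[0] >= params[1]:  # keep tau_r < tau_d after jitter
                params[0] = 0.5 * params[1]
            if params[2] >= params[3]:
                params[2] = 0.5 * params[3]
            amp = 100.0 * (1.0 + jitter * rng.standard_normal())
            out.append((_wave_template(tuple(params), fs_hz, amp=abs(amp)), typ))
    return out


def default_scenario(
    seed: int = 0, duration_s: float = 150.0, n_units: int = 6
) -> tuple[RecordingSession, SyntheticGroundTruth]:
    """The reference validation scenario.

    Kernels confined to 0.8 mm; spatially correlated background with common
    drive; instantaneous volume-conduction mixing of width 0.2 mm (the broad
    spatial correlations come mainly from the background field).  RS kernels
    carry an extra 1 ms synaptic delay (di-synaptic route); one third of
    units are FS.
    """
    fs_spec = UnitaryKernelSpec()
    rs_spec = replace(fs_spec, synaptic_delay_ms=fs_spec.synaptic_delay_ms + 1.0)
    types = ["FS" if i % 3 == 0 else "RS" for i in range(n_units)]
    specs = [fs_spec if t == "FS" else rs_spec for t in types]
    return simulate_session(
        kernel_specs=specs,
        unit_types=types,
        duration_s=duration_s,
        rates_hz=12.0,
        seed=seed,
    )


def propagation_scenario(
    seed: int = 0, duration_s: float = 150.0, n_units: int = 3
) -> tuple[RecordingSession, SyntheticGroundTruth]:
    """Scenario for propagation-speed recovery.

    The kernel reaches 2.4 mm (six shells) with a 1.0 mm spatial decay so
    that trough latencies are measurable over enough distances for the
    latency-versus-distance regression; the axonal speed stays at the
    default 0.2 m/s.
    """
    spec = UnitaryKernelSpec(lambda_u_mm=1.0, r_max_mm=2.4)
    types = ["FS"] * n_units
    return simulate_session(
        kernel_specs=[spec] * n_units,
        unit_types=types,
        duration_s=duration_s,
        rates_hz=12.0,
        seed=seed,
        label_units=True,  # single-type scenario: k=2 clustering is moot
    )
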