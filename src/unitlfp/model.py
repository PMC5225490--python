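"""Model/Results interface for the unitary-LFP analysis.

:class:`UnitaryLFPModel` wraps a :class:`~unitlfp.session.RecordingSession`
with the analysis settings (band-pass, st-LFP window, whitening
regularisation, population filters); :meth:`UnitaryLFPModel.fit` runs the
pipeline — band-pass, waveform classification, per-unit spike-triggered
averages, per-unit ZCA whitening, distance profiles, exponential-decay and
propagation fits, group comparisons — and returns a
:class:`UnitaryLFPResults` carrying every estimate with its uncertainty,
a ``summary()`` table, and a machine-readable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .classify import UnitClassification, classify_units, extract_features
from .errors import EmptyResultError, FitError, UnitLfpError
from .filtering import BandpassSpec, bandpass_filter
from .profiles import (
    DistanceProfile,
    ExpDecayFit,
    PropagationFit,
    bootstrap_difference,
    compare_space_constants,
    distance_profile,
    fit_exp_decay,
    fit_propagation,
    population_average,
)
from .session import RecordingSession, read_session
from .stlfp import StLfpMap, compute_stlfp, jitter_surrogates
from .whitening import ongoing_covariance, whiten_stlfp, whitening_matrix

__all__ = ["UnitaryLFPModel", "UnitaryLFPResults"]


@dataclass
class UnitaryLFPResults:
    """Fitted unitary-LFP estimates for one session.

    Keys of the per-population dicts are ``(cell_type, kind)`` with kind
    ``"st"`` (raw spike-triggered average) or ``"wst"`` (whitened).
    """

    stlfp_maps: dict[str, StLfpMap]
    wstlfp_maps: dict[str, StLfpMap]
    profiles_st: dict[str, DistanceProfile]
    profiles_wst: dict[str, DistanceProfile]
    classifications: dict[str, UnitClassification]
    labels: dict[str, str]
    population_profiles: dict[tuple[str, str], DistanceProfile]
    decay_fits: dict[tuple[str, str], ExpDecayFit]
    propagation_fits: dict[tuple[str, str], PropagationFit]
    comparisons: dict[str, float]
    stage_errors: list[tuple[str, str, str]]
    seed: int | None
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable table of the headline numbers."""
        lines = [
            "Unitary LFP analysis summary",
            "=" * 64,
            f"units analysed: {len(self.stlfp_maps)}   "
            f"labels: " + ", ".join(
                f"{t}={sum(1 for v in self.labels.values() if v == t)}"
                for t in ("FS", "RS", "unknown", "unclassified")
                if any(v == t for v in self.labels.values())
            ),
            "",
            f"{'population':<12}{'kind':<6}{'lambda (mm)':<16}"
            f"{'trough@min dist':<18}{'latency (ms)':<14}{'speed (m/s)':<12}",
            "-" * 78,
        ]
        for (ctype, kind), fit in sorted(self.decay_fits.items()):
            prof = self.population_profiles[(ctype, kind)]
            prop = self.propagation_fits.get((ctype, kind))
            speed = (
                f"{prop.speed_m_per_s:.2f}"
                if prop is not None and prop.speed_defined
                else "undef"
            )
            lines.append(
                f"{ctype:<12}{kind:<6}"
                f"{fit.lambda_mm:.3f} ± {fit.sd_lambda:.3f}   "
                f"{prof.trough_amp[0]:>+9.3f}        "
                f"{prof.trough_latency_ms[0]:>6.2f}      "
                f"{speed:>8}"
            )
        if self.comparisons:
            lines += ["", "comparisons (p-values):"]
            for name, p in sorted(self.comparisons.items()):
                lines.append(f"  {name}: p = {p:.4f}")
        if self.stage_errors:
            lines += ["", "stage errors:"]
            for stage, uid, msg in self.stage_errors:
                lines.append(f"  [{stage}] {uid}: {msg}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable flat report of every headline number."""
        rep: dict = {
            "version": _pkg_version,
            "seed": self.seed,
            "settings": {k: _jsonable(v) for k, v in self.settings.items()},
            "n_units": len(self.stlfp_maps),
            "labels": dict(sorted(self.labels.items())),
            "units": {
                uid: {
                    "n_spikes_used": m.n_spikes_used,
                    "excluded_channel": m.excluded_channel,
                }
                for uid, m in sorted(self.stlfp_maps.items())
            },
            "populations": {},
            "comparisons": dict(sorted(self.comparisons.items())),
            "stage_errors": [list(e) for e in self.stage_errors],
        }
        for (ctype, kind), fit in sorted(self.decay_fits.items()):
            prof = self.population_profiles[(ctype, kind)]
            prop = self.propagation_fits.get((ctype, kind))
            rep["populations"][f"{ctype}/{kind}"] = {
                "n_neurons": prof.n_neurons,
                "lambda_mm": fit.lambda_mm,
                "sd_lambda_mm": fit.sd_lambda,
                "A": fit.A,
                "C": fit.C,
                "unreliable": fit.unreliable,
                "trough_amp_nearest": float(prof.trough_amp[0]),
                "trough_latency_ms_nearest": float(prof.trough_latency_ms[0]),
                "distances_mm": [float(d) for d in prof.distances_mm],
                "trough_amp": [float(a) for a in prof.trough_amp],
                "trough_latency_ms": [float(t) for t in prof.trough_latency_ms],
                "speed_m_per_s": (
                    prop.speed_m_per_s
                    if prop is not None and prop.speed_defined
                    else None
                ),
                "speed_r_squared": prop.r_squared if prop is not None else None,
            }
        return rep

    def save(self, out_dir: str | Path) -> Path:
        """Write report.json plus CSV tables of profiles and classifications."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_report(), indent=1, sort_keys=True)
        )
        rows = []
        for (ctype, kind), prof in sorted(self.population_profiles.items()):
            for d, a, t, n in zip(
                prof.distances_mm, prof.trough_amp, prof.trough_latency_ms, prof.n_electrodes
            ):
                rows.append(
                    {
                        "cell_type": ctype,
                        "kind": kind,
                        "distance_mm": d,
                        "trough_amp": a,
                        "trough_latency_ms": t,
                        "n_electrodes": n,
                        "n_neurons": prof.n_neurons,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "population_profiles.csv", index=False)
        cls_rows = [
            {
                "unit_id": uid,
                "label": c.label,
                "boundary_distance": c.boundary_distance,
                "peak_to_valley": c.features.peak_to_valley,
                "pos_half_width_ms": c.features.pos_half_width_ms,
                "neg_half_width_ms": c.features.neg_half_width_ms,
                "pos_to_neg_interval_ms": c.features.pos_to_neg_interval_ms,
            }
            for uid, c in sorted(self.classifications.items())
        ]
        pd.DataFrame(cls_rows).to_csv(out / "classifications.csv", index=False)
        return out


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    return v


class UnitaryLFPModel:
    """Unitary-LFP estimation on a multielectrode recording session.

    Parameters
    ----------
    session : RecordingSession
        LFP, spike trains and geometry.  The LFP is band-pass filtered at
        fit time; pass raw (already decimated) LFP.
    band : BandpassSpec
        Fourier-domain band-pass (default 15-300 Hz, 10 Hz Gaussian roll).
    window_ms : (pre, post)
        st-LFP window around each spike, default (100, 100) ms.
    min_spikes : int
        Spike-count threshold for a unit to enter population averages
        (default 1000, strictly greater).
    max_distance_mm : float
        Farthest distance shell analysed (default 3.2 mm).
    trough_window_ms : (lo, hi)
        Peri-spike window for trough extraction, default (-10, 15) ms.
    reg_floor_rel : float
        Relative eigenvalue floor of the whitening pseudo-inverse.
    quality_threshold : float
        Minimum distance from the K-means decision hyperplane (z-units) for
        a unit to receive an FS/RS label.
    """

    def __init__(
        self,
        session: RecordingSession,
        band: BandpassSpec | None = None,
        window_ms: tuple[float, float] = (100.0, 100.0),
        min_spikes: int = 1000,
        max_distance_mm: float = 3.2,
        trough_window_ms: tuple[float, float] = (-10.0, 15.0),
        reg_floor_rel: float = 1e-8,
        quality_threshold: float = 0.5,
    ) -> None:
        self.session = session
        self.band = band or BandpassSpec()
        self.window_ms = window_ms
        self.min_spikes = min_spikes
        self.max_distance_mm = max_distance_mm
        self.trough_window_ms = trough_window_ms
        self.reg_floor_rel = reg_floor_rel
        self.quality_threshold = quality_threshold

    @classmethod
    def from_path(cls, path: str | Path, **kwargs) -> "UnitaryLFPModel":
        """Build a model from a native session directory."""
        return cls(read_session(path), **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        seed: int | None = 0,
        surrogates: bool = False,
        n_surrogate: int = 1000,
        jitter_sd_s: float = 0.1,
    ) -> UnitaryLFPResults:
        """Run the full pipeline and return results.

        Every random stage (classification restarts, surrogate jitter,
        bootstrap comparisons) derives its generator from ``seed`` via a
        spawned seed sequence, so reruns are reproducible.  Per-unit stage
        failures are recorded in ``stage_errors`` and the fit continues
        over the remaining units.
        """
        ses = self.session
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        seed_classify, seed_surr, seed_boot = ss.spawn(3)
        errors: list[tuple[str, str, str]] = []

        filtered = bandpass_filter(ses.lfp, ses.fs_hz, self.band)
        fses = RecordingSession(
            lfp=filtered,
            fs_hz=ses.fs_hz,
            units=ses.units,
            geometry=ses.geometry,
            excluded_intervals=list(ses.excluded_intervals),
        )
        cov = ongoing_covariance(filtered, ses.channels)

        labels, classifications = self._classify(seed_classify, errors)

        stlfp_maps: dict[str, StLfpMap] = {}
        wst_maps: dict[str, StLfpMap] = {}
        prof_st: dict[str, DistanceProfile] = {}
        prof_wst: dict[str, DistanceProfile] = {}
        for u in ses.units:
            uid = u.unit_id
            try:
                m = compute_stlfp(fses, uid, self.window_ms)
                if surrogates:
                    m.surrogate_band = jitter_surrogates(
                        fses,
                        uid,
                        self.window_ms,
                        n_rep=n_surrogate,
                        jitter_sd_s=jitter_sd_s,
                        seed=seed_surr.spawn(1)[0],
                    )
                stlfp_maps[uid] = m
                w = whitening_matrix(cov.submatrix(m.channels), self.reg_floor_rel)
                wm = whiten_stlfp(w, m)
                wst_maps[uid] = wm
                p_st = distance_profile(
                    m, ses.geometry, u.channel, self.max_distance_mm, self.trough_window_ms
                )
                p_wst = distance_profile(
                    wm, ses.geometry, u.channel, self.max_distance_mm, self.trough_window_ms
                )
                p_st.cell_type = p_wst.cell_type = labels.get(uid, "unknown")
                prof_st[uid] = p_st
                prof_wst[uid] = p_wst
            except UnitLfpError as e:
                errors.append(("per-unit", uid, str(e)))

        if not stlfp_maps:
            raise EmptyResultError("no unit produced a spike-triggered average")

        pop_profiles: dict[tuple[str, str], DistanceProfile] = {}
        decay_fits: dict[tuple[str, str], ExpDecayFit] = {}
        prop_fits: dict[tuple[str, str], PropagationFit] = {}
        for ctype in ("FS", "RS"):
            for kind, profs in (("st", prof_st), ("wst", prof_wst)):
                try:
                    pop = population_average(
                        list(profs.values()),
                        min_spikes=self.min_spikes,
                        cell_type=ctype,
                        trough_window_ms=self.trough_window_ms,
                    )
                    pop_profiles[(ctype, kind)] = pop
                    decay_fits[(ctype, kind)] = fit_exp_decay(
                        pop.distances_mm, pop.trough_amp
                    )
                    prop_fits[(ctype, kind)] = fit_propagation(
                        pop.distances_mm, pop.trough_latency_ms
                    )
                except UnitLfpError as e:
                    errors.append(("population", f"{ctype}/{kind}", str(e)))

        comparisons = self._compare(
            prof_wst, decay_fits, labels, seed_boot, errors
        )

        return UnitaryLFPResults(
            stlfp_maps=stlfp_maps,
            wstlfp_maps=wst_maps,
            profiles_st=prof_st,
            profiles_wst=prof_wst,
            classifications=classifications,
            labels=labels,
            population_profiles=pop_profiles,
            decay_fits=decay_fits,
            propagation_fits=prop_fits,
            comparisons=comparisons,
            stage_errors=errors,
            seed=seed,
            settings={
                "band": (self.band.low_hz, self.band.high_hz, self.band.roll_width_hz),
                "window_ms": self.window_ms,
                "min_spikes": self.min_spikes,
                "max_distance_mm": self.max_distance_mm,
                "trough_window_ms": self.trough_window_ms,
                "reg_floor_rel": self.reg_floor_rel,
                "quality_threshold": self.quality_threshold,
            },
        )

    # -- helpers ----------------------------------------------------------

    def _classify(self, seed_seq, errors):
        """Waveform classification; externally supplied labels win."""
        ses = self.session
        labels: dict[str, str] = {u.unit_id: u.label for u in ses.units}
        classifications: dict[str, UnitClassification] = {}
        unl = [
            u
            for u in ses.units
            if u.label == "unknown" and u.mean_waveform is not None
        ]
        if len(unl) >= 4:
            try:
                feats = [
                    extract_features(u.mean_waveform, u.waveform_fs_hz) for u in unl
                ]
                cls = classify_units(
                    feats,
                    unit_ids=[u.unit_id for u in unl],
                    seed=int(seed_seq.generate_state(1)[0] % (2**31)),
                    quality_threshold=self.quality_threshold,
                )
                for c in cls:
                    classifications[c.unit_id] = c
                    labels[c.unit_id] = c.label
            except UnitLfpError as e:
                errors.append(("classification", "-", str(e)))
        return labels, classifications

    def _compare(self, prof_wst, decay_fits, labels, seed_boot, errors):
        """Group comparisons: trough latency bootstrap and lambda Wald test."""
        comparisons: dict[str, float] = {}
        lat = {"FS": [], "RS": []}
        for uid, p in prof_wst.items():
            if labels.get(uid) in lat and p.n_spikes > self.min_spikes:
                lat[labels[uid]].append(p.trough_latency_ms[0])
        try:
            if len(lat["FS"]) >= 3 and len(lat["RS"]) >= 3:
                comparisons["trough_latency_FS_vs_RS_wst"] = bootstrap_difference(
                    lat["FS"], lat["RS"], seed=seed_boot
                )
        except UnitLfpError as e:
            errors.append(("comparison", "latency", str(e)))
        for kind in ("st", "wst"):
            a, b = decay_fits.get(("FS", kind)), decay_fits.get(("RS", kind))
            if a is not None and b is not None:
                try:
                    comparisons[f"lambda_FS_vs_RS_{kind}"] = compare_space_constants(a, b)
                except FitError as e:
                    errors.append(("comparison", f"lambda/{kind}", str(e)))
        return comparisons
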