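"""Waveform-based classification of units into fast-spiking / regular-spiking.

Extracellular spike waveforms of putative inhibitory interneurons are
narrower than those of putative excitatory cells.  Each unit's mean waveform
is reduced to four features — peak-to-valley amplitude, positive and
negative half-widths, and the positive-to-negative interval — which are
z-scored and clustered with K-means (k=2).  The cluster with the narrower
mean negative half-width is labelled FS (thin-spike convention); units lying
too close to the midpoint hyperplane between the centroids are left
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ClassificationError, FeatureError

__all__ = [
    "WaveformFeatures",
    "UnitClassification",
    "extract_features",
    "classify_units",
]


@dataclass(frozen=True)
class WaveformFeatures:
    """The four waveform features used for FS/RS discrimination."""

    peak_to_valley: float
    pos_half_width_ms: float
    neg_half_width_ms: float
    pos_to_neg_interval_ms: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.peak_to_valley,
                self.pos_half_width_ms,
                self.neg_half_width_ms,
                self.pos_to_neg_interval_ms,
            ]
        )


@dataclass
class UnitClassification:
    unit_id: str
    label: str  # FS | RS | unclassified
    boundary_distance: float  # in z-scored feature space
    features: WaveformFeatures


def _refine_extremum(w: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum (position, value) by parabolic interpolation."""
    if 0 < i < w.size - 1:
        y0, y1, y2 = w[i - 1], w[i], w[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1:
                return i + delta, y1 - 0.25 * (y0 - y2) * delta
    return float(i), float(w[i])


def _half_width(w: np.ndarray, i_ext: int, value: float) -> float:
    """Full width (in samples) of the phase around ``i_ext`` at half ``value``.

    Crossing positions are linearly interpolated.  Works for either polarity
    (``value`` carries the sign of the extremum).
    """
    half = value / 2.0
    sign = 1.0 if value > 0 else -1.0
    s = sign * w  # phase now positive with max at i_ext
    h = sign * half
    left = float(0)
    for j in range(i_ext, 0, -1):
        if s[j - 1] < h <= s[j]:
            left = (j - 1) + (h - s[j - 1]) / (s[j] - s[j - 1])
            break
    else:
        left = 0.0
    right = float(s.size - 1)
    for j in range(i_ext, s.size - 1):
        if s[j + 1] < h <= s[j]:
            right = j + (s[j] - h) / (s[j] - s[j + 1])
            break
    else:
        right = float(s.size - 1)
    return right - left


def extract_features(mean_waveform: np.ndarray, fs_hz: float) -> WaveformFeatures:
    """Reduce a mean spike waveform to the four discriminative features.

    The waveform must be biphasic in the extracellular convention: a dominant
    negative trough plus a positive deflection.  Half-widths are full widths
    at half the phase extremum; extrema positions are refined by parabolic
    interpolation; the positive-to-negative interval is the (unsigned) time
    between the positive peak and the negative trough.
    """
    w = np.asarray(mean_waveform, dtype=float)
    i_neg = int(np.argmin(w))
    i_pos = int(np.argmax(w))
    if w[i_neg] >= 0:
        raise FeatureError("waveform has no negative phase (trough)")
    if w[i_pos] <= 0:
        raise FeatureError("waveform has no positive phase (peak)")
    t_neg, v_neg = _refine_extremum(w, i_neg)
    t_pos, v_pos = _refine_extremum(w, i_pos)
    ms_per_sample = 1000.0 / fs_hz
    return WaveformFeatures(
        peak_to_valley=float(v_pos - v_neg),
        pos_half_width_ms=_half_width(w, i_pos, v_pos) * ms_per_sample,
        neg_half_width_ms=_half_width(w, i_neg, v_neg) * ms_per_sample,
        pos_to_neg_interval_ms=abs(t_pos - t_neg) * ms_per_sample,
    )


def classify_units(
    features: list[WaveformFeatures],
    unit_ids: list[str] | None = None,
    seed: int | None = 0,
    quality_threshold: float = 0.5,
) -> list[UnitClassification]:
    """K-means (k=2) classification of units in z-scored feature space.

    ``boundary_distance`` is each unit's distance to the midpoint hyperplane
    between the two centroids, in z-units; units closer than
    ``quality_threshold`` are labelled ``unclassified``.  The cluster with
    the smaller mean negative half-width is FS.  Deterministic given
    ``seed``.
    """
    if len(features) < 4:
        raise ClassificationError("need at least 4 units to cluster")
    if unit_ids is None:
        unit_ids = [str(i) for i in range(len(features))]
    x = np.asarray([f.as_vector() for f in features], dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0) or np.allclose(x, x[0]):
        raise ClassificationError(
            "degenerate features: at least one feature has zero variance"
        )
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    centers = km.cluster_centers_
    # thin-spike convention: narrower negative half-width => FS
    neg_hw = np.array([f.neg_half_width_ms for f in features])
    mean_hw = [neg_hw[km.labels_ == k].mean() for k in (0, 1)]
    fs_cluster = int(np.argmin(mean_hw))
    # signed distance to the midpoint hyperplane between centroids
    u = centers[1] - centers[0]
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ClassificationError("cluster centroids coincide")
    u = u / norm
    mid = centers.mean(axis=0)
    dist = np.abs((z - mid) @ u)
    out = []
    for uid, lab, d, f in zip(unit_ids, km.labels_, dist, features):
        label = ("FS" if lab == fs_cluster else "RS") if d >= quality_threshold else "unclassified"
        out.append(
            UnitClassification(
                unit_id=uid, label=label, boundary_distance=float(d), features=f
            )
        )
    return out
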