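"""Spatial whitening of spike-triggered LFP maps.

The ongoing band-passed LFP has strong spatial correlations (volume
conduction, shared synaptic drive) that dominate the raw st-LFP.  ZCA
whitening removes them: with C the channel-space covariance of the ongoing
LFP, the whitening matrix is its inverse square root

    W = E D E^T,   D_ii = 1 / sqrt(lambda_i),

E the eigenvectors and lambda_i the eigenvalues of C.  Applying W to an
st-LFP (per time lag) yields the whitened st-LFP (wst-LFP), in which globally
correlated components are suppressed and the focal, unitary contribution of
the trigger neuron remains.  Eigenvalues below a relative floor are zeroed
rather than floored, giving a proper pseudo-inverse square root for
rank-deficient covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, DegenerateCovarianceError, ParameterError
from .geometry import ArrayGeometry
from .stlfp import StLfpMap

__all__ = [
    "SpatialCovariance",
    "WhiteningFilter",
    "ongoing_covariance",
    "whitening_matrix",
    "whiten_stlfp",
    "laplacian_matrix",
]


@dataclass
class SpatialCovariance:
    """Channel-space second-moment matrix of the ongoing LFP."""

    matrix: np.ndarray
    channel_order: list[int]
    n_samples_used: int
    rank_warning: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParameterError("covariance must be square")
        if len(self.channel_order) != m.shape[0]:
            raise ParameterError("channel_order length must match matrix dimension")
        if len(set(self.channel_order)) != len(self.channel_order):
            raise ParameterError("channel_order has duplicates")
        self.matrix = 0.5 * (m + m.T)  # enforce exact symmetry

    def submatrix(self, channels: list[int]) -> "SpatialCovariance":
        """Covariance restricted to (and ordered by) ``channels``."""
        try:
            idx = [self.channel_order.index(ch) for ch in channels]
        except ValueError as e:
            raise AlignmentError(f"channel not in covariance: {e}")
        return SpatialCovariance(
            matrix=self.matrix[np.ix_(idx, idx)],
            channel_order=list(channels),
            n_samples_used=self.n_samples_used,
            rank_warning=self.rank_warning,
        )


@dataclass
class WhiteningFilter:
    """ZCA whitening matrix with its eigendecomposition record.

    ``n_regularized`` counts eigenmodes zeroed because their eigenvalue fell
    below ``reg_floor`` (= reg_floor_rel * lambda_max).
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    channel_order: list[int]
    reg_floor: float
    n_regularized: int


def ongoing_covariance(
    lfp_bandpassed: np.ndarray, channel_order: list[int]
) -> SpatialCovariance:
    """Second-moment matrix C_ij = <LFP_i(t) LFP_j(t)>_t of the band-passed LFP.

    No mean subtraction beyond the band-pass (which removes DC).  A rank
    warning is recorded when there are fewer samples than channels.
    """
    x = np.asarray(lfp_bandpassed, dtype=float)
    n_ch, n_s = x.shape
    if n_ch != len(channel_order):
        raise ParameterError("channel_order length must match LFP rows")
    c = (x @ x.T) / n_s
    return SpatialCovariance(
        matrix=c,
        channel_order=list(channel_order),
        n_samples_used=n_s,
        rank_warning=n_s < n_ch,
    )


def whitening_matrix(
    cov: SpatialCovariance, reg_floor_rel: float = 1e-8
) -> WhiteningFilter:
    """Inverse square root of a covariance via eigendecomposition.

    ``W = E D E^T`` with ``D_ii = 1/sqrt(lambda_i)`` for eigenvalues above
    ``reg_floor_rel * lambda_max`` and 0 otherwise (pseudo-inverse square
    root).  W is symmetric positive semi-definite.
    """
    lam, vec = np.linalg.eigh(cov.matrix)
    lam_max = lam.max() if lam.size else 0.0
    floor = reg_floor_rel * max(lam_max, 0.0)
    keep = lam > floor
    if not keep.any():
        raise DegenerateCovarianceError(
            "all covariance eigenvalues fall below the regularisation floor"
        )
    d = np.where(keep, 1.0 / np.sqrt(np.where(keep, lam, 1.0)), 0.0)
    w = (vec * d[None, :]) @ vec.T
    return WhiteningFilter(
        matrix=0.5 * (w + w.T),
        eigenvalues=lam,
        channel_order=list(cov.channel_order),
        reg_floor=floor,
        n_regularized=int((~keep).sum()),
    )


def whiten_stlfp(filt: WhiteningFilter, stlfp_map: StLfpMap) -> StLfpMap:
    """Apply a whitening filter to an st-LFP map, lag by lag.

    The filter's channel order must equal the map's channels (the trigger
    electrode absent from both).  Metadata and the lag axis are preserved;
    the result is flagged as whitened.  The s.e.m. is propagated only
    approximately (|W| applied in quadrature) and the surrogate band is
    dropped — recompute it on whitened data if needed.
    """
    if list(filt.channel_order) != list(stlfp_map.channels):
        missing = set(filt.channel_order) ^ set(stlfp_map.channels)
        raise AlignmentError(
            f"whitening filter channels do not match st-LFP channels; "
            f"differing channels: {sorted(missing)}"
        )
    w = filt.matrix
    new_sem = None
    if stlfp_map.sem is not None:
        new_sem = np.sqrt((w**2) @ (stlfp_map.sem**2))
    return replace(
        stlfp_map,
        traces=w @ stlfp_map.traces,
        sem=new_sem,
        surrogate_band=None,
        whitened=True,
        meta={**stlfp_map.meta, "n_regularized": filt.n_regularized},
    )


def laplacian_matrix(geometry: ArrayGeometry, channels: list[int]) -> np.ndarray:
    """Discrete second-spatial-derivative filter, as a comparison baseline.

    Row i has weight 1 at channel i and -1/k at each of its k live
    Manhattan-1 neighbours present in ``channels``.  Data-driven whitening
    filters resemble this operator but carry additional off-centre structure.
    """
    pos = {ch: geometry.position(ch) for ch in channels}
    index = {ch: i for i, ch in enumerate(channels)}
    n = len(channels)
    lap = np.zeros((n, n))
    by_pos = {p: ch for ch, p in pos.items()}
    for ch, (r, c) in pos.items():
        i = index[ch]
        lap[i, i] = 1.0
        neigh = [
            by_pos[p]
            for p in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if p in by_pos
        ]
        for nb in neigh:
            lap[i, index[nb]] = -1.0 / len(neigh)
    return lap
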