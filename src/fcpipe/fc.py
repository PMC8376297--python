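"""Temporal preprocessing of ROI time series and Fisher-z connectivity.

The functional-connectivity path mirrors the standard resting-state
pipeline once voxel-level work is done: region-averaged BOLD series are
linearly detrended, band-pass filtered (default 0.01-0.08 Hz), optionally
cleaned of nuisance signals (white matter, CSF, motion parameters and
their temporal derivatives), and correlated pairwise.  Pearson r values
are variance-stabilized with the Fisher z transform (``atanh``), giving a
symmetric zero-diagonal matrix per subject; its upper triangle is the
subject's edge vector (6670 dimensions for a 116-region parcellation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import edges as edgemod
from .atlas import default_labels

logger = logging.getLogger(__name__)

#: Correlations are clipped to +/- this bound before atanh so z stays finite.
CLIP_BOUND = 1.0 - 1e-10

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "EdgeVector",
    "detrend_bandpass",
    "regress_nuisance",
    "connectivity_matrix",
    "vectorize",
    "matricize",
    "preprocess",
]


@dataclass
class RoiTimeSeries:
    """One subject's ``T x N`` matrix of region-averaged BOLD amplitudes."""

    values: np.ndarray
    sampling_interval: float = 2.5  # seconds between volumes (TR)
    region_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T, N) array")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(f"need T >= 2 and N >= 2, got shape {(t, n)}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.region_labels is None:
            self.region_labels = default_labels(n)
        elif len(self.region_labels) != n:
            raise ValueError("region_labels length must match column count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.sampling_interval)

    def discard_initial(self, n_volumes: int) -> "RoiTimeSeries":
        """Drop the first ``n_volumes`` rows (scanner equilibration period)."""
        if n_volumes < 0 or n_volumes >= self.n_timepoints - 1:
            raise ValueError("cannot discard that many volumes")
        return RoiTimeSeries(
            self.values[n_volumes:], self.sampling_interval, list(self.region_labels)
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric ``N x N`` Fisher-z connectivity with an exactly zero diagonal."""

    z: np.ndarray
    region_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectivity must be a square matrix")
        if not np.isfinite(self.z).all():
            raise ValueError("connectivity contains non-finite values")
        if not np.allclose(self.z, self.z.T, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix is not symmetric (tol 1e-12)")
        # enforce exact symmetry and a hard-zero diagonal
        self.z = (self.z + self.z.T) / 2.0
        np.fill_diagonal(self.z, 0.0)
        if self.region_labels is None:
            self.region_labels = default_labels(self.z.shape[0])
        elif len(self.region_labels) != self.z.shape[0]:
            raise ValueError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class EdgeVector:
    """Upper-triangle edge values in canonical row-major order.

    ``values[k]`` is the Fisher-z weight of the k-th unordered region pair
    under the bijection of :mod:`fcpipe.edges`.
    """

    values: np.ndarray
    region_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        n = edgemod.regions_for_edge_count(self.values.size)
        if self.region_labels is None:
            self.region_labels = default_labels(n)
        elif len(self.region_labels) != n:
            raise ValueError("region_labels length inconsistent with vector length")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_edges(self) -> int:
        return self.values.size

    def pair_for(self, index: int) -> tuple[int, int]:
        i, j = edgemod.index_to_pairs([index], self.n_regions)[0]
        return int(i), int(j)

    def index_for(self, i: int, j: int) -> int:
        return int(edgemod.pairs_to_index([(i, j)], self.n_regions)[0])

    def edge_label(self, index: int) -> str:
        i, j = self.pair_for(index)
        return f"{self.region_labels[i]}--{self.region_labels[j]}"


def _bandpass_sos(low_hz: float, high_hz: float, fs: float, order: int) -> np.ndarray:
    if low_hz <= 0.0:  # degenerate band: plain low-pass
        return signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def detrend_bandpass(
    ts: RoiTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
) -> RoiTimeSeries:
    """Remove each column's linear trend, then zero-phase band-pass filter.

    The filter is a forward-backward (``sosfiltfilt``) Butterworth of the
    given order per pass, so the net response is the squared magnitude and
    the phase is exactly zero.

    Parameters
    ----------
    low_hz, high_hz
        Pass-band edges in Hz; must satisfy ``0 <= low < high < Nyquist``.
    """
    nyq = ts.nyquist_hz
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyq:.4g} Hz for sampling interval {ts.sampling_interval} s"
        )
    sos = _bandpass_sos(low_hz, high_hz, 1.0 / ts.sampling_interval, order)
    # pad with ~5 cycles of the slowest pass-band component so the
    # forward and backward transients die out (the scipy default of a few
    # samples is far too short for narrow low-frequency bands); capped at
    # T-1 so realistic-length series still filter
    min_padlen = 3 * (2 * sos.shape[0] + 1)
    if ts.n_timepoints <= min_padlen:
        raise ValueError(
            f"time series too short for zero-phase filtering: need at least "
            f"{min_padlen + 1} timepoints, got {ts.n_timepoints}"
        )
    cycles = (
        int(np.ceil(5.0 / (low_hz * ts.sampling_interval))) if low_hz > 0 else 0
    )
    padlen = min(max(min_padlen, cycles), ts.n_timepoints - 1)
    detrended = signal.detrend(ts.values, axis=0, type="linear")
    filtered = signal.sosfiltfilt(sos, detrended, axis=0, padlen=padlen)
    return RoiTimeSeries(filtered, ts.sampling_interval, list(ts.region_labels))


def _derivative(confounds: np.ndarray) -> np.ndarray:
    # backward difference; first sample has no predecessor and is set to 0
    d = np.zeros_like(confounds)
    d[1:] = np.diff(confounds, axis=0)
    return d


def regress_nuisance(
    ts: RoiTimeSeries,
    confounds: np.ndarray,
    add_derivatives: bool = True,
) -> RoiTimeSeries:
    """Residualize each ROI column against a nuisance design.

    The design is ``[intercept, confounds, backward-difference derivatives]``
    (derivatives optional).  Columns that are linearly dependent on earlier
    ones are dropped with a warning; residuals are orthogonal to the kept
    design within 1e-8.
    """
    c = np.atleast_2d(np.asarray(confounds, dtype=float))
    if c.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confounds have {c.shape[0]} rows but time series has "
            f"{ts.n_timepoints} timepoints"
        )
    if c.shape[1] < 1:
        raise ValueError("need at least one confound column")
    blocks = [np.ones((ts.n_timepoints, 1)), c]
    if add_derivatives:
        blocks.append(_derivative(c))
    design = np.column_stack(blocks)

    # drop linearly dependent columns (QR diagonal collapse signals rank loss)
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = design.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    keep = diag > tol
    if not keep.all():
        logger.warning(
            "nuisance design is rank deficient; dropping %d dependent column(s)",
            int((~keep).sum()),
        )
        # recompute with independent columns only (greedy left-to-right)
        kept_cols: list[int] = []
        for k in range(design.shape[1]):
            cand = design[:, kept_cols + [k]]
            if np.linalg.matrix_rank(cand) == len(kept_cols) + 1:
                kept_cols.append(k)
        design = design[:, kept_cols]

    coef, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ coef
    return RoiTimeSeries(resid, ts.sampling_interval, list(ts.region_labels))


def connectivity_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation followed by the Fisher z transform.

    ``z[i, j] = atanh(clip(r[i, j]))`` off the diagonal; the diagonal is
    zero by definition and excluded from every downstream analysis.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = ts.values.std(axis=0)
    scale = np.abs(ts.values).max(axis=0) + 1.0
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        names = ", ".join(ts.region_labels[k] for k in dead[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    clipped = np.clip(r, -CLIP_BOUND, CLIP_BOUND)
    if (np.abs(r) > CLIP_BOUND).any():
        logger.info("clipped %d correlation(s) at +/-%s before atanh",
                    int((np.abs(r) > CLIP_BOUND).sum()), CLIP_BOUND)
    z = np.arctanh(clipped)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, list(ts.region_labels))


def vectorize(m: ConnectivityMatrix) -> EdgeVector:
    """Edge vector of the strict upper triangle (length ``N(N-1)/2``)."""
    return EdgeVector(edgemod.vectorize(m.z, check=False), list(m.region_labels))


def matricize(v: EdgeVector) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize`; the round trip is bit-exact."""
    return ConnectivityMatrix(edgemod.matricize(v.values), list(v.region_labels))


def preprocess(
    ts: RoiTimeSeries,
    confounds: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: str = "bandpass_first",
    discard_volumes: int = 0,
) -> RoiTimeSeries:
    """Full temporal preprocessing: detrend + band-pass and nuisance removal.

    ``order`` selects whether filtering precedes nuisance regression
    (``"bandpass_first"``, the default) or follows it (``"regress_first"``).
    """
    if order not in ("bandpass_first", "regress_first"):
        raise ValueError("order must be 'bandpass_first' or 'regress_first'")
    if discard_volumes:
        ts = ts.discard_initial(discard_volumes)
        if confounds is not None:
            confounds = np.asarray(confounds, dtype=float)[discard_volumes:]
    if order == "bandpass_first":
        out = detrend_bandpass(ts, low_hz, high_hz)
        if confounds is not None:
            out = regress_nuisance(out, confounds)
    else:
        out = ts if confounds is None else regress_nuisance(ts, confounds)
        out = detrend_bandpass(out, low_hz, high_hz)
    return out
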