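"""Band-limited phase-locking connectivity.

The pipeline from parcellated time series to connectomes:

1. zero-phase FIR band-pass filtering into a canonical EEG band,
2. instantaneous phase via the analytic signal (Hilbert transform),
   computed independently per epoch,
3. sliding-window phase-locking value (PLV) per ROI pair,
4. a static connectome (window-averaged PLV) and a dynamic-variability
   matrix (per-edge sample variance of the window PLV trajectory).

PLV between two signals over a window of W samples is the magnitude of
the mean unit phasor of their instantaneous phase difference::

    PLV = | (1/W) * sum_t exp(i * (phi_x(t) - phi_y(t))) |

which is 1 for perfect phase locking and near 0 for independent phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import RegionalTimeSeries

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "DynamicConnectome",
    "ConnectivityMatrix",
    "VarianceMatrix",
    "bandpass",
    "instantaneous_phase",
    "sliding_plv",
    "static_plv",
    "dynamic_variance",
    "default_window_samples",
    "n_edges",
    "edge_pairs",
    "vectorize_edges",
    "matrix_from_edges",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band: need 0 < f_lo < f_hi, got {self}")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: The five canonical EEG bands.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}


# ---------------------------------------------------------------------------
# edge vectorization


def n_edges(n_rois: int) -> int:
    """Number of unordered ROI pairs: n(n-1)/2."""
    return n_rois * (n_rois - 1) // 2


def edge_pairs(n_rois: int) -> np.ndarray:
    """(n_edges, 2) array of 0-based (i, j) pairs, row-major upper triangle."""
    iu = np.triu_indices(n_rois, k=1)
    return np.column_stack(iu)


def vectorize_edges(m, *, atol: float = 1e-10) -> np.ndarray:
    """Row-major upper-triangle vector of a symmetric ROI x ROI matrix.

    The diagonal is excluded: for ``n`` ROIs the result has length
    ``n(n-1)/2`` (2278 for the 68-region parcellation). Accepts a bare
    array, a :class:`ConnectivityMatrix` or a :class:`VarianceMatrix`.
    """
    if isinstance(m, (ConnectivityMatrix, VarianceMatrix)):
        m = m.weights if isinstance(m, ConnectivityMatrix) else m.values
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=atol, rtol=0.0):
        raise ValueError("matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def matrix_from_edges(edges: np.ndarray, *, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`: rebuild the symmetric matrix."""
    edges = np.asarray(edges, dtype=float)
    e = edges.shape[-1]
    n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(n) != e:
        raise ValueError(f"edge vector length {e} is not n(n-1)/2 for integer n")
    m = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    m[iu] = edges
    m[(iu[1], iu[0])] = edges
    return m


# ---------------------------------------------------------------------------
# matrices


@dataclass
class ConnectivityMatrix:
    """Static ROI x ROI PLV matrix: symmetric, unit diagonal, weights in [0, 1]."""

    weights: np.ndarray
    band: BandDefinition | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12, rtol=0.0):
            raise ValueError("weights must be symmetric within 1e-12")
        off = w[np.triu_indices(w.shape[0], k=1)]
        if off.size and (off.min() < 0.0 or off.max() > 1.0):
            raise ValueError("off-diagonal weights must lie in [0, 1]")
        np.fill_diagonal(w, 1.0)
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def edge_vector(self) -> np.ndarray:
        return vectorize_edges(self.weights)


@dataclass
class VarianceMatrix:
    """Per-edge temporal variance of dynamic PLV (units PLV^2); symmetric, >= 0."""

    values: np.ndarray
    band: BandDefinition | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValueError("values must be symmetric within 1e-12")
        if v.min() < 0.0:
            raise ValueError("variances must be nonnegative")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def edge_vector(self) -> np.ndarray:
        return vectorize_edges(self.values)


@dataclass
class DynamicConnectome:
    """Sliding-window PLV trajectory for one subject: windows x edges in [0, 1].

    ``epoch_boundaries`` gives, per epoch, the index of its first window
    in the concatenated window axis (windows never straddle epochs).
    """

    values: np.ndarray
    window_len: int
    step: int
    band: BandDefinition | None = None
    epoch_boundaries: tuple[int, ...] = field(default_factory=tuple)
    n_rois: int = 0
    subject_id: str = ""
    trimmed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be (windows, edges)")
        if v.size and (v.min() < -1e-12 or v.max() > 1.0 + 1e-12):
            raise ValueError("PLV values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        if self.n_rois == 0:
            # infer from edge count
            e = v.shape[1]
            self.n_rois = int(round((1 + np.sqrt(1 + 8 * e)) / 2))

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# filtering and phase


def _fir_taps(band: BandDefinition, fs: float, n_samples: int,
              transition_frac: float) -> np.ndarray:
    """Hamming-window FIR band-pass taps; transition width a fraction of f_lo.

    The tap count is capped so that forward-backward filtering remains
    valid (`filtfilt` needs 3*ntaps < n_samples of padding).
    """
    transition_hz = transition_frac * band.f_lo
    ntaps = int(np.ceil(3.3 * fs / transition_hz))
    cap = max(11, (n_samples - 2) // 3)
    ntaps = min(ntaps, cap)
    if ntaps % 2 == 0:
        ntaps -= 1
    return signal.firwin(ntaps, [band.f_lo, band.f_hi], pass_zero=False,
                         window="hamming", fs=fs)


def bandpass(ts: RegionalTimeSeries, band: BandDefinition,
             *, transition_frac: float = 0.1) -> RegionalTimeSeries:
    """Zero-phase FIR band-pass filter, applied per epoch.

    Forward-backward filtering (`filtfilt`) gives zero phase distortion,
    which matters because downstream connectivity is phase-based.

    Raises
    ------
    ValueError
        If the band violates the Nyquist criterion ``fs >= 2 * f_hi``.
    """
    if ts.fs < 2.0 * band.f_hi:
        raise ValueError(
            f"band {band.name} ({band.f_hi} Hz upper edge) violates Nyquist "
            f"at fs={ts.fs} Hz"
        )
    taps = _fir_taps(band, ts.fs, ts.n_samples, transition_frac)
    filtered = signal.filtfilt(taps, [1.0], ts.data, axis=-1)
    return RegionalTimeSeries(filtered, ts.fs, ts.roi_names, ts.epoch_len_s)


def instantaneous_phase(ts: RegionalTimeSeries) -> np.ndarray:
    """Instantaneous phase of the analytic signal, per epoch.

    Returns an array with the same shape as ``ts.data`` (radians). Each
    epoch is Hilbert-transformed independently so transients never leak
    across epoch boundaries.
    """
    analytic = signal.hilbert(ts.data, axis=-1)
    return np.angle(analytic)


def default_window_samples(band: BandDefinition, fs: float,
                           *, cycles: float = 6.0) -> int:
    """Default sliding-window length: 6 cycles of the band's center frequency."""
    return max(2, int(round(cycles * fs / band.center)))


def sliding_plv(ts: RegionalTimeSeries, band: BandDefinition,
                window_len: int | None = None, step: int | None = None,
                *, assume_filtered: bool = False,
                trim_edges: bool = False) -> list[DynamicConnectome]:
    """Sliding-window PLV for every subject of a regional time series.

    Parameters
    ----------
    ts
        Regional time series. Band-pass filtered internally unless
        ``assume_filtered`` is set.
    band
        Frequency band; also determines the default window length
        (6 cycles of the center frequency).
    window_len, step
        Window length and hop in samples. Defaults: 6 center-frequency
        cycles, non-overlapping (step = window). Windows are laid out
        within each epoch; they never straddle epoch boundaries.
    trim_edges
        Drop the first and last window of each epoch to suppress
        filter/Hilbert edge transients (off by default).

    Returns
    -------
    list of DynamicConnectome, one per subject.
    """
    if window_len is None:
        window_len = default_window_samples(band, ts.fs)
    if step is None:
        step = window_len
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_len > ts.n_samples:
        raise ValueError(
            f"window ({window_len} samples) longer than epoch ({ts.n_samples})"
        )

    filtered = ts if assume_filtered else bandpass(ts, band)
    phase = instantaneous_phase(filtered)
    phasor = np.exp(1j * phase)  # subjects x epochs x rois x samples

    n_win_per_epoch = (ts.n_samples - window_len) // step + 1
    starts = np.arange(n_win_per_epoch) * step
    keep = slice(None)
    if trim_edges and n_win_per_epoch > 2:
        keep = slice(1, -1)
    starts = starts[keep]
    iu = np.triu_indices(ts.n_rois, k=1)

    out: list[DynamicConnectome] = []
    boundaries = tuple(e * len(starts) for e in range(ts.n_epochs))
    for s in range(ts.n_subjects):
        rows = []
        for e in range(ts.n_epochs):
            u = phasor[s, e]  # rois x samples
            for w0 in starts:
                uw = u[:, w0:w0 + window_len]
                m = uw @ uw.conj().T / window_len
                rows.append(np.abs(m)[iu])
        values = np.clip(np.asarray(rows), 0.0, 1.0)
        out.append(DynamicConnectome(
            values, window_len=window_len, step=step, band=band,
            epoch_boundaries=boundaries, n_rois=ts.n_rois,
            subject_id=f"sub-{s:03d}", trimmed=bool(trim_edges),
        ))
    return out


def static_plv(dyn: DynamicConnectome) -> ConnectivityMatrix:
    """Static connectome: arithmetic mean of PLV over all windows (all epochs pooled)."""
    if dyn.n_windows < 1:
        raise ValueError("need at least one window to average")
    mean_edges = dyn.values.mean(axis=0)
    return ConnectivityMatrix(matrix_from_edges(mean_edges, diagonal=1.0),
                              band=dyn.band, subject_id=dyn.subject_id)


def dynamic_variance(dyn: DynamicConnectome) -> VarianceMatrix:
    """Per-edge sample variance (n-1 denominator) of the concatenated PLV trajectory."""
    if dyn.n_windows < 2:
        raise ValueError("need at least two windows for a sample variance")
    var_edges = dyn.values.var(axis=0, ddof=1)
    return VarianceMatrix(matrix_from_edges(var_edges, diagonal=0.0),
                          band=dyn.band, subject_id=dyn.subject_id)
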