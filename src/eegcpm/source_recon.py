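"""Depth-weighted minimum-norm inverse solution and ROI aggregation.

The weighted minimum norm estimate (wMNE) maps sensor data back to
cortical sources with a depth-weighted, Tikhonov-regularized linear
kernel::

    K = W^-2 L^T (L W^-2 L^T + lambda I)^-1,   W = diag(||L[:, i]||^gamma)

where ``L`` is the lead field, ``gamma`` the depth-weighting exponent
(1 by default: deep sources, whose gain columns are small, are boosted)
and ``lambda`` the regularization strength. Estimated source series are
then averaged per ROI to give regional time series.

This is a toy forward/inverse pair: there is no head geometry, dipole
orientation, or noise-covariance estimation — only the algebra of the
inverse stage, sufficient to exercise the pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import RegionalTimeSeries, SensorTimeSeries
from .synth import LeadField

__all__ = [
    "InverseOperator",
    "default_lambda",
    "build_wmne_operator",
    "apply_inverse_and_aggregate",
]


@dataclass
class InverseOperator:
    """Linear inverse kernel (sources x sensors) with its settings."""

    kernel: np.ndarray
    lam: float
    depth_exponent: float

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def _depth_weights(lead: LeadField, depth_exponent: float) -> np.ndarray:
    return np.linalg.norm(lead.gain, axis=0) ** depth_exponent


def default_lambda(lead: LeadField, depth_exponent: float = 1.0,
                   snr_ratio: float = 1.0 / 9.0) -> float:
    """Conventional regularization: ratio * trace(L W^-2 L^T) / n_sensors.

    ``snr_ratio`` defaults to 1/9, the usual 1/SNR^2 heuristic at an
    assumed SNR of 3.
    """
    w2 = _depth_weights(lead, depth_exponent) ** 2
    gram_trace = float(np.einsum("ij,ij->", lead.gain / w2, lead.gain))
    return snr_ratio * gram_trace / lead.n_sensors


def build_wmne_operator(lead: LeadField, lam: float | None = None,
                        depth_exponent: float = 1.0) -> InverseOperator:
    """Assemble the depth-weighted minimum-norm inverse kernel.

    With ``lam=None`` the default SNR-heuristic regularization is used.
    At ``lam=0`` the inner matrix may be singular for rank-deficient
    lead fields; the resulting numerical error suggests setting
    ``lam > 0``.
    """
    if depth_exponent < 0:
        raise ValueError("depth_exponent must be nonnegative")
    if lam is None:
        lam = default_lambda(lead, depth_exponent)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    w2 = _depth_weights(lead, depth_exponent) ** 2
    lw = lead.gain / w2  # L W^-2, shape sensors x sources
    inner = lw @ lead.gain.T + lam * np.eye(lead.n_sensors)
    try:
        if lam > 0:
            solved = linalg.solve(inner, lw, assume_a="pos")
        else:
            solved = linalg.solve(inner, lw)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular inner matrix in wMNE; the lead field is likely "
            "rank-deficient — set lambda > 0"
        ) from err
    kernel = solved.T  # W^-2 L^T (L W^-2 L^T + lam I)^-1
    return InverseOperator(kernel, float(lam), depth_exponent)


def apply_inverse_and_aggregate(op: InverseOperator,
                                sensors: SensorTimeSeries,
                                source_to_roi: np.ndarray,
                                roi_names: tuple[str, ...] | None = None,
                                ) -> RegionalTimeSeries:
    """Estimate source series and average them per ROI.

    Source series = kernel @ sensor series, per subject and epoch; the
    ROI series is the per-sample arithmetic mean of its member sources
    (no sign flipping — the toy lead field carries no orientations).
    """
    source_to_roi = np.asarray(source_to_roi, dtype=int)
    if op.kernel.shape[1] != sensors.n_sensors:
        raise ValueError("kernel sensor dimension does not match the data")
    if op.kernel.shape[0] != source_to_roi.size:
        raise ValueError("kernel source dimension does not match source_to_roi")
    n_rois = int(source_to_roi.max()) + 1
    counts = np.bincount(source_to_roi, minlength=n_rois)
    if np.any(counts == 0):
        raise ValueError("every ROI needs at least one source")

    src = np.einsum("qn,bent->beqt", op.kernel, sensors.data)
    # mean over member sources, per ROI
    agg = np.zeros(src.shape[:2] + (n_rois, src.shape[-1]))
    for roi in range(n_rois):
        agg[:, :, roi] = src[:, :, source_to_roi == roi].mean(axis=2)
    if roi_names is None:
        roi_names = tuple(f"roi_{i:03d}" for i in range(n_rois))
    return RegionalTimeSeries(agg, sensors.fs, roi_names, sensors.epoch_len_s)
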