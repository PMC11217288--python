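"""Synthetic cohorts with planted brain-behavior structure.

Real resting-state EEG cohorts with creativity inventories are not
openly deposited, so every downstream stage is exercised on synthetic
data that emulates the study regime: 68-region parcellated time series
at 1000 Hz in three 40-s epochs, PLV connectomes in [0, 1], and
right-skewed behavior scores. A configurable subset of edges carries a
linear association with the behavioral trait (the "planted effect"),
which gives the pipeline a known ground truth to recover.

The planted mechanism is deliberately linear in the standardized trait:
connectome-based predictive modeling selects edges by Pearson
correlation, so a linear edge-trait association makes the pipeline's own
modeling assumption the ground truth rather than a confound.

Determinism: every generator derives one independent child stream per
subject from the master seed (``numpy.random.SeedSequence.spawn``), so
the same seed reproduces the same cohort bit-for-bit and growing the
cohort never perturbs already-generated subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import default_roi_names
from .connectivity import (
    BandDefinition,
    ConnectivityMatrix,
    bandpass,
    matrix_from_edges,
    n_edges,
)
from .containers import RegionalTimeSeries, SensorTimeSeries

logger = logging.getLogger(__name__)

BEHAVIOR_COLUMNS = ("subject_id", "c_act", "c_ach", "c_total",
                    "age", "gender", "education")

#: Lognormal parameters (mean and sd of log score) for the two creativity
#: scales. Chosen to give right-skewed scores whose totals fall inside the
#: inventory's 1-472 range, with activity contributing more than achievement.
#: The log-SDs are moderate so that a 90-subject cohort's standardized trait
#: stays within a few SD — heavier tails would routinely push planted edge
#: weights against the [0, 1] clip.
DEFAULT_SCORE_PARAMS = {
    "c_act": {"mean_log": 3.2, "sd_log": 0.5},
    "c_ach": {"mean_log": 2.4, "sd_log": 0.6},
}


def lognormal_mean(mean_log: float, sd_log: float) -> float:
    """Expected value of a lognormal with the given log-scale parameters."""
    return float(np.exp(mean_log + 0.5 * sd_log**2))


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth brain-behavior structure injected into synthetic cohorts.

    ``effect_size`` (beta) is the edge-weight change per unit of the
    standardized trait; positive edges gain ``+beta * trait``, negative
    edges ``-beta * trait``. ``noise_sd`` is the SD of the additive
    edge noise and ``baseline`` the trait-independent weight level.
    """

    positive_edges: tuple[int, ...]
    negative_edges: tuple[int, ...]
    effect_size: float = 0.2
    noise_sd: float = 0.02
    baseline: float = 0.5

    def __post_init__(self) -> None:
        pos = tuple(sorted(int(i) for i in self.positive_edges))
        neg = tuple(sorted(int(i) for i in self.negative_edges))
        if set(pos) & set(neg):
            raise ValueError("positive and negative planted edges overlap")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.baseline < 1.0:
            raise ValueError("baseline must lie in (0, 1)")
        object.__setattr__(self, "positive_edges", pos)
        object.__setattr__(self, "negative_edges", neg)

    def validate_for(self, n_rois: int) -> None:
        e = n_edges(n_rois)
        for idx in (*self.positive_edges, *self.negative_edges):
            if not 0 <= idx < e:
                raise ValueError(
                    f"planted edge index {idx} out of range for {n_rois} ROIs "
                    f"({e} edges)"
                )

    def to_dict(self) -> dict:
        return {
            "positive_edges": list(self.positive_edges),
            "negative_edges": list(self.negative_edges),
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "baseline": self.baseline,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedEffect":
        return cls(tuple(d["positive_edges"]), tuple(d["negative_edges"]),
                   d["effect_size"], d["noise_sd"], d["baseline"])


@dataclass
class LeadField:
    """Toy forward model: sensor gains plus a source-to-ROI assignment."""

    gain: np.ndarray
    source_to_roi: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_to_roi = np.asarray(self.source_to_roi, dtype=int)
        if self.gain.ndim != 2:
            raise ValueError("gain must be sensors x sources")
        if self.gain.shape[1] != self.source_to_roi.size:
            raise ValueError("source_to_roi length must equal the source count")
        col_norms = np.linalg.norm(self.gain, axis=0)
        if np.any(col_norms == 0.0):
            raise ValueError("lead field has an all-zero gain column")
        rois = np.unique(self.source_to_roi)
        expected = np.arange(self.source_to_roi.max() + 1)
        if not np.array_equal(rois, expected):
            raise ValueError("every ROI must own at least one source")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


# Domain tags keep the per-subject substreams of the different generators
# mutually independent even when they share one master seed.
_STREAM_BEHAVIOR = 1
_STREAM_CONNECTOME = 2
_STREAM_TIMESERIES = 3
_STREAM_FORWARD = 4


def _subject_rngs(seed: int, n_subjects: int,
                  stream: int) -> list[np.random.Generator]:
    root = np.random.SeedSequence(seed, spawn_key=(stream,))
    return [np.random.default_rng(c) for c in root.spawn(n_subjects)]


def standardize_trait(scores: np.ndarray) -> np.ndarray:
    """Center and scale a score vector to mean 0, SD 1 (population SD)."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant score vector")
    return (scores - scores.mean()) / sd


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(n_subjects: int, seed: int,
                      score_params: dict | None = None) -> pd.DataFrame:
    """Synthetic behavior table with creativity scores and covariates.

    Scores are right-skewed (lognormal) like real-life creativity
    inventories; ``c_total`` is exactly ``c_act + c_ach``. Covariates
    mimic a community adult cohort: age ~ N(39.6, 12.7) clipped to
    [18, 68] years, gender coded 0/1 (1 = female, p = 2/3), education an
    ordinal 0-5. The ``normalized`` flag lives in ``df.attrs``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    params = dict(DEFAULT_SCORE_PARAMS)
    if score_params:
        params.update(score_params)

    rows = []
    for s, rng in enumerate(_subject_rngs(seed, n_subjects, _STREAM_BEHAVIOR)):
        c_act = float(rng.lognormal(params["c_act"]["mean_log"],
                                    params["c_act"]["sd_log"]))
        c_ach = float(rng.lognormal(params["c_ach"]["mean_log"],
                                    params["c_ach"]["sd_log"]))
        age = float(np.clip(rng.normal(39.6, 12.7), 18.0, 68.0))
        gender = int(rng.random() < 2.0 / 3.0)
        education = int(rng.integers(0, 6))
        rows.append((f"sub-{s:03d}", c_act, c_ach, c_act + c_ach,
                     age, gender, education))
    df = pd.DataFrame(rows, columns=list(BEHAVIOR_COLUMNS))
    df.attrs["normalized"] = False
    return df


def normalize_behavior(behavior: pd.DataFrame) -> pd.DataFrame:
    """Max-normalize the three score columns to [0, 1] (within this cohort).

    Each score column is divided by its own within-cohort maximum, so
    the maximum maps to exactly 1. Applied independently per cohort,
    which is how heterogeneous scoring scales across datasets are
    reconciled before analysis.
    """
    out = behavior.copy()
    for col in ("c_act", "c_ach", "c_total"):
        mx = out[col].max()
        if not mx > 0:
            raise ValueError(f"cannot normalize {col}: non-positive maximum")
        out[col] = out[col] / mx
    out.attrs["normalized"] = True
    return out


# ---------------------------------------------------------------------------
# connectomes


def generate_connectomes(n_subjects: int, n_rois: int, planted: PlantedEffect,
                         trait: np.ndarray, seed: int,
                         *, subject_level_sd: float = 0.1,
                         clip_warn_fraction: float = 1e-3,
                         ) -> list[ConnectivityMatrix]:
    """Connectomes whose planted edges vary linearly with the trait.

    Each subject's edge vector is ``baseline + level + noise``, with
    ``+/- effect_size * trait`` added on the planted positive/negative
    edges; weights are clipped to [0, 1] (a warning is logged when
    clipping exceeds ``clip_warn_fraction`` of all weights).

    ``level`` is a per-subject global connectivity offset
    (SD ``subject_level_sd``) applied to every edge. It emulates the
    overall coupling-level differences real cohorts show (electrode
    impedance, vigilance, anatomy) and is behavior-independent. Because
    it loads equally on both tails, it cancels in the combined
    (positive minus negative) network index but contaminates each
    single-tail index — the structure that makes the combined model the
    robust one.

    ``trait`` must already be standardized (mean 0, SD 1).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    trait = np.asarray(trait, dtype=float)
    if trait.size != n_subjects:
        raise ValueError("trait length must equal n_subjects")
    if abs(trait.mean()) > 1e-6 or abs(trait.std() - 1.0) > 1e-6:
        raise ValueError("trait must be standardized (mean 0, SD 1)")
    planted.validate_for(n_rois)

    e = n_edges(n_rois)
    pos = np.asarray(planted.positive_edges, dtype=int)
    neg = np.asarray(planted.negative_edges, dtype=int)
    matrices = []
    n_clipped = 0
    for s, rng in enumerate(_subject_rngs(seed, n_subjects, _STREAM_CONNECTOME)):
        level = rng.normal(0.0, subject_level_sd) if subject_level_sd > 0 else 0.0
        edges = np.full(e, planted.baseline + level)
        edges[pos] += planted.effect_size * trait[s]
        edges[neg] -= planted.effect_size * trait[s]
        edges += rng.normal(0.0, planted.noise_sd, size=e)
        n_clipped += int(np.sum((edges < 0.0) | (edges > 1.0)))
        np.clip(edges, 0.0, 1.0, out=edges)
        matrices.append(ConnectivityMatrix(matrix_from_edges(edges),
                                           subject_id=f"sub-{s:03d}"))
    frac = n_clipped / (n_subjects * e)
    if frac > clip_warn_fraction:
        logger.warning("clipped %.3f%% of generated edge weights to [0, 1]",
                       100 * frac)
    return matrices


# ---------------------------------------------------------------------------
# time series


def _filtered_noise(rng: np.random.Generator, shape: tuple[int, ...],
                    band: BandDefinition, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise; ``shape`` is (rows, samples)."""
    raw = rng.standard_normal(shape)
    rts = RegionalTimeSeries(raw[np.newaxis, np.newaxis], fs,
                             tuple(f"r{i}" for i in range(shape[0])),
                             shape[1] / fs)
    out = bandpass(rts, band).data[0, 0]
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_timeseries(n_subjects: int, n_rois: int, fs: float,
                        epoch_len_s: float, n_epochs: int,
                        band: BandDefinition, planted: PlantedEffect,
                        trait: np.ndarray, seed: int,
                        *, coupling_mode: str = "static",
                        modulation_freq_hz: float = 0.6,
                        modulation_base: float = 0.3,
                        baseline_jitter_sd: float = 0.14,
                        ) -> RegionalTimeSeries:
    """Band-limited regional time series with planted phase coupling.

    Every ROI receives independent band-limited Gaussian noise. For each
    planted edge ``(i, j)`` a shared band-limited oscillation is mixed
    into both ROIs with mixing proportion ``a``::

        x = (1 - a) * own_noise + a * shared

    so ``a = 1`` makes the pair identical (PLV 1) and ``a = 0``
    independent.

    ``coupling_mode='static'``
        ``a`` is constant over time: ``baseline + effect_size * trait``
        for positive edges and ``baseline - effect_size * trait`` for
        negative ones — mean coupling strength carries the effect.
    ``coupling_mode='dynamic'``
        the mixing oscillates between ``baseline - modulation_base`` and
        ``baseline + modulation_base`` for *every* subject — identical
        coupling levels and time-averaged coupling — but the oscillation
        frequency depends on the trait:
        ``f = modulation_freq_hz * 2**(-effect_size * trait)`` for
        positive edges (``+effect_size`` for negative ones), i.e.,
        ``effect_size`` is in octaves of switching rate per trait SD.
        Slow switchers (high trait on a positive edge) hold each
        coupling state across many analysis windows, producing a large
        window-to-window PLV variance; fast switchers average the states
        out within each window. Only the temporal *variability* of
        coupling carries the effect, which is the regime the
        dynamic-variance pipeline is built to detect: an
        amplitude-in-trait modulation would leak into the static mean
        because PLV is nonlinear in the mixing proportion. A small
        residual static footprint remains (windows containing a state
        switch have downward-biased PLV), so each subject additionally
        receives a trait-independent random offset of the mean coupling
        level (``baseline_jitter_sd``, emulating individual differences
        in overall coupling strength) that swamps the residual mean
        signal while barely touching the variance signal.

    Each ROI may participate in at most one planted edge.
    """
    if fs < 2.0 * band.f_hi:
        raise ValueError(f"fs={fs} violates Nyquist for band {band.name}")
    if coupling_mode not in ("static", "dynamic"):
        raise ValueError(f"unknown coupling_mode {coupling_mode!r}")
    trait = np.asarray(trait, dtype=float)
    if trait.size != n_subjects:
        raise ValueError("trait length must equal n_subjects")
    planted.validate_for(n_rois)

    iu = np.triu_indices(n_rois, k=1)
    pairs = {idx: (int(iu[0][idx]), int(iu[1][idx]))
             for idx in (*planted.positive_edges, *planted.negative_edges)}
    used: set[int] = set()
    for i, j in pairs.values():
        if i in used or j in used:
            raise ValueError("each ROI may appear in at most one planted edge "
                             "for time-series generation")
        used.update((i, j))

    n_samples = round(epoch_len_s * fs)
    t = np.arange(n_samples) / fs
    data = np.empty((n_subjects, n_epochs, n_rois, n_samples))
    for s, rng in enumerate(_subject_rngs(seed, n_subjects, _STREAM_TIMESERIES)):
        jitter = rng.normal(0.0, baseline_jitter_sd) \
            if coupling_mode == "dynamic" and baseline_jitter_sd > 0 else 0.0
        for ep in range(n_epochs):
            own = _filtered_noise(rng, (n_rois, n_samples), band, fs)
            x = own.copy()
            for idx, (i, j) in pairs.items():
                sign = 1.0 if idx in planted.positive_edges else -1.0
                shared = _filtered_noise(rng, (1, n_samples), band, fs)[0]
                if coupling_mode == "static":
                    a = np.clip(planted.baseline
                                + sign * planted.effect_size * trait[s], 0.0, 1.0)
                else:
                    amp = min(modulation_base, planted.baseline,
                              1.0 - planted.baseline)
                    f_mod = modulation_freq_hz * 2.0 ** (
                        -sign * planted.effect_size * trait[s])
                    phase0 = rng.uniform(0.0, 2.0 * np.pi)
                    a = np.clip(planted.baseline + jitter
                                + amp * np.sin(2 * np.pi * f_mod * t + phase0),
                                0.0, 1.0)
                x[i] = (1.0 - a) * own[i] + a * shared
                x[j] = (1.0 - a) * own[j] + a * shared
            data[s, ep] = x
    return RegionalTimeSeries(data, fs, default_roi_names(n_rois), epoch_len_s)


# ---------------------------------------------------------------------------
# toy forward model


def generate_toy_forward(rts: RegionalTimeSeries, n_sensors: int | None = None,
                         sources_per_roi: int = 1,
                         sensor_noise_sd: float = 0.0, seed: int = 0,
                         gain: np.ndarray | str | None = None,
                         ) -> tuple[LeadField, SensorTimeSeries]:
    """Project regional time series through a toy lead field to sensors.

    Each ROI contributes ``sources_per_roi`` sources carrying its time
    series; sensor data is ``gain @ sources + noise``. The default gain
    is a seeded random Gaussian matrix (well-conditioned with high
    probability); pass ``gain='identity'`` for a lossless projection.
    """
    n_sources = rts.n_rois * sources_per_roi
    if n_sensors is None:
        n_sensors = n_sources
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_FORWARD,)))
    if gain is None:
        g = rng.standard_normal((n_sensors, n_sources))
    elif isinstance(gain, str) and gain == "identity":
        if n_sensors != n_sources:
            raise ValueError("identity gain needs n_sensors == n_sources")
        g = np.eye(n_sources)
    else:
        g = np.asarray(gain, dtype=float)
    source_to_roi = np.repeat(np.arange(rts.n_rois), sources_per_roi)
    lead = LeadField(g, source_to_roi)

    # sources: replicate each ROI series for its member sources
    src = np.repeat(rts.data, sources_per_roi, axis=2)
    sens = np.einsum("ns,best->bent", g, src)
    if sensor_noise_sd > 0:
        sens = sens + rng.normal(0.0, sensor_noise_sd, size=sens.shape)
    sensors = SensorTimeSeries(sens, rts.fs, rts.epoch_len_s)
    return lead, sensors


# ---------------------------------------------------------------------------
# recovery scoring


def score_edge_recovery(found_positive: np.ndarray, found_negative: np.ndarray,
                        planted: PlantedEffect) -> dict[str, float]:
    """Recall and false-discovery proportion of recovered planted edges.

    An edge counts as recovered only in its planted tail (a planted
    positive edge found in the negative tail is both a miss and a false
    discovery).
    """
    found_pos = set(int(i) for i in np.asarray(found_positive).ravel())
    found_neg = set(int(i) for i in np.asarray(found_negative).ravel())
    true_pos = set(planted.positive_edges)
    true_neg = set(planted.negative_edges)
    hits = len(found_pos & true_pos) + len(found_neg & true_neg)
    n_true = len(true_pos) + len(true_neg)
    n_found = len(found_pos) + len(found_neg)
    recall = hits / n_true if n_true else float("nan")
    fdp = (n_found - hits) / n_found if n_found else 0.0
    return {"recall": recall, "fdp": fdp,
            "n_found": float(n_found), "n_true": float(n_true)}
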