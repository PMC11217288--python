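"""Connectome-based predictive modeling (CPM).

The pipeline relates a vector of behavior scores to subjects' connectome
edge weights:

1. **Standardize** each edge across training subjects (z-transform with
   train-set mean and sample SD; held-out subjects reuse the train
   parameters — never their own).
2. **Select** edges whose standardized weights correlate with behavior
   below a significance threshold (default p < 0.01, two-sided t test),
   split into a positive tail ("high" network) and a negative tail
   ("low" network).
3. **Summarize** each subject into a single network-strength index:
   sum of positive-tail z-weights minus sum of negative-tail z-weights
   (combined mode; single-tail modes use one sum).
4. **Fit** an epsilon-insensitive support vector regression with an RBF
   kernel on (index, score) pairs.
5. **Validate** by leave-one-out or k-fold cross-validation with pooled
   observed-vs-predicted metrics, a score-permutation null, consensus
   (persistence-thresholded) networks, and external transfer of the
   frozen model to an independent cohort.

Steps 1-3 are estimated inside each training fold only, which is what
makes the cross-validated correlation an honest estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .connectivity import ConnectivityMatrix, VarianceMatrix
from .metrics import MetricSet, regression_metrics

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_N_PERM",
    "DEFAULT_CONSENSUS_THRESHOLD",
    "MODES",
    "EdgeStandardization",
    "PredictiveNetworks",
    "SummaryFeature",
    "SVRHyper",
    "CVConfig",
    "ValidationReport",
    "PermutationResult",
    "CPMModelBundle",
    "fit_standardization",
    "apply_standardization",
    "select_edges",
    "summary_index",
    "summary_features",
    "fit_svr",
    "predict_svr",
    "make_folds",
    "features_matrix",
    "run_internal_cv",
    "run_dynamic_cpm",
    "permutation_test",
    "consensus_networks",
    "finalize_model",
    "external_validate",
]

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 5000
DEFAULT_CONSENSUS_THRESHOLD = 0.9
MODES = ("positive", "negative", "combined")


# ---------------------------------------------------------------------------
# standardization


@dataclass
class EdgeStandardization:
    """Per-edge z-transform parameters estimated on a training set.

    Constant edges (zero training SD) are masked: their z-score is
    defined as 0 for every subject, including held-out ones.
    """

    means: np.ndarray
    sds: np.ndarray
    constant_edge_mask: np.ndarray
    denominator_convention: str = "sample (n-1)"

    @property
    def n_features(self) -> int:
        return self.means.size


def fit_standardization(train_edges: np.ndarray) -> EdgeStandardization:
    """Estimate per-edge mean and sample SD from a subjects x edges matrix."""
    x = np.asarray(train_edges, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a subjects x edges matrix with >= 3 subjects")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    mask = sds == 0.0
    sds = np.where(mask, 1.0, sds)
    return EdgeStandardization(means, sds, mask)


def apply_standardization(std: EdgeStandardization,
                          edges: np.ndarray) -> np.ndarray:
    """z = (x - train_mean) / train_sd; masked (constant) edges map to 0."""
    x = np.atleast_2d(np.asarray(edges, dtype=float))
    if x.shape[1] != std.n_features:
        raise ValueError("edge count does not match the standardization")
    z = (x - std.means) / std.sds
    z[:, std.constant_edge_mask] = 0.0
    return z if np.asarray(edges).ndim == 2 else z[0]


# ---------------------------------------------------------------------------
# edge selection


@dataclass
class PredictiveNetworks:
    """Positive- and negative-tail edge index sets from one selection.

    ``persistence_*`` holds, when produced by :func:`consensus_networks`,
    the per-edge fraction of folds in which the edge was selected.
    """

    positive_edges: np.ndarray
    negative_edges: np.ndarray
    alpha: float = DEFAULT_ALPHA
    persistence_positive: np.ndarray | None = None
    persistence_negative: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positive_edges = np.asarray(self.positive_edges, dtype=int)
        self.negative_edges = np.asarray(self.negative_edges, dtype=int)
        if np.intersect1d(self.positive_edges, self.negative_edges).size:
            raise ValueError("positive and negative tails overlap")

    @property
    def degenerate(self) -> bool:
        return self.positive_edges.size == 0 and self.negative_edges.size == 0

    def to_dict(self) -> dict:
        d = {"positive_edges": self.positive_edges.tolist(),
             "negative_edges": self.negative_edges.tolist(),
             "alpha": self.alpha}
        for k in ("persistence_positive", "persistence_negative"):
            v = getattr(self, k)
            d[k] = None if v is None else np.asarray(v).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PredictiveNetworks":
        return cls(np.asarray(d["positive_edges"], dtype=int),
                   np.asarray(d["negative_edges"], dtype=int),
                   d.get("alpha", DEFAULT_ALPHA),
                   None if d.get("persistence_positive") is None
                   else np.asarray(d["persistence_positive"]),
                   None if d.get("persistence_negative") is None
                   else np.asarray(d["persistence_negative"]))


def _edgewise_pearson(z_edges: np.ndarray,
                      scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-edge Pearson r and two-sided t-based p."""
    n = scores.size
    xc = z_edges - z_edges.mean(axis=0)
    yc = scores - scores.mean()
    xn = np.sqrt(np.sum(xc * xc, axis=0))
    yn = np.sqrt(np.sum(yc * yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (xn * yn)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(t), 0.0, p))
    return r, p


def select_edges(z_edges: np.ndarray, scores: np.ndarray,
                 alpha: float = DEFAULT_ALPHA) -> PredictiveNetworks:
    """Threshold per-edge behavior correlations into positive/negative tails.

    Selection is invariant to any per-edge affine map with positive
    scale, so it gives identical tails on raw or z-transformed weights;
    constant edges can never be selected.
    """
    z_edges = np.asarray(z_edges, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if z_edges.shape[0] != scores.size:
        raise ValueError("subject counts disagree")
    if scores.size < 4:
        raise ValueError("need >= 4 subjects for a defined p value")
    if np.ptp(scores) == 0:
        raise ValueError("behavior scores are constant")
    r, p = _edgewise_pearson(z_edges, scores)
    sig = (p < alpha) & np.isfinite(r)
    pos = np.flatnonzero(sig & (r > 0))
    neg = np.flatnonzero(sig & (r < 0))
    return PredictiveNetworks(pos, neg, alpha)


# ---------------------------------------------------------------------------
# summary index


@dataclass(frozen=True)
class SummaryFeature:
    """Single-subject network-strength index."""

    value: float
    mode: str
    degenerate: bool = False


def summary_features(z_edges: np.ndarray, networks: PredictiveNetworks,
                     mode: str) -> tuple[np.ndarray, bool]:
    """Network-strength index for every row of a subjects x edges z matrix.

    combined = (sum over positive tail) - (sum over negative tail);
    empty tails contribute 0. Returns the values and a degenerate flag
    (True when every relevant tail is empty).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    z = np.atleast_2d(np.asarray(z_edges, dtype=float))
    for idx_set in (networks.positive_edges, networks.negative_edges):
        if idx_set.size and idx_set.max() >= z.shape[1]:
            raise ValueError("network edge index out of bounds")
    pos = z[:, networks.positive_edges].sum(axis=1)
    neg = z[:, networks.negative_edges].sum(axis=1)
    if mode == "positive":
        values, degenerate = pos, networks.positive_edges.size == 0
    elif mode == "negative":
        values, degenerate = neg, networks.negative_edges.size == 0
    else:
        values, degenerate = pos - neg, networks.degenerate
    return values, degenerate


def summary_index(z_vector: np.ndarray, networks: PredictiveNetworks,
                  mode: str = "combined") -> SummaryFeature:
    """Single-subject wrapper around :func:`summary_features`."""
    values, degenerate = summary_features(np.atleast_2d(z_vector), networks, mode)
    return SummaryFeature(float(values[0]), mode, degenerate)


# ---------------------------------------------------------------------------
# SVR


@dataclass(frozen=True)
class SVRHyper:
    """RBF-kernel SVR hyperparameters.

    ``gamma=None`` uses the 1 / (n_features * feature variance)
    bandwidth heuristic, resolved to a number at fit time so it can be
    frozen into a model bundle.
    """

    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _resolve_gamma(features: np.ndarray, hyper: SVRHyper) -> float:
    if hyper.gamma is not None:
        return hyper.gamma
    var = float(features.var())
    if var == 0.0:
        var = 1.0
    return 1.0 / (features.shape[1] * var)


def fit_svr(features: np.ndarray, scores: np.ndarray,
            hyper: SVRHyper = SVRHyper()) -> SVR:
    """Fit an epsilon-insensitive RBF SVR on 1-D summary features."""
    f = np.asarray(features, dtype=float).reshape(-1, 1)
    y = np.asarray(scores, dtype=float)
    if f.shape[0] < 3:
        raise ValueError("need >= 3 training points")
    model = SVR(kernel="rbf", C=hyper.C, epsilon=hyper.epsilon,
                gamma=_resolve_gamma(f, hyper))
    model.fit(f, y)
    return model


def predict_svr(model: SVR, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features, dtype=float).reshape(-1, 1))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme plus selection/permutation settings."""

    scheme: str = "loo"
    k: int | None = None
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM

    def __post_init__(self) -> None:
        if self.scheme not in ("loo", "kfold"):
            raise ValueError("scheme must be 'loo' or 'kfold'")
        if self.scheme == "kfold" and (self.k is None or self.k < 2):
            raise ValueError("k-fold needs k >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def make_folds(n_subjects: int,
               config: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train, test) index pairs: one per subject for LOO, else a seeded
    random partition into k near-equal folds (no stratification)."""
    idx = np.arange(n_subjects)
    if config.scheme == "loo":
        return [(np.delete(idx, i), np.array([i])) for i in idx]
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n_subjects)
    parts = np.array_split(perm, config.k)
    return [(np.setdiff1d(idx, test), np.sort(test)) for test in parts]


def features_matrix(connectomes) -> np.ndarray:
    """Subjects x edges matrix from matrices, edge vectors, or an array."""
    if isinstance(connectomes, np.ndarray):
        return np.asarray(connectomes, dtype=float)
    rows = []
    for c in connectomes:
        if isinstance(c, (ConnectivityMatrix, VarianceMatrix)):
            rows.append(c.edge_vector())
        else:
            rows.append(np.asarray(c, dtype=float))
    return np.asarray(rows)


@dataclass
class ValidationReport:
    """Pooled observed-vs-predicted evaluation of one tail mode."""

    mode: str
    scheme: str
    n_folds: int
    r: float
    p_param: float
    mae: float
    r2_sq: float
    r2_ss: float
    observed: np.ndarray
    predicted: np.ndarray
    p_perm: float | None = None
    fold_mean_r: float | None = None
    fold_networks: list[PredictiveNetworks] = field(default_factory=list)
    fold_standardizations: list[EdgeStandardization] = field(default_factory=list)
    degenerate: bool = False
    constant_predictions: bool = False

    @property
    def metrics(self) -> MetricSet:
        return MetricSet(self.r, self.p_param, self.mae, self.r2_sq, self.r2_ss)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "scheme": self.scheme, "n_folds": self.n_folds,
            "r": self.r, "p_param": self.p_param, "p_perm": self.p_perm,
            "mae": self.mae, "r2_sq": self.r2_sq, "r2_ss": self.r2_ss,
            "fold_mean_r": self.fold_mean_r, "degenerate": self.degenerate,
            "constant_predictions": self.constant_predictions,
            "observed": np.asarray(self.observed).tolist(),
            "predicted": np.asarray(self.predicted).tolist(),
            "fold_networks": [n.to_dict() for n in self.fold_networks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(
            mode=d["mode"], scheme=d["scheme"], n_folds=d["n_folds"],
            r=d["r"], p_param=d["p_param"], mae=d["mae"], r2_sq=d["r2_sq"],
            r2_ss=d["r2_ss"], observed=np.asarray(d["observed"]),
            predicted=np.asarray(d["predicted"]), p_perm=d.get("p_perm"),
            fold_mean_r=d.get("fold_mean_r"),
            fold_networks=[PredictiveNetworks.from_dict(n)
                           for n in d.get("fold_networks", [])],
            degenerate=d.get("degenerate", False),
            constant_predictions=d.get("constant_predictions", False),
        )


def _pooled_report(mode: str, config: CVConfig, n_folds: int,
                   observed: np.ndarray, predicted: np.ndarray,
                   fold_networks: list[PredictiveNetworks],
                   fold_stds: list[EdgeStandardization],
                   fold_r: list[float], all_degenerate: bool,
                   ) -> ValidationReport:
    # Metrics always come from the actual pooled predictions, even when no
    # fold selected an edge (the report is then flagged degenerate, but the
    # trivial per-fold constants are still what the pipeline predicts —
    # substituting an arbitrary r would bias the permutation null). Only
    # exactly constant predictions leave r undefined; those report r = 0
    # with p undefined.
    constant = bool(np.ptp(predicted) == 0)
    if constant:
        r, p, r2_sq = 0.0, float("nan"), 0.0
        mae = float(np.mean(np.abs(observed - predicted)))
        ss_tot = float(np.sum((observed - observed.mean()) ** 2))
        r2_ss = 1.0 - float(np.sum((observed - predicted) ** 2)) / ss_tot
    else:
        m = regression_metrics(observed, predicted)
        r, p, mae, r2_sq, r2_ss = m.r, m.p, m.mae, m.r2_sq, m.r2_ss
    if all_degenerate:
        p = float("nan")  # no edge was ever selected: the model is invalid
    fold_mean_r = float(np.mean(fold_r)) if fold_r else None
    return ValidationReport(
        mode=mode, scheme=config.scheme, n_folds=n_folds, r=r, p_param=p,
        mae=mae, r2_sq=r2_sq, r2_ss=r2_ss, observed=observed,
        predicted=predicted, fold_mean_r=fold_mean_r,
        fold_networks=fold_networks, fold_standardizations=fold_stds,
        degenerate=all_degenerate, constant_predictions=constant,
    )


def run_internal_cv(connectomes, scores, config: CVConfig,
                    modes: Sequence[str] = MODES,
                    hyper: SVRHyper = SVRHyper(),
                    keep_fold_details: bool = True,
                    min_subjects: int = 10,
                    ) -> dict[str, ValidationReport]:
    """Cross-validated CPM: one :class:`ValidationReport` per tail mode.

    Per fold, standardization and edge selection are estimated on the
    training subjects only; the held-out subjects are transformed with
    train parameters, summarized on the train-selected networks, and
    predicted by an SVR fitted on the training pairs. Predictions are
    pooled across folds before computing metrics (with one test subject
    per LOO fold, per-fold correlations are undefined); for k-fold the
    fold-averaged r is additionally reported.
    """
    X = features_matrix(connectomes)
    y = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if y.size != n:
        raise ValueError("scores length does not match the subject count")
    if n < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects")
    folds = make_folds(n, config)

    predicted = {m: np.zeros(n) for m in modes}
    fold_r: dict[str, list[float]] = {m: [] for m in modes}
    any_selected = {m: False for m in modes}
    fold_networks: list[PredictiveNetworks] = []
    fold_stds: list[EdgeStandardization] = []

    for train, test in folds:
        std = fit_standardization(X[train])
        z_train = apply_standardization(std, X[train])
        z_test = apply_standardization(std, X[test])
        nets = select_edges(z_train, y[train], config.alpha)
        if keep_fold_details:
            fold_networks.append(nets)
            fold_stds.append(std)
        for m in modes:
            f_train, degen = summary_features(z_train, nets, m)
            f_test, _ = summary_features(z_test, nets, m)
            any_selected[m] |= not degen
            model = fit_svr(f_train, y[train], hyper)
            pred = predict_svr(model, f_test)
            predicted[m][test] = pred
            if config.scheme == "kfold" and test.size >= 3 \
                    and np.ptp(pred) > 0 and np.ptp(y[test]) > 0:
                fold_r[m].append(float(np.corrcoef(y[test], pred)[0, 1]))

    return {m: _pooled_report(m, config, len(folds), y, predicted[m],
                              fold_networks, fold_stds, fold_r[m],
                              not any_selected[m])
            for m in modes}


def run_dynamic_cpm(variance_matrices, scores, config: CVConfig,
                    modes: Sequence[str] = MODES,
                    hyper: SVRHyper = SVRHyper(),
                    keep_fold_details: bool = True,
                    ) -> dict[str, ValidationReport]:
    """CPM on dynamic-variance features.

    The contract and code path are identical to :func:`run_internal_cv`;
    only the feature semantics differ (per-edge temporal variance of the
    sliding-window PLV trajectory instead of static PLV).
    """
    return run_internal_cv(variance_matrices, scores, config, modes, hyper,
                           keep_fold_details)


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationResult:
    """Observed pooled r, the permutation null, and the permutation p."""

    r_observed: float
    null_r: np.ndarray
    p_perm: float
    n_perm: int
    add_one_smoothing: bool = False


def permutation_test(connectomes, scores, config: CVConfig,
                     n_perm: int | None = None, seed: int | None = None,
                     mode: str = "combined", hyper: SVRHyper = SVRHyper(),
                     add_one_smoothing: bool = False,
                     min_subjects: int = 10) -> PermutationResult:
    """Score-permutation null for the cross-validated prediction r.

    Each permutation shuffles the entire score vector once and reruns
    the full cross-validated pipeline, including per-fold edge
    re-selection. The p value is the literal counting formula
    ``#(r_null >= r_observed) / n_perm`` (which can be exactly 0); set
    ``add_one_smoothing`` for the conventional (b + 1) / (n + 1)
    estimator.
    """
    if n_perm is None:
        n_perm = config.n_perm
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = features_matrix(connectomes)
    y = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    observed = run_internal_cv(X, y, config, modes=(mode,), hyper=hyper,
                               keep_fold_details=False,
                               min_subjects=min_subjects)[mode]
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null[b] = run_internal_cv(X, y_perm, config, modes=(mode,),
                                  hyper=hyper, keep_fold_details=False,
                                  min_subjects=min_subjects)[mode].r
    exceed = int(np.sum(null >= observed.r))
    if add_one_smoothing:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    return PermutationResult(observed.r, null, float(p), n_perm,
                             add_one_smoothing)


# ---------------------------------------------------------------------------
# consensus and external validation


def consensus_networks(fold_networks: Sequence[PredictiveNetworks],
                       threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
                       n_edges: int | None = None) -> PredictiveNetworks:
    """Edges selected in at least ``threshold`` of the folds, per tail.

    The persistence fraction of every edge is retained alongside the
    thresholded sets.
    """
    if not fold_networks:
        raise ValueError("need at least one fold")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if n_edges is None:
        n_edges = 1 + max(
            [int(max(n.positive_edges.max(initial=0),
                     n.negative_edges.max(initial=0)))
             for n in fold_networks])
    pos_counts = np.zeros(n_edges)
    neg_counts = np.zeros(n_edges)
    for nets in fold_networks:
        pos_counts[nets.positive_edges] += 1
        neg_counts[nets.negative_edges] += 1
    pos_frac = pos_counts / len(fold_networks)
    neg_frac = neg_counts / len(fold_networks)
    return PredictiveNetworks(
        np.flatnonzero(pos_frac >= threshold),
        np.flatnonzero(neg_frac >= threshold),
        alpha=fold_networks[0].alpha,
        persistence_positive=pos_frac,
        persistence_negative=neg_frac,
    )


def _rbf_predict(features: np.ndarray, support: np.ndarray,
                 dual_coef: np.ndarray, intercept: float,
                 gamma: float) -> np.ndarray:
    """Numpy RBF-SVR decision function; the bundle's own predict path."""
    f = np.asarray(features, dtype=float).reshape(-1, 1)
    d2 = (f - support.reshape(1, -1)) ** 2
    return np.exp(-gamma * d2) @ dual_coef + intercept


@dataclass
class CPMModelBundle:
    """A frozen CPM model: standardization + consensus networks + SVR.

    Prediction is computed from the stored support vectors in numpy, so
    a serialize/deserialize round trip reproduces predictions
    bit-identically (doubles survive JSON via shortest-round-trip repr).
    """

    standardization: EdgeStandardization
    networks: PredictiveNetworks
    mode: str
    svr_support: np.ndarray
    svr_dual_coef: np.ndarray
    svr_intercept: float
    svr_gamma: float
    hyper: SVRHyper
    provenance: dict = field(default_factory=dict)

    def summary(self, edge_matrix: np.ndarray) -> np.ndarray:
        z = apply_standardization(self.standardization,
                                  np.atleast_2d(edge_matrix))
        values, _ = summary_features(z, self.networks, self.mode)
        return values

    def predict(self, edge_matrix: np.ndarray) -> np.ndarray:
        """Predicted scores from raw (unstandardized) edge vectors."""
        return _rbf_predict(self.summary(edge_matrix), self.svr_support,
                            self.svr_dual_coef, self.svr_intercept,
                            self.svr_gamma)

    def to_dict(self) -> dict:
        return {
            "standardization": {
                "means": self.standardization.means.tolist(),
                "sds": self.standardization.sds.tolist(),
                "constant_edge_mask":
                    self.standardization.constant_edge_mask.tolist(),
                "denominator_convention":
                    self.standardization.denominator_convention,
            },
            "networks": self.networks.to_dict(),
            "mode": self.mode,
            "svr": {
                "kernel": "RBF",
                "support": self.svr_support.tolist(),
                "dual_coef": self.svr_dual_coef.tolist(),
                "intercept": self.svr_intercept,
                "gamma": self.svr_gamma,
                "C": self.hyper.C,
                "epsilon": self.hyper.epsilon,
            },
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "CPMModelBundle":
        s = d["standardization"]
        std = EdgeStandardization(
            np.asarray(s["means"]), np.asarray(s["sds"]),
            np.asarray(s["constant_edge_mask"], dtype=bool),
            s.get("denominator_convention", "sample (n-1)"),
        )
        svr = d["svr"]
        return cls(
            standardization=std,
            networks=PredictiveNetworks.from_dict(d["networks"]),
            mode=d["mode"],
            svr_support=np.asarray(svr["support"]),
            svr_dual_coef=np.asarray(svr["dual_coef"]),
            svr_intercept=svr["intercept"],
            svr_gamma=svr["gamma"],
            hyper=SVRHyper(C=svr["C"], epsilon=svr["epsilon"],
                           gamma=svr["gamma"]),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, s: str) -> "CPMModelBundle":
        return cls.from_dict(json.loads(s))


def finalize_model(connectomes, scores, consensus: PredictiveNetworks,
                   hyper: SVRHyper = SVRHyper(), mode: str = "combined",
                   provenance: dict | None = None) -> CPMModelBundle:
    """Refit standardization and SVR on the full internal cohort.

    The per-fold models of the internal validation differ slightly; the
    frozen model carried to external cohorts is the deterministic refit
    on all internal subjects, restricted to the consensus networks.
    """
    if mode == "combined" and consensus.degenerate:
        raise ValueError("consensus networks are empty in both tails")
    if mode == "positive" and consensus.positive_edges.size == 0:
        raise ValueError("consensus positive tail is empty")
    if mode == "negative" and consensus.negative_edges.size == 0:
        raise ValueError("consensus negative tail is empty")
    X = features_matrix(connectomes)
    y = np.asarray(scores, dtype=float)
    std = fit_standardization(X)
    z = apply_standardization(std, X)
    feats, _ = summary_features(z, consensus, mode)
    gamma = _resolve_gamma(feats.reshape(-1, 1), hyper)
    model = fit_svr(feats, y, SVRHyper(hyper.C, hyper.epsilon, gamma))
    prov = {"mode": mode, "alpha": consensus.alpha,
            "n_subjects": int(X.shape[0])}
    if provenance:
        prov.update(provenance)
    return CPMModelBundle(
        standardization=std, networks=consensus, mode=mode,
        svr_support=model.support_vectors_.ravel().copy(),
        svr_dual_coef=model.dual_coef_.ravel().copy(),
        svr_intercept=float(model.intercept_[0]),
        svr_gamma=gamma, hyper=hyper, provenance=prov,
    )


def external_validate(bundle: CPMModelBundle, new_connectomes, new_scores,
                      normalize: bool = True) -> ValidationReport:
    """Apply a frozen bundle to an independent cohort.

    New edges are standardized with the bundle's training-cohort
    parameters (never the new cohort's own); behavior scores are
    max-normalized within the new cohort before comparison, reconciling
    heterogeneous scoring scales across datasets.
    """
    X = features_matrix(new_connectomes)
    if X.shape[1] != bundle.standardization.n_features:
        raise ValueError(
            f"edge count mismatch: bundle expects "
            f"{bundle.standardization.n_features}, got {X.shape[1]}")
    y = np.asarray(new_scores, dtype=float)
    if normalize:
        mx = y.max()
        if not mx > 0:
            raise ValueError("cannot max-normalize non-positive scores")
        y = y / mx
    predicted = bundle.predict(X)
    constant = bool(np.ptp(predicted) == 0)
    if constant:
        r, p, r2_sq = 0.0, float("nan"), 0.0
        mae = float(np.mean(np.abs(y - predicted)))
        r2_ss = 1.0 - float(np.sum((y - predicted) ** 2)) / float(
            np.sum((y - y.mean()) ** 2))
    else:
        m = regression_metrics(y, predicted)
        r, p, mae, r2_sq, r2_ss = m.r, m.p, m.mae, m.r2_sq, m.r2_ss
    return ValidationReport(
        mode=bundle.mode, scheme="external", n_folds=0, r=r, p_param=p,
        mae=mae, r2_sq=r2_sq, r2_ss=r2_ss, observed=y, predicted=predicted,
        constant_predictions=constant,
    )
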