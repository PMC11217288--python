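"""File formats: behavior CSV, HDF5 array containers, TSV edge lists, JSON.

Layout conventions
------------------
* Behavior tables: UTF-8 comma-separated CSV with header
  ``subject_id,c_act,c_ach,c_total,age,gender,education``.
* Array containers: HDF5 with datasets ``/data``, ``/fs``, ``/roi_names``
  (and ``/window_meta`` for dynamic outputs).
* Edge lists: TSV with columns ``roi_i``, ``roi_j``, ``weight`` (static
  matrices) or ``roi_i``, ``roi_j``, ``tail``, ``persistence``
  (consensus networks).
* Reports and model bundles: JSON (doubles round-trip exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, edge_pairs
from .containers import RegionalTimeSeries
from .cpm import CPMModelBundle, PredictiveNetworks, ValidationReport
from .synth import BEHAVIOR_COLUMNS


class SchemaError(ValueError):
    """A file does not match the expected schema."""


# ---------------------------------------------------------------------------
# behavior CSV


def write_behavior_csv(behavior: pd.DataFrame, path) -> None:
    behavior.to_csv(path, index=False, columns=list(BEHAVIOR_COLUMNS))


def read_behavior_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing behavior columns {sorted(missing)}")
    for col in ("c_act", "c_ach", "c_total"):
        if df[col].isna().any():
            bad = int(df[col].isna().idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path}: NaN score in column {col!r} "
                              f"(line {bad})")
    df.attrs["normalized"] = bool(np.isclose(df["c_total"].max(), 1.0))
    return df


# ---------------------------------------------------------------------------
# HDF5 arrays


def write_timeseries_h5(ts: RegionalTimeSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("fs", data=float(ts.fs))
        f.create_dataset("roi_names",
                         data=np.array(ts.roi_names, dtype="S64"))
        f.create_dataset("epoch_len_s", data=float(ts.epoch_len_s))


def read_timeseries_h5(path) -> RegionalTimeSeries:
    with h5py.File(path, "r") as f:
        for ds in ("data", "fs", "roi_names", "epoch_len_s"):
            if ds not in f:
                raise SchemaError(f"{path}: missing dataset /{ds}")
        return RegionalTimeSeries(
            f["data"][()], float(f["fs"][()]),
            tuple(n.decode() for n in f["roi_names"][()]),
            float(f["epoch_len_s"][()]),
        )


def write_connectomes_h5(matrices: list[ConnectivityMatrix], path,
                         extra: dict | None = None) -> None:
    """Stack of subject connectivity matrices as /data (subjects x n x n)."""
    data = np.stack([m.weights for m in matrices])
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("subject_ids", data=np.array(
            [m.subject_id for m in matrices], dtype="S32"))
        if matrices[0].band is not None:
            band = matrices[0].band
            f.attrs["band_name"] = band.name
            f.attrs["band_f_lo"] = band.f_lo
            f.attrs["band_f_hi"] = band.f_hi
        for k, v in (extra or {}).items():
            f.attrs[k] = v


def read_connectomes_h5(path) -> list[ConnectivityMatrix]:
    from .connectivity import BandDefinition
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise SchemaError(f"{path}: missing dataset /data")
        data = f["data"][()]
        ids = [s.decode() for s in f["subject_ids"][()]] \
            if "subject_ids" in f else [""] * data.shape[0]
        band = None
        if "band_name" in f.attrs:
            band = BandDefinition(str(f.attrs["band_name"]),
                                  float(f.attrs["band_f_lo"]),
                                  float(f.attrs["band_f_hi"]))
    return [ConnectivityMatrix(w, band=band, subject_id=sid)
            for w, sid in zip(data, ids)]


# ---------------------------------------------------------------------------
# TSV edge lists


def write_edge_list_tsv(matrix: ConnectivityMatrix, path,
                        roi_names: tuple[str, ...] | None = None) -> None:
    pairs = edge_pairs(matrix.n_rois)
    names = roi_names or tuple(f"roi_{i:03d}" for i in range(matrix.n_rois))
    weights = matrix.edge_vector()
    df = pd.DataFrame({"roi_i": [names[i] for i in pairs[:, 0]],
                       "roi_j": [names[j] for j in pairs[:, 1]],
                       "weight": weights})
    df.to_csv(path, sep="\t", index=False)


def write_networks_tsv(networks: PredictiveNetworks, n_rois: int, path,
                       roi_names: tuple[str, ...] | None = None) -> None:
    """Consensus networks as a TSV edge list with tail and persistence."""
    pairs = edge_pairs(n_rois)
    names = roi_names or tuple(f"roi_{i:03d}" for i in range(n_rois))
    rows = []
    for tail, edges, pers in (
            ("positive", networks.positive_edges, networks.persistence_positive),
            ("negative", networks.negative_edges, networks.persistence_negative)):
        for e in edges:
            rows.append({"roi_i": names[pairs[e, 0]],
                         "roi_j": names[pairs[e, 1]],
                         "tail": tail,
                         "persistence": float(pers[e]) if pers is not None
                         else float("nan")})
    pd.DataFrame(rows, columns=["roi_i", "roi_j", "tail", "persistence"]) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON


def write_report_json(report: ValidationReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def read_report_json(path) -> ValidationReport:
    return ValidationReport.from_dict(json.loads(Path(path).read_text()))


def write_bundle_json(bundle: CPMModelBundle, path) -> None:
    Path(path).write_text(bundle.to_json())


def read_bundle_json(path) -> CPMModelBundle:
    return CPMModelBundle.from_json(Path(path).read_text())
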