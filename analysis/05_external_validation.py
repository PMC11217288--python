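"""External validation: freeze the internal model, apply it to the
independent cohort.

Refits standardization and the SVR on the full internal cohort using the
90%-persistence consensus networks, serializes the bundle, reloads it,
and evaluates on the 41-subject external cohort (scores max-normalized
within that cohort).

Writes results/external/: model_bundle.json, report_external.json.
"""

import argparse
import json
from pathlib import Path

from eegcpm import cpm, io, synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    ap.add_argument("--out", type=Path, default=Path("results/external"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    beh_int = io.read_behavior_csv(args.cohorts / "behavior_internal.csv")
    y_int = synth.normalize_behavior(beh_int)["c_total"].to_numpy()
    X_int = cpm.features_matrix(
        io.read_connectomes_h5(args.cohorts / "connectomes_internal.h5"))

    cfg = cpm.CVConfig(scheme="loo", seed=args.seed)
    rep = cpm.run_internal_cv(X_int, y_int, cfg,
                              modes=("combined",))["combined"]
    consensus = cpm.consensus_networks(rep.fold_networks, threshold=0.9,
                                       n_edges=X_int.shape[1])
    bundle = cpm.finalize_model(X_int, y_int, consensus,
                                provenance={"seed": args.seed,
                                            "threshold": 0.9})
    io.write_bundle_json(bundle, args.out / "model_bundle.json")
    bundle = io.read_bundle_json(args.out / "model_bundle.json")

    beh_ext = io.read_behavior_csv(args.cohorts / "behavior_external.csv")
    X_ext = cpm.features_matrix(
        io.read_connectomes_h5(args.cohorts / "connectomes_external.h5"))
    ext = cpm.external_validate(bundle, X_ext,
                                beh_ext["c_total"].to_numpy())
    io.write_report_json(ext, args.out / "report_external.json")
    print(f"external cohort (n={len(beh_ext)}): r={ext.r:.3f} "
          f"p={ext.p_param:.2e} MAE={ext.mae:.3f} R2={ext.r2_ss:.3f}")
    print(f"frozen model: {bundle.networks.positive_edges.size} positive / "
          f"{bundle.networks.negative_edges.size} negative consensus edges")


if __name__ == "__main__":
    main()
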