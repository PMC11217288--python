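"""Demonstrate the toy forward/inverse stage on a small synthetic recording.

Projects band-limited regional time series through a random lead field
(2 sources per ROI), inverts with the depth-weighted minimum-norm kernel
at the default SNR-heuristic regularization, and reports how well the
regional series are recovered. Writes results/source_recon.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from eegcpm import connectivity as conn
from eegcpm import source_recon as sr
from eegcpm import synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    band = conn.CANONICAL_BANDS["alpha"]
    planted = synth.PlantedEffect((0,), (), 0.0, 0.02, baseline=0.6)
    rts = synth.generate_timeseries(2, 8, 200.0, 10.0, 2, band, planted,
                                    np.zeros(2), args.seed)
    lead, sensors = synth.generate_toy_forward(rts, n_sensors=32,
                                               sources_per_roi=2,
                                               sensor_noise_sd=0.01,
                                               seed=args.seed + 1)
    op = sr.build_wmne_operator(lead)  # default lambda heuristic, gamma=1
    recovered = sr.apply_inverse_and_aggregate(op, sensors,
                                               lead.source_to_roi,
                                               roi_names=rts.roi_names)
    corr = [float(np.corrcoef(rts.data[s, e, r], recovered.data[s, e, r])[0, 1])
            for s in range(2) for e in range(2) for r in range(8)]
    summary = {"lambda": op.lam, "depth_exponent": op.depth_exponent,
               "n_sensors": lead.n_sensors, "n_sources": lead.n_sources,
               "roi_recovery_corr_mean": float(np.mean(corr)),
               "roi_recovery_corr_min": float(np.min(corr))}
    (args.out / "source_recon.json").write_text(json.dumps(summary, indent=1))
    print(f"wMNE roundtrip: mean ROI correlation {np.mean(corr):.4f} "
          f"(min {np.min(corr):.4f}) at lambda={op.lam:.3g}")


if __name__ == "__main__":
    main()
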