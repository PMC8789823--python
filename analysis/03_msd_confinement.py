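"""State-wise MSD curves and confinement lengths.

Builds MSD-lag curves from maximal constant-state segments of the
channel-1 trajectories and fits the square-domain confined model
msd(t) = (L^2/3)(1 - exp(-12 D t / L^2)) + c. The immobile and slow
states should show confinement lengths in the sub-250-nm membrane-domain
range; the medium/fast states fit as effectively unconfined (large L,
flagged). Writes results/msd/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from smtrack import default_config, fit_msd, read_tracks
from smtrack.msd import state_msd
from smtrack.vbhmm import StateAssignment

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = default_config()
    ts = read_tracks(ROOT / "sim" / "tracks.csv", {"dt": cfg.dt}).channel(1)
    labels = pd.read_csv(ROOT / "segment" / "labels_ch1.csv")
    K = int(labels["state"].max())
    assign = StateAssignment(labels=labels, K=K)
    out = ROOT / "msd"
    out.mkdir(parents=True, exist_ok=True)
    curves, fits = [], {}
    for k in range(1, K + 1):
        try:
            curve = state_msd(ts, assign, k, max_lag=10)
        except ValueError:
            continue
        curves.append(curve.to_frame())
        fit = fit_msd(curve, model="confined")
        fits[str(k)] = vars(fit)
        tag = " [unconfined]" if fit.unconfined_flag else ""
        print(f"state {k}: D={fit.D:.4g} um^2/s, L={fit.L * 1000:.0f} nm{tag}")
    pd.concat(curves, ignore_index=True).to_csv(out / "msd.csv", index=False)
    (out / "msd_fits.json").write_text(json.dumps(fits, indent=2))


if __name__ == "__main__":
    main()
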