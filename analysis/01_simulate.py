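"""Generate the synthetic two-channel acquisition used by all later stages.

Simulates one cell of the default acquisition-mimicking configuration
(four switching diffusion states at 30.5 ms/frame, 300 frames, ~0.45
particles/um^2 initially, immobile/slow states confined to 120/220 nm
domains, scripted receptor-kinase binding) and writes the track CSV,
ground-truth sidecar and run manifest under results/sim/.
"""

import sys
from pathlib import Path

from smtrack import default_config, simulate_tracks, write_tracks
from smtrack.io import write_ground_truth
from smtrack.report import write_manifest

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    ts, gt = simulate_tracks(cfg, n_cells=1, seed=SEED)
    write_tracks(ts, OUT / "tracks.csv")
    write_ground_truth(gt, OUT / "ground_truth.ndjson")
    write_manifest(OUT / "manifest.json", cfg.model_dump(), SEED)
    n1 = len(ts.df[ts.df.channel == 1])
    print(f"wrote {len(ts.df)} localizations ({n1} in channel 1), "
          f"{len(gt['binding_events'])} scripted binding events -> {OUT}")


if __name__ == "__main__":
    main()
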