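"""Spatial-versus-functional connectivity: curves, regressions, corr2.

Pools node pairs per condition and connection class (neuron-neuron,
astrocyte-astrocyte, interlayer), bins functional edge existence by spatial
weight (30 bins) with a slope CI, regresses functional on spatial edge
weight, and reports the random-matrix-corrected 2-D correlation per dish.
"""

import argparse
import importlib
from pathlib import Path

from nanet.pipeline import (
    connectivity_stage,
    events_stage,
    simulate_stage,
    spatial_stage,
)
from nanet.types import as_seedseq

load_run = importlib.import_module("02_detect_events").load_run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg, seed = load_run(args.run)
    study = simulate_stage(cfg, seed)
    pruned_ts, *_ = events_stage(study, cfg)
    _, s_conn, _, s_spatial, _ = as_seedseq(seed).spawn(5)
    nets = connectivity_stage(pruned_ts, cfg, s_conn)
    out = spatial_stage(nets, study, cfg, s_spatial)

    for key, df in out.items():
        df.to_csv(args.run / f"spatial_{key}.csv", index=False)

    curves = out["curves"]
    print("connection-probability slope by group and class:")
    print(
        curves.set_index(["group", "pair_class"])[["slope", "ci_low", "ci_high", "p"]]
        .round(4)
        .to_string()
    )
    cc = out["corrected_corr2"]
    if len(cc):
        print("\nmean corrected 2-D correlation by group and class:")
        print(cc.groupby(["group", "pair_class"])["corrected_corr2"].mean()
              .round(4).to_string())


if __name__ == "__main__":
    main()
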