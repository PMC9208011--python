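"""Community structure of functional and spatial networks.

Runs 50-replicate Louvain consensus at gamma = 1 on each dish's functional
multilayer network, tunes the spatial network's resolution to match the
functional community count, and compares partitions by adjusted Rand index
(including the morphological astrocyte partition where the dish retains
>= 2 active segments). Also reports module participation per cell type.
"""

import argparse
import importlib
from pathlib import Path

from nanet import io as nio
from nanet.pipeline import (
    community_stage,
    connectivity_stage,
    events_stage,
    simulate_stage,
)
from nanet.types import as_seedseq

load_run = importlib.import_module("02_detect_events").load_run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg, seed = load_run(args.run)
    study = simulate_stage(cfg, seed)
    pruned_ts, trains, report, _ = events_stage(study, cfg)
    _, s_conn, _, _, s_comm = as_seedseq(seed).spawn(5)
    nets = connectivity_stage(pruned_ts, cfg, s_conn)
    comm_df, partitions = community_stage(nets, study, cfg, report, s_comm)

    comm_df.to_csv(args.run / "communities.csv", index=False)
    part_dir = args.run / "partitions"
    part_dir.mkdir(parents=True, exist_ok=True)
    for dish_id, parts in partitions.items():
        func, _ = nets[dish_id]
        for kind, res in parts.items():
            nio.write_partition_csv(
                func.roi_ids, res.partition, part_dir / f"{dish_id}_{kind}.csv"
            )

    print(
        "mean ARI(functional, spatial) = "
        f"{comm_df['ari_functional_spatial'].mean():.4f} over {len(comm_df)} dishes"
    )
    for col in ("participation_functional_neuron", "participation_functional_astro"):
        print(f"{col}: {comm_df[col].mean():.3f}")
    if "ari_morph_functional_astro" in comm_df:
        sub = comm_df.dropna(subset=["ari_morph_functional_astro"])
        print(
            f"astrocyte layer (n={len(sub)} dishes): "
            f"ARI(cell, functional) = {sub['ari_morph_functional_astro'].mean():.3f}, "
            f"ARI(cell, spatial) = {sub['ari_morph_spatial_astro'].mean():.3f}"
        )


if __name__ == "__main__":
    main()
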