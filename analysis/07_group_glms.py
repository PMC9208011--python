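"""Treatment-group GLMs and event-rate comparisons for one study run.

Fits identity-link normal GLMs of C, B, and E (mean nodal strength as
covariate) and of S (event rate as covariate) against MPEP, Sham, and their
interaction, per network scope, and runs the one-way ANOVA + Tukey
comparisons of final-timepoint event rates between arms.
"""

import argparse
import importlib
from pathlib import Path

from nanet import io as nio
from nanet.pipeline import (
    connectivity_stage,
    events_stage,
    metrics_stage,
    simulate_stage,
    stats_stage,
)
from nanet.types import as_seedseq

load_run = importlib.import_module("02_detect_events").load_run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg, seed = load_run(args.run)
    study = simulate_stage(cfg, seed)
    pruned_ts, trains, report, rates = events_stage(study, cfg)
    _, s_conn, s_metrics, *_ = as_seedseq(seed).spawn(5)
    nets = connectivity_stage(pruned_ts, cfg, s_conn)
    metrics = metrics_stage(nets, study, cfg, report, s_metrics)
    stats = stats_stage(metrics, rates, cfg)

    stats["glm"].to_csv(args.run / "glm.csv", index=False)
    stats["injury_contrasts"].to_csv(args.run / "injury_contrasts.csv",
                                     index=False)
    nio.write_json({"anova": stats["anova"], "tukey": stats["tukey"]},
                   args.run / "group_tests.json")

    ic = stats["injury_contrasts"]
    if len(ic):
        print("injury contrasts (positive effect = injury increases the metric):")
        print(ic.round(4).to_string(index=False))
    glm = stats["glm"]
    if len(glm):
        sham = glm.query("term == 'Sham'")
        print("\nGLM Sham coefficients (negative = injury raises the outcome):")
        print(sham[["scope", "outcome", "coef", "z", "p"]].round(4)
              .to_string(index=False))


if __name__ == "__main__":
    main()
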