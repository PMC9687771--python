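#!/usr/bin/env python
"""Parameter-recovery study across the scenario library.

For each scenario, repeats generate-noise-and-fit cycles (3 replicates per
experiment, replicate-mean reporting) and summarizes the median relative
bias, relative RMSE and 2-SD coverage of every fitted parameter.  The number
of seeds is configurable (default 10 here; the acceptance suite runs 50).

This study is what exposes the identifiability limit of the two-site
fluorescence design: at 1% amplitude noise the (K1, K2, amp1, amp2) model
has near-degenerate ridges (K1 -> inf with a step amplitude; K2 -> 0
one-site collapse) whose residual cost is comparable to the noise, so K1
escapes in roughly half the replicates and its median bias is far above the
few-percent level, while the one-site fluorescence and both ITC fits
recover their parameters to a few percent.

Writes results/recovery_summary.json.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from coopbind import io as cio, synthetic as syn  # noqa: E402
from coopbind.config import default_chelator  # noqa: E402
from coopbind.synthetic import NoiseModel  # noqa: E402

HERE = Path(__file__).resolve().parents[1]


def scenario_noise(sc):
    if isinstance(sc, syn.FluorScenario):
        return NoiseModel("relative", 0.01)
    if sc.kind == "one-site":
        return NoiseModel("absolute", 0.5)
    return NoiseModel("relative", 0.015)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seeds", type=int, default=10)
    parser.add_argument("--base-seed", type=int, default=20260101)
    args = parser.parse_args()

    ida = default_chelator()
    summaries = {}
    for key, sc in syn.scenario_library().items():
        s = syn.recovery_experiment(sc, n_seeds=args.seeds, noise=scenario_noise(sc),
                                    n_replicates=3, chelator=ida, base_seed=args.base_seed)
        summaries[key] = s
        line = ", ".join(
            f"{nm}: bias {e['median_rel_bias']:+.1%} cov {e['coverage_2sd']:.0%}"
            for nm, e in s["parameters"].items()
        )
        print(f"{key:30s} {line}")
    out = HERE / "results" / "recovery_summary.json"
    out.parent.mkdir(exist_ok=True)
    cio.write_results_json(summaries, out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
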