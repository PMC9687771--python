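#!/usr/bin/env python
"""Generate the synthetic titration datasets used by the downstream fits.

Simulates triplicate fluorescence titrations (peptide + IDA competitor,
stepwise uranyl additions) and triplicate reverse ITC titrations (peptide
injected into uranyl + IDA) for one representative one-site and one two-site
peptide each, at the study concentrations, with the default noise model.

Writes CSV files under results/simulated/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from coopbind import io as cio, synthetic as syn  # noqa: E402

HERE = Path(__file__).resolve().parents[1]
OUT = HERE / "results" / "simulated"

SCENARIOS = ["fluor/CaM Y II", "fluor/CaM Y I-II", "itc/CaM Y II", "itc/CaM Y I-II"]
SEED = 20260926


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    lib = syn.scenario_library()
    for key in SCENARIOS:
        sc = lib[key]
        stem = key.replace("/", "_").replace(" ", "_")
        if isinstance(sc, syn.FluorScenario):
            reps = syn.gen_fluor(sc, syn.NoiseModel("relative", 0.01, SEED), 3)
            for i, s in enumerate(reps, 1):
                cio.write_fluor_series(s, OUT / f"{stem}.rep{i}.csv")
        else:
            reps = syn.gen_itc(sc, syn.NoiseModel("absolute", 0.5, SEED), n_replicates=3)
            for i, s in enumerate(reps, 1):
                cio.write_itc_series(s, sc.design, OUT / f"{stem}.rep{i}.csv",
                                     OUT / f"{stem}.rep{i}.blank.csv")
        print(f"{key}: 3 replicates written")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
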