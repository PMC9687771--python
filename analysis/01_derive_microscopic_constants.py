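#!/usr/bin/env python
"""Derive microscopic constants, cooperativity and entropy terms.

Takes the assay's primary estimates — the macroscopic constants (K1, K2) of
each two-site peptide together with the site-II constant KII measured on the
matching one-site peptide — and derives the full microscopic picture:
KI = K1 - KII, the occupied-site constants KI_II and KII_I, the
cooperativity constant Kc and free energy ddG = -RT ln Kc, dissociation
constants, and (where enthalpies are available) the TdS terms.

Writes results/microscopic_constants.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from coopbind import workflow  # noqa: E402

HERE = Path(__file__).resolve().parents[1]

# primary constants: fluorescence-derived macroscopic constants with the
# matching one-site site-II constants; enthalpies from the calorimetric fits
ROWS = [
    dict(peptide="CaM Y I-II", pH=6, K1=3.5e7, K2=7.4e6, KII=3.7e6,
         dH_I=-40.2, dH_II=-2.0, dH_c=25.0),
    dict(peptide="CaM1 Y I-II", pH=6, K1=3.0e7, K2=7.0e6, KII=3.5e6,
         dH_I=-26.1, dH_II=-3.5, dH_c=22.0),
    dict(peptide="CaM YW I-II", pH=6, K1=7.4e7, K2=9.7e6, KII=5.1e6,
         dH_I=-34.8, dH_II=-8.9, dH_c=3.8),
    dict(peptide="CaM1 YW I-II", pH=6, K1=7.8e7, K2=9.4e6, KII=5.9e6,
         dH_I=-26.1, dH_II=-15.0, dH_c=8.9),
    dict(peptide="CaM1 Y I-II P", pH=6, K1=3.6e8, K2=7.8e7, KII=2.1e7),
    dict(peptide="CaM1 Y I-II P", pH=7, K1=1.0e11, K2=7.1e8, KII=1.8e8),
    dict(peptide="CaM1 YW I-II P", pH=6, K1=3.8e8, K2=1.3e8, KII=2.1e7),
    dict(peptide="CaM1 YW I-II P", pH=7, K1=6.0e11, K2=5.1e9, KII=1.8e8),
]


def main():
    table = workflow.derive_table(pd.DataFrame(ROWS))
    out = HERE / "results" / "microscopic_constants.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False, float_format="%.6g")
    cols = ["peptide", "pH", "KI", "KII", "KI_II", "KII_I", "Kc", "ddG_kJ_mol"]
    print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(f"\nAll two-site peptides show positive cooperativity (ddG < 0), "
          f"from {table.ddG_kJ_mol.max():.1f} to {table.ddG_kJ_mol.min():.1f} kJ/mol; "
          f"phosphorylation of the site-I loop roughly doubles |ddG|.")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
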