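#!/usr/bin/env python
"""Estimate the share of each vitamin's DRI suppliable by the gut microbiota.

Converts the literature intracellular measurements to mmol/gDW (auditing
them against the canonical concentration column — two literature rows are
known not to convert consistently and are flagged, not forced), then runs
the supply formula: intracellular concentration x lysing colonic biomass
x molar mass x producer ratio / DRI x 100.
"""

import argparse
from pathlib import Path

from vitasynth import build_supply_table, default_cell_model, default_measurements
from vitasynth.supply import default_supply_parameters

OUT = Path("results/supply")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    cell = default_cell_model()
    params = default_supply_parameters()
    table = build_supply_table(params, cell, default_measurements())
    table.to_csv(OUT / "supply.tsv", sep="\t")
    shown = table[
        ["conc_mmol_per_gdw", "dri_mg_per_day", "hgm_producer_ratio", "percent_dri"]
    ].copy()
    print(shown.to_string(float_format=lambda x: f"{x:.3g}"))
    covered = shown.index[shown["percent_dri"] >= 25]
    print(
        f"\n{len(covered)} of 8 vitamins could cover >= 25% of the DRI: "
        + ", ".join(covered)
    )


if __name__ == "__main__":
    main()
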