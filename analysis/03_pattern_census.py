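#!/usr/bin/env python
"""Pathway-pattern census, cohort comparison and inversed pattern pairs.

Censuses the 8-bit producer patterns of each cohort, partitions the 256
possible patterns into cohort-specific / shared / absent groups, and
detects inversed (bitwise-complement) pattern pairs — the signature of
candidate B-vitamin cross-feeding between organisms.
"""

import argparse
from pathlib import Path

from vitasynth import compare_cohorts, inversed_pairs, pattern_census, read_taxonomy
from vitasynth.patterns import heatmap_frame, taxon_pattern_summary
from vitasynth.predict import PredictionTable

IN_PRED = Path("results/predictions")
IN_SYN = Path("results/synthetic")
OUT = Path("results/patterns")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    censuses = {}
    for label in ("hgm", "nonhgm"):
        predictions = PredictionTable.read_tsv(IN_PRED / f"{label}_predictions.tsv")
        taxonomy = read_taxonomy(IN_SYN / f"{label}_taxonomy.tsv")
        census = pattern_census(predictions)
        censuses[label] = census
        census.to_frame().to_csv(OUT / f"{label}_census.tsv", sep="\t", index=False)
        pairs = inversed_pairs(census)
        pairs.to_frame().to_csv(OUT / f"{label}_pairs.tsv", sep="\t", index=False)
        taxon_pattern_summary(predictions, taxonomy, rank="phylum").to_csv(
            OUT / f"{label}_taxon_patterns.tsv", sep="\t", index=False
        )
        heatmap_frame(predictions).to_csv(
            OUT / f"{label}_heatmap.tsv", sep="\t", index_label="genome_id"
        )
        print(
            f"{label}: {census.total} genomes, {census.n_distinct} distinct "
            f"patterns, {pairs.n_pairs} inversed pairs "
            f"({pairs.n_genomes} genomes in pairs)"
        )
    comparison = compare_cohorts(censuses["hgm"], censuses["nonhgm"])
    with open(OUT / "comparison.tsv", "w") as fh:
        fh.write("group\tn_patterns\n")
        for group, n in comparison.sizes().items():
            fh.write(f"{group}\t{n}\n")
    print("pattern-space partition:", comparison.sizes())


if __name__ == "__main__":
    main()
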