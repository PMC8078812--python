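#!/usr/bin/env python
"""QC and filter the cohort OTU table.

Drops samples under 5 000 reads, keeps OTUs of known phylum present in at
least 5 samples with > 0.01% of total reads, and writes both the filtered
(unrarefied) table used for relative abundances and a table rarefied to
4 831 reads/sample used for diversity.
"""

import argparse
from pathlib import Path

from weanotype import abundance
from weanotype.tables import read_count_table, read_taxonomy

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--out", type=Path, default=Path("results/derived"))
args = ap.parse_args()

counts = read_count_table(args.cohort / "counts.tsv")
taxonomy = read_taxonomy(args.cohort / "taxonomy.tsv")

qc = abundance.qc_filter_samples(counts, abundance.DEFAULT_MIN_READS)
filtered = abundance.filter_otus(qc, taxonomy)
rarefied = abundance.rarefy(filtered, abundance.DEFAULT_RAREFACTION_DEPTH,
                            seed=args.seed)

args.out.mkdir(parents=True, exist_ok=True)
filtered.to_tsv(args.out / "filtered_counts.tsv")
rarefied.to_tsv(args.out / "rarefied_counts.tsv")

print(f"samples: {len(counts.sample_ids)} -> {len(qc.sample_ids)} after the "
      f"{abundance.DEFAULT_MIN_READS}-read QC cut")
print(f"OTUs:    {len(counts.otu_ids)} -> {len(filtered.otu_ids)} after the "
      "known-phylum / prevalence / abundance filters")
print(f"rarefied to {abundance.DEFAULT_RAREFACTION_DEPTH} reads per sample "
      f"-> {args.out}")
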