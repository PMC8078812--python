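#!/usr/bin/env python
"""Growth classes, farm effects, weaning fold changes, and the two-step
growth-association procedure.

Computes rADG and the within-farm 40/40/20 classes, summarizes the pooled
d26 -> d35 family percent changes, tests farm effects per age
(Kruskal-Wallis + Dunn), and runs the two-step rADG procedure (rank-sum + BH
prescreen, then within-farm permutation tests of class, age, and their
interaction on genus abundances).
"""

import argparse
from pathlib import Path

from weanotype import abundance, association, growth
from weanotype.tables import RelAbundanceTable, read_count_table, read_metadata, read_taxonomy

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--derived", type=Path, default=Path("results/derived"))
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--n-perm", type=int, default=5000)
args = ap.parse_args()

filtered = read_count_table(args.derived / "filtered_counts.tsv")
taxonomy = read_taxonomy(args.cohort / "taxonomy.tsv")
meta = read_metadata(args.cohort / "metadata.tsv")
meta_f = meta.data.loc[filtered.data.index]

records = growth.classify_within_farm(growth.compute_radg(meta))
print("growth classes:")
print(growth.class_summary(records).table.round(2).to_string())
records.to_csv(args.derived / "growth.tsv", sep="\t")

rel_family = abundance.to_relative(abundance.aggregate(filtered, taxonomy, "family"))
pc = association.percent_change(rel_family, meta)
headline = ["Prevotellaceae", "Lachnospiraceae", "Clostridiaceae",
            "Christensenellaceae", "Enterobacteriaceae", "Bacteroidaceae"]
print("\npooled d26->d35 family changes (%):")
print(pc.loc[headline, ["percent_change", "p_adj"]].round(2).to_string())
pc.to_csv(args.derived / "family_percent_change.tsv", sep="\t")

for age in ("d26", "d35"):
    sub = RelAbundanceTable(rel_family.data[meta_f["age_point"] == age])
    kw = association.kruskal_dunn(sub, meta_f["farm_id"])
    n_sig = int((kw.table["p"] < 0.05).sum())
    print(f"\nfarm effect at {age}: {n_sig} of {len(kw.table)} families at p<0.05")

rel_genus = abundance.to_relative(abundance.aggregate(filtered, taxonomy, "genus"))
ts = association.two_step_radg(rel_genus, records, meta,
                               n_perm=args.n_perm, seed=args.seed)
sig = ts.step2[ts.step2["p_interaction"] < 0.05]
print(f"\ntwo-step rADG procedure: {int(ts.step1['retained'].sum())} genera "
      f"retained; class x age interaction significant for: {list(sig.index)}")
ts.step1.to_csv(args.derived / "two_step_step1.tsv", sep="\t")
ts.step2.to_csv(args.derived / "two_step_step2.tsv", sep="\t")
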