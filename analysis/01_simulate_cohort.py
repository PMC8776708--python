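#!/usr/bin/env python
"""Simulate the study-like aging skin cohort and write it to results/cohort.

Three young and four old donors; five fibroblast populations whose
young/old membership probabilities encode the published composition odds
ratios; a 10-gene marker program per population with the dermal-sheath
program on the DS signature symbols; and an emulated stem-vs-fibroblast
DE reference over the same gene namespace."""

import os

import dermalscore as ds
from dermalscore.synthetic import write_cohort_bundle

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")
SEED = 0

spec = ds.default_cohort_spec(cells_per_donor=500, n_genes=2000, seed=SEED)
write_cohort_bundle(spec, OUT)

ref = ds.generate_reference_de(
    spec.n_genes, n_up=250, n_down=250, seed=SEED + 1,
    gene_symbols=ds.generate_cohort(spec)[0].gene_symbols,
)
ref.to_csv(os.path.join(OUT, "reference_de.tsv"), sep="\t", index=False)

print(f"wrote cohort bundle ({spec.n_young_donors} young + {spec.n_old_donors} old "
      f"donors x {spec.cells_per_donor} cells, {spec.n_genes} genes) to {OUT}")
print("membership probabilities encode ORs 1.685 (F1, old-enriched), "
      "1.666 (F3), 7.097 (F4a) and 2.258 (F4b) (young-enriched)")
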