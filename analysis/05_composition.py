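#!/usr/bin/env python
"""Young-vs-old composition analysis of the simulated cohort.

Per-population one-vs-rest Fisher's exact odds ratios with Woolf 95% CIs,
the per-donor DS fraction t-test, and a parameter-recovery check of the
published odds ratios at the published cohort sizes."""

import os

import numpy as np

import dermalscore as ds
from dermalscore.synthetic import simulate_membership_counts

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
meta = ds.io_qc.read_cell_meta(os.path.join(BASE, "cohort", "meta.tsv"))

orientations = {"F1": "old-enriched", "F2": "young-enriched",
                "F3": "young-enriched", "F4a": "young-enriched",
                "F4b": "young-enriched"}
comp = ds.composition_analysis(meta, orientations=orientations)
comp.to_csv(os.path.join(BASE, "composition.tsv"), sep="\t", index=False)
print("per-population composition (odds ratio, 95% CI, Fisher p):")
print(comp.to_string(index=False, float_format="%.4g"))

fr = ds.donor_fractions(meta, "F4a")
ft = ds.fraction_test(fr.fraction, fr.age_group)
print(f"\nper-donor F4a fraction, young vs old: t = {ft['t']:.2f}, p = {ft['p']:.3g} "
      f"(young {ft['mean_a']:.4f} +/- {ft['sem_a']:.4f}, "
      f"old {ft['mean_b']:.4f} +/- {ft['sem_b']:.4f})")

print("\nOR recovery at published cohort sizes (mean over 200 cohorts):")
designs = {"F1": (0.3000, 0.419328, "old-enriched", 1.685),
           "F4a": (0.034, 0.004935, "young-enriched", 7.097),
           "F4b": (0.030, 0.013512, "young-enriched", 2.258)}
rng = np.random.default_rng(0)
for name, (py, po, ori, published) in designs.items():
    ors = []
    for _ in range(200):
        y_in, y_out, o_in, o_out = simulate_membership_counts(19139, 31010, py, po, rng)
        ors.append(ds.fisher_or(ds.ContingencyTable(o_in, o_out, y_in, y_out), ori)["OR"])
    print(f"  {name}: recovered {np.mean(ors):.3f} (generating value {published})")
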