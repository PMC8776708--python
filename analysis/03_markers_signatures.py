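#!/usr/bin/env python
"""Dermal-sheath marker detection and signature summaries.

One-vs-rest Wilcoxon marker table for population F4a, the DS-signature
per-cell score, and the dot-plot summary (percent expressed / average
expression) of the signature across populations."""

import os

import pandas as pd

import dermalscore as ds
from dermalscore.synthetic import DS_SIGNATURE

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
cm = ds.read_10x(os.path.join(BASE, "cohort"))
meta = ds.io_qc.read_cell_meta(os.path.join(BASE, "cohort", "meta.tsv"))
kept, _ = ds.qc_filter(cm)
meta = meta.set_index("cell_id").loc[kept.cell_ids].reset_index()
norm = ds.normalize(kept)

markers = ds.find_markers(norm, meta.cluster.to_numpy(), "F4a")
markers.to_csv(os.path.join(BASE, "markers_F4a.tsv"), sep="\t", index=False)
top = markers.head(10)
n_sig = (top.gene.isin(DS_SIGNATURE)).sum()
print(f"top-10 F4a markers contain {n_sig}/10 DS signature genes; "
      f"best: {top.gene.iloc[0]} (log_fc {top.log_fc.iloc[0]:.2f}, "
      f"p_adj {top.p_adj.iloc[0]:.2e})")

sig = ds.GeneSignature("DS", list(DS_SIGNATURE))
scores, missing = ds.signature_score(norm, sig)
means = pd.Series(scores).groupby(meta.cluster.to_numpy()).mean().sort_values()
print("mean DS signature score by population:")
print(means.to_string(float_format="%.3f"))

dp = ds.dotplot_summary(norm, meta.cluster.to_numpy(),
                        genes=list(DS_SIGNATURE), signatures=[sig])
dp.to_csv(os.path.join(BASE, "dotplot_DS.tsv"), sep="\t", index=False)
print(f"wrote marker table and dot-plot summary to {BASE}")
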