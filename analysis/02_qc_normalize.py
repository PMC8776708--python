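#!/usr/bin/env python
"""QC-filter the simulated cohort and report what the filters removed.

Applies the droplet-QC rule (expressed genes in [200, 7500], mitochondrial
UMI fraction <= 5%, strict boundaries) and writes the QC report."""

import os

import dermalscore as ds

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
cm = ds.read_10x(os.path.join(BASE, "cohort"))
meta = ds.io_qc.read_cell_meta(os.path.join(BASE, "cohort", "meta.tsv"))

kept, report = ds.qc_filter(cm, ds.QCConfig(), meta=meta)
report.to_json(os.path.join(BASE, "qc_report.json"))

print(f"kept {report.n_kept}/{report.n_input} cells "
      f"(low-genes {report.n_low_genes}, high-genes {report.n_high_genes}, "
      f"high-mito {report.n_high_mito}); per-donor removals {report.removed_per_donor}")
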