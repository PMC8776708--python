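"""End-to-end orchestration: simulate/load -> QC -> normalize -> markers &
signatures -> stemness -> composition, from a single YAML-able config.

All result tables are written atomically (temp file then rename) so a
failed run never leaves partial outputs, and identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import tempfile
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .composition import composition_analysis, donor_fractions, fraction_test
from .io_qc import QCConfig, normalize, qc_filter, read_10x, read_cell_meta
from .markers import GeneSignature, dotplot_summary, find_markers, signature_score
from .stemness import select_signature_genes, stemness_score
from .synthetic import (
    SyntheticSpec,
    default_cohort_spec,
    generate_cohort,
    generate_reference_de,
)

log = logging.getLogger("dermalscore")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]

STAGES = ["input", "qc", "normalize", "markers", "stemness", "composition"]


@dataclass
class PipelineConfig:
    """Exactly one of ``input_dir`` (a 10x bundle + meta.tsv) or
    ``synthetic`` must be set."""

    out_dir: str
    input_dir: str | None = None
    meta_path: str | None = None
    synthetic: SyntheticSpec | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    signature_path: str | None = None
    reference_de_path: str | None = None
    k: int = 250
    marker_cluster: str = "F4a"
    cluster_col: str = "cluster"
    group_col: str = "age_group"
    scale: float = 1e6
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError(
                "config must set exactly one of input_dir or synthetic"
            )
        if self.input_dir is not None and self.meta_path is None:
            raise ValueError("input_dir requires meta_path")


@dataclass
class RunReport:
    version: str
    config: dict
    stages: list[dict]
    outputs: dict
    warnings: list[str]

    def to_json(self, path: str | os.PathLike) -> None:
        _atomic_write_text(path, json.dumps(dataclasses.asdict(self), indent=2))


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    path = os.fspath(path)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_tsv(df: pd.DataFrame, path: str, **kwargs) -> None:
    _atomic_write_text(path, df.to_csv(sep="\t", index=False, **kwargs))


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load a pipeline config from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    syn = raw.pop("synthetic", None)
    if syn is not None:
        from .synthetic import PopulationSpec

        pops = [PopulationSpec(**p) for p in syn.pop("populations", [])]
        for p in pops:
            p.program_genes = [tuple(g) for g in p.program_genes]
        syn = SyntheticSpec(populations=pops, **syn)
    qc = QCConfig(**raw.pop("qc", {}))
    return PipelineConfig(synthetic=syn, qc=qc, **raw)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in fixed order; any stage error aborts with the
    stage name attached."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    stages: list[dict] = []
    outputs: dict = {}
    warnings_log: list[str] = []

    def stage(name: str):
        t0 = time.time()
        log.info("stage %s ...", name)

        def done(**info):
            stages.append({"stage": name, "seconds": round(time.time() - t0, 3), **info})

        return done

    try:
        done = stage("input")
        if cfg.synthetic is not None:
            spec = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            cm, meta, gt = generate_cohort(spec)
            outputs["ground_truth"] = os.path.join(cfg.out_dir, "ground_truth.tsv")
            _atomic_write_text(
                outputs["ground_truth"],
                gt.cell_population.rename("population")
                .rename_axis("cell_id")
                .to_frame()
                .to_csv(sep="\t"),
            )
        else:
            cm = read_10x(cfg.input_dir)
            meta = read_cell_meta(cfg.meta_path)
        done(n_cells=cm.n_cells, n_genes=cm.n_genes)

        done = stage("qc")
        cm_f, qr = qc_filter(cm, cfg.qc, meta=meta)
        meta = meta.set_index("cell_id").loc[cm_f.cell_ids].reset_index()
        outputs["qc_report"] = os.path.join(cfg.out_dir, "qc_report.json")
        _atomic_write_text(
            outputs["qc_report"], json.dumps(dataclasses.asdict(qr), indent=2)
        )
        done(n_cells=cm_f.n_cells, removed=qr.n_input - qr.n_kept)

        done = stage("normalize")
        norm = normalize(cm_f, scale=cfg.scale)
        done(scale=cfg.scale)

        done = stage("markers")
        labels = meta[cfg.cluster_col].to_numpy()
        mk = find_markers(norm, labels, cfg.marker_cluster)
        outputs["markers"] = os.path.join(
            cfg.out_dir, f"markers_{cfg.marker_cluster}.tsv"
        )
        _atomic_write_tsv(mk, outputs["markers"])
        if cfg.signature_path:
            sigs = GeneSignature.read_tsv(cfg.signature_path)
            for sig in sigs:
                _, missing = signature_score(norm, sig)
                if missing:
                    warnings_log.append(
                        f"signature {sig.name}: {len(missing)} genes absent"
                    )
            dp = dotplot_summary(norm, labels, signatures=sigs)
            outputs["dotplot"] = os.path.join(cfg.out_dir, "dotplot_signatures.tsv")
            _atomic_write_tsv(dp, outputs["dotplot"])
        done(n_marker_rows=len(mk))

        done = stage("stemness")
        if cfg.reference_de_path:
            ref = pd.read_csv(cfg.reference_de_path, sep="\t")
        else:
            ref = generate_reference_de(
                n_genes=cm.n_genes,
                n_up=min(cfg.k, cm.n_genes // 4),
                n_down=min(cfg.k, cm.n_genes // 4),
                seed=cfg.seed + 1,
                gene_symbols=cm.gene_symbols,
            )
        up, down = select_signature_genes(ref, k=cfg.k)
        res = stemness_score(norm, cm_f, up, down)
        sc = res.table.merge(meta, on="cell_id")
        outputs["stemness"] = os.path.join(cfg.out_dir, "stemness_scores.tsv")
        _atomic_write_tsv(sc, outputs["stemness"])
        if res.up_missing or res.down_missing:
            warnings_log.append(
                f"stemness: {len(res.up_missing)} up / {len(res.down_missing)} down "
                "reference genes absent from the matrix"
            )
        done(n_cells=len(sc), n_up=len(res.up_used), n_down=len(res.down_used))

        done = stage("composition")
        comp = composition_analysis(
            meta, cluster_col=cfg.cluster_col, group_col=cfg.group_col
        )
        outputs["composition"] = os.path.join(cfg.out_dir, "composition.tsv")
        _atomic_write_tsv(comp, outputs["composition"])
        if "donor" in meta.columns:
            fr = donor_fractions(meta, cfg.marker_cluster, cluster_col=cfg.cluster_col)
            try:
                ft = fraction_test(fr["fraction"], fr["age_group"])
                outputs["fraction_test"] = os.path.join(
                    cfg.out_dir, "fraction_test.json"
                )
                _atomic_write_text(
                    outputs["fraction_test"], json.dumps(ft, indent=2)
                )
            except ValueError as e:
                warnings_log.append(f"fraction test skipped: {e}")
        done(n_clusters=len(comp))
    except Exception as e:
        failed = STAGES[len(stages)] if len(stages) < len(STAGES) else "output"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {e}") from e

    cfg_echo = dataclasses.asdict(cfg)
    report = RunReport(
        version=__version__,
        config=cfg_echo,
        stages=stages,
        outputs=outputs,
        warnings=warnings_log,
    )
    report.to_json(os.path.join(cfg.out_dir, "run_report.json"))
    return report


def demo_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """Small synthetic end-to-end demo configuration."""
    return PipelineConfig(
        out_dir=out_dir,
        synthetic=default_cohort_spec(cells_per_donor=300, n_genes=1200),
        k=100,
        seed=seed,
    )
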