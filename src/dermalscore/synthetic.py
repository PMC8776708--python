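"""Synthetic aging skin scRNA-seq cohorts with known ground truth.

The generator emulates the structure of a droplet scRNA-seq study of human
dermal fibroblasts from young and old donors: two age groups of donors, a
fixed set of fibroblast populations (by convention F1 reticular, F2
papillary, F3 pro-inflammatory, and the mesenchymal subpopulations F4a —
the dermal sheath — and F4b), per-population marker programs expressed as
fold-changes on gene-level baseline means, age-dependent shifts in
population membership probabilities of chosen odds-ratio magnitude, and a
negative-binomial UMI count model with a cohort-wide dispersion.

A paired generator emits an emulated stem-vs-fibroblast differential
expression reference table (the kind derived from comparing dermal
fibroblasts with fibroblast-derived iPS cells) over the same gene
namespace, with planted up-/down-regulated sets, so reference-based
stemness scoring can be tested end to end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import CountMatrix, write_10x

__all__ = [
    "PopulationSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_reference_de",
    "simulate_membership_counts",
    "default_cohort_spec",
    "stemness_demo_spec",
    "DS_SIGNATURE",
]

# Top-10 dermal-sheath signature symbols used by the default cohort so that
# signature-scoring workflows run on realistic gene names.
DS_SIGNATURE = [
    "CCDC80", "COL11A1", "TNMD", "LRRC15", "COL12A1",
    "FGL2", "CD200", "FAM101B", "SPARC", "IGFBP7",
]


@dataclass
class PopulationSpec:
    """One cell population: membership probabilities per age group and its
    marker program as (gene index, fold-change > 0) pairs."""

    name: str
    prob_young: float
    prob_old: float
    program_genes: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.prob_young <= 1 and 0 <= self.prob_old <= 1):
            raise ValueError(f"{self.name}: membership probabilities must be in [0,1]")
        idx = [g for g, _ in self.program_genes]
        if len(set(idx)) != len(idx):
            raise ValueError(f"{self.name}: duplicate program gene indices")
        if any(fc <= 0 for _, fc in self.program_genes):
            raise ValueError(f"{self.name}: fold-changes must be strictly positive")


@dataclass
class SyntheticSpec:
    """Full cohort description.

    ``aging_effects`` is a list of (gene index, fold-change) applied
    multiplicatively to every old cell's mean, on top of its population
    program — the mechanism for age-attenuated expression programs.
    """

    n_young_donors: int = 3
    n_old_donors: int = 4
    cells_per_donor: int = 500
    populations: list[PopulationSpec] = field(default_factory=list)
    n_genes: int = 2000
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    mito_fraction_mean: float = 0.02
    n_mito_genes: int = 13
    donor_lognorm_sigma: float = 0.15
    aging_effects: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young_donors < 1 or self.n_old_donors < 1:
            raise ValueError("need at least one donor per age group")
        if self.cells_per_donor < 1:
            raise ValueError("cells_per_donor must be >= 1")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if not 0 <= self.mito_fraction_mean < 1:
            raise ValueError("mito_fraction_mean must be in [0, 1)")
        for attr in ("prob_young", "prob_old"):
            s = sum(getattr(p, attr) for p in self.populations)
            if abs(s - 1.0) > 1e-12:
                raise ValueError(
                    f"population {attr} values sum to {s!r}, expected 1"
                )
        for g, fc in self.aging_effects:
            if fc <= 0:
                raise ValueError("aging_effects fold-changes must be positive")
            if not 0 <= g < self.n_genes:
                raise ValueError("aging_effects gene index out of range")


@dataclass
class GroundTruth:
    """What the generator planted: per-cell population labels, the true
    membership probabilities, and the planted marker/stem gene lists."""

    cell_population: pd.Series  # index = cell_id
    membership_probs: pd.DataFrame  # populations x {young, old}
    marker_genes: dict  # population name -> list of gene symbols
    stem_up_genes: list = field(default_factory=list)
    stem_down_genes: list = field(default_factory=list)
    aging_effect_genes: list = field(default_factory=list)

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.cell_population.rename("population").rename_axis("cell_id")
        df.to_frame().to_csv(path, sep="\t")


def _gene_names(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Gene ids/symbols: MT- genes first, then DS signature symbols, then
    generic symbols."""
    symbols: list[str] = [f"MT-SYN{i + 1}" for i in range(spec.n_mito_genes)]
    for s in DS_SIGNATURE:
        if len(symbols) < spec.n_genes:
            symbols.append(s)
    i = 0
    while len(symbols) < spec.n_genes:
        symbols.append(f"GENE{i:05d}")
        i += 1
    ids = np.array([f"SYNG{j:05d}" for j in range(spec.n_genes)], dtype=object)
    return ids, np.array(symbols[: spec.n_genes], dtype=object)


def _baseline_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Log-normal gene baselines with overall mean ~= baseline_mean, then the
    MT- genes rescaled so the expected mitochondrial fraction is
    mito_fraction_mean."""
    sigma = 1.0
    mu = np.log(spec.baseline_mean) - sigma**2 / 2
    means = rng.lognormal(mean=mu, sigma=sigma, size=spec.n_genes)
    nm = spec.n_mito_genes
    if nm > 0 and spec.mito_fraction_mean > 0:
        other = means[nm:].sum()
        target_mt = spec.mito_fraction_mean / (1 - spec.mito_fraction_mean) * other
        means[:nm] *= target_mt / means[:nm].sum()
    return means


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a full cohort: counts, per-cell metadata, and ground truth.

    Each donor gets a deterministic substream of the master seed, so output
    is bit-identical for identical spec + seed regardless of evaluation
    order. Counts are negative binomial with mean = gene baseline x
    population program fold-change x donor library-size factor (x aging
    effect for old cells) and cohort-wide size parameter ``dispersion``.
    """
    if not spec.populations:
        raise ValueError("spec lists no populations")
    master = np.random.SeedSequence(spec.seed)
    base_rng = np.random.default_rng(master.spawn(1)[0])
    gene_ids, gene_symbols = _gene_names(spec)
    base_means = _baseline_means(spec, base_rng)

    pop_names = [p.name for p in spec.populations]
    # per-population mean multipliers (n_pops x n_genes)
    pop_mult = np.ones((len(pop_names), spec.n_genes))
    for i, p in enumerate(spec.populations):
        for g, fc in p.program_genes:
            if not 0 <= g < spec.n_genes:
                raise ValueError(f"{p.name}: program gene index {g} out of range")
            pop_mult[i, g] = fc
    aging_mult = np.ones(spec.n_genes)
    for g, fc in spec.aging_effects:
        aging_mult[g] = fc

    donors = [(f"Y{i + 1}", "young") for i in range(spec.n_young_donors)] + [
        (f"O{i + 1}", "old") for i in range(spec.n_old_donors)
    ]
    donor_seeds = master.spawn(1 + len(donors))[1:]

    blocks = []
    cell_ids: list[str] = []
    donor_col: list[str] = []
    age_col: list[str] = []
    pop_col: list[str] = []
    p_young = np.array([p.prob_young for p in spec.populations])
    p_old = np.array([p.prob_old for p in spec.populations])

    for (donor, age), dseed in zip(donors, donor_seeds):
        rng = np.random.default_rng(dseed)
        size_factor = rng.lognormal(
            mean=-spec.donor_lognorm_sigma**2 / 2, sigma=spec.donor_lognorm_sigma
        )
        probs = p_young if age == "young" else p_old
        pops = rng.choice(len(pop_names), size=spec.cells_per_donor, p=probs)
        mu = pop_mult[pops] * base_means[None, :] * size_factor
        if age == "old":
            mu = mu * aging_mult[None, :]
        # NB with size r and mean mu: p = r / (r + mu)
        r = spec.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        blocks.append(sp.csr_matrix(counts))
        cell_ids.extend(f"{donor}_C{j + 1:05d}" for j in range(spec.cells_per_donor))
        donor_col.extend([donor] * spec.cells_per_donor)
        age_col.extend([age] * spec.cells_per_donor)
        pop_col.extend(pop_names[k] for k in pops)

    cm = CountMatrix(
        cell_ids=np.array(cell_ids, dtype=object),
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        counts=sp.vstack(blocks).tocsr(),
    )
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor": donor_col,
            "age_group": age_col,
            "cluster": pop_col,
        }
    )
    marker_genes = {
        p.name: [str(gene_symbols[g]) for g, _ in p.program_genes]
        for p in spec.populations
    }
    gt = GroundTruth(
        cell_population=pd.Series(pop_col, index=cell_ids, name="population"),
        membership_probs=pd.DataFrame(
            {"young": p_young, "old": p_old}, index=pop_names
        ),
        marker_genes=marker_genes,
        aging_effect_genes=[str(gene_symbols[g]) for g, _ in spec.aging_effects],
    )
    return cm, meta, gt


def simulate_membership_counts(
    n_young: int,
    n_old: int,
    prob_young: float,
    prob_old: float,
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Draw one cohort's cluster-membership 2x2 table by binomial sampling.

    Returns (young_in, young_out, old_in, old_out): each young cell joins
    the cluster independently with probability ``prob_young``, each old
    cell with ``prob_old``. This is the membership layer of the full
    generator, isolated for composition parameter-recovery studies at
    published cohort sizes.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("need at least one cell per age group")
    y_in = int(rng.binomial(n_young, prob_young))
    o_in = int(rng.binomial(n_old, prob_old))
    return y_in, n_young - y_in, o_in, n_old - o_in


def generate_reference_de(
    n_genes: int,
    n_up: int = 250,
    n_down: int = 250,
    effect_size: float = 2.0,
    seed: int = 0,
    gene_symbols: list[str] | np.ndarray | None = None,
    up_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Emulated stem-vs-fibroblast DE reference table with planted truth.

    Returns a DataFrame (symbol, effect, p_adj) in which exactly ``n_up``
    genes carry large positive effects (up in stem cells) and ``n_down``
    large negative effects, all with p_adj far below 0.05; the remaining
    genes get near-zero effects with non-significant p_adj. When
    ``gene_symbols`` is given the table lives in that namespace (e.g. the
    cohort's genes) so stemness scoring is wired end to end; ``up_genes``
    forces named symbols (e.g. a population's planted stem program) into
    the up set.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("n_up and n_down must be non-negative")
    if n_up + n_down > n_genes:
        raise ValueError(f"n_up + n_down = {n_up + n_down} exceeds n_genes = {n_genes}")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if gene_symbols is None:
        symbols = np.array([f"REFG{i:05d}" for i in range(n_genes)], dtype=object)
    else:
        symbols = np.asarray(gene_symbols, dtype=object)
        if len(symbols) != n_genes:
            raise ValueError("gene_symbols length must equal n_genes")

    order = np.arange(n_genes)
    if up_genes:
        wanted = [np.flatnonzero(symbols == g) for g in up_genes]
        missing = [g for g, w in zip(up_genes, wanted) if len(w) == 0]
        if missing:
            raise ValueError(f"up_genes not in namespace: {missing}")
        forced = np.array([w[0] for w in wanted])
        if len(forced) > n_up:
            raise ValueError("more forced up_genes than n_up slots")
        rest = np.setdiff1d(order, forced)
        order = np.concatenate([forced, rng.permutation(rest)])
    else:
        order = rng.permutation(order)

    effect = np.zeros(n_genes)
    p_adj = np.full(n_genes, np.nan)
    up_idx = order[:n_up]
    down_idx = order[n_up : n_up + n_down]
    null_idx = order[n_up + n_down :]
    # planted effects well-separated from the null band
    effect[up_idx] = effect_size + rng.exponential(effect_size / 4, n_up)
    effect[down_idx] = -(effect_size + rng.exponential(effect_size / 4, n_down))
    effect[null_idx] = rng.normal(0, 0.05, len(null_idx))
    p_adj[up_idx] = 10.0 ** rng.uniform(-30, -5, n_up)
    p_adj[down_idx] = 10.0 ** rng.uniform(-30, -5, n_down)
    p_adj[null_idx] = rng.uniform(0.2, 1.0, len(null_idx))

    return pd.DataFrame({"symbol": symbols, "effect": effect, "p_adj": p_adj})


# ---------------------------------------------------------------------------
# Canned study designs


def default_cohort_spec(
    cells_per_donor: int = 500,
    n_genes: int = 2000,
    seed: int = 0,
    marker_fold_change: float = 8.0,
) -> SyntheticSpec:
    """The study-like design: 3 young / 4 old donors and five fibroblast
    populations whose young/old membership probabilities encode the
    published composition odds ratios (reticular old-enriched OR 1.685;
    pro-inflammatory young-enriched OR 1.666; dermal sheath F4a OR 7.097
    and F4b OR 2.258 young-enriched). Each population gets a planted
    10-gene marker program; F4a's program sits on the dermal-sheath
    signature symbols.
    """
    nm = 13  # MT- genes occupy indices 0..12, DS signature 13..22

    def program(start: int, k: int = 10) -> list[tuple[int, float]]:
        return [(start + j, marker_fold_change) for j in range(k)]

    pops = [
        PopulationSpec("F1", 0.300, 0.419328, program(30)),
        PopulationSpec("F2", 0.486, 0.466444, program(40)),
        PopulationSpec("F3", 0.150, 0.095781, program(50)),
        PopulationSpec("F4a", 0.034, 0.004935, program(nm)),  # DS signature genes
        PopulationSpec("F4b", 0.030, 0.013512, program(60)),
    ]
    return SyntheticSpec(
        n_young_donors=3,
        n_old_donors=4,
        cells_per_donor=cells_per_donor,
        populations=pops,
        n_genes=n_genes,
        seed=seed,
    )


def stemness_demo_spec(
    cells_per_donor: int = 700,
    n_genes: int = 1500,
    seed: int = 0,
    n_stem_genes: int = 40,
    stem_fold_change: float = 6.0,
    old_attenuation: float = 0.35,
) -> tuple[SyntheticSpec, list[int]]:
    """Balanced-composition cohort with a stem-cell program planted in the
    dermal-sheath population F4a and attenuated in old cells.

    Populations are near-balanced so every population has enough cells per
    age group for rank-based comparisons. Returns (spec, stem gene
    indices); the stem genes sit outside every marker program.
    """
    stem_idx = list(range(100, 100 + n_stem_genes))

    def program(start: int, fc: float = 8.0, k: int = 10) -> list[tuple[int, float]]:
        return [(start + j, fc) for j in range(k)]

    f4a_program = program(13) + [(g, stem_fold_change) for g in stem_idx]
    pops = [
        PopulationSpec("F1", 0.22, 0.22, program(30)),
        PopulationSpec("F2", 0.22, 0.22, program(40)),
        PopulationSpec("F3", 0.18, 0.18, program(50)),
        PopulationSpec("F4a", 0.20, 0.20, f4a_program),
        PopulationSpec("F4b", 0.18, 0.18, program(60)),
    ]
    spec = SyntheticSpec(
        n_young_donors=3,
        n_old_donors=4,
        cells_per_donor=cells_per_donor,
        populations=pops,
        n_genes=n_genes,
        aging_effects=[(g, old_attenuation) for g in stem_idx],
        seed=seed,
    )
    return spec, stem_idx


def write_cohort_bundle(
    spec: SyntheticSpec, out_dir: str | os.PathLike, gzipped: bool = False
) -> None:
    """Write matrix.mtx/features.tsv/barcodes.tsv plus meta.tsv and
    ground_truth.tsv under ``out_dir``."""
    cm, meta, gt = generate_cohort(spec)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_10x(cm, out_dir, gzipped=gzipped)
    meta.to_csv(os.path.join(out_dir, "meta.tsv"), sep="\t", index=False)
    gt.to_tsv(os.path.join(out_dir, "ground_truth.tsv"))
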