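"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the *statistical structure* of a curated
estrogen-receptor perturbation database — a shared ER-response program
modulated by drug class and dose, cell-line and batch effects, platform
gene-universe differences, planted bidirectional genes, mutant-shifted
cohort samples and TSS-proximal gained binding peaks — without attempting
to mimic real gene symbols, genome builds or any particular experiment
registry.  Every generator is deterministic given its seed; one master
seed fans out to independent child streams keyed by an artifact tag.

Effect sizes for the comparison generator are specified on the log2
fold-change scale (percentiles are a pipeline output, not an input); the
regression and cohort generators work directly on the scales their
consumers see (percentile points, log-expression standard deviations).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import ComparisonMeta, CountMatrix

__all__ = [
    "GroundTruth",
    "child_rng",
    "ComparisonConfig",
    "generate_comparisons",
    "generate_class_comparisons",
    "expected_class_correlation",
    "planted_percentile_matrix",
    "generate_regression_dataset",
    "generate_counts",
    "generate_cohort",
    "generate_peaks",
]


def child_rng(master_seed: int, tag: str) -> np.random.Generator:
    """Independent child stream: master seed + CRC32 of the artifact tag."""
    key = zlib.crc32(tag.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % (2**31), key]))


@dataclass
class GroundTruth:
    """Planted structure serialized alongside every generated dataset."""

    seed: int
    roles: dict[str, list[str]] = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_genes: set[str] = set()
        for role, genes in self.roles.items():
            overlap = all_genes & set(genes)
            if overlap:
                raise ValueError(f"role sets not disjoint at {role!r}: {sorted(overlap)[:3]}")
            all_genes |= set(genes)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], roles=d.get("roles", {}), design=d.get("design", {}))


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


# ---------------------------------------------------------------------------
# Differential-expression comparisons
# ---------------------------------------------------------------------------


@dataclass
class ComparisonConfig:
    """Stated world for the comparison generator.

    ``core_effect`` is the mean |log2FC| of the shared ER program at full
    drug potency; class multipliers scale it (a degrader flips the whole
    program harder than a partial agonist).  ``bidir_up_frac`` /
    ``bidir_down_frac`` are the fractions of comparisons in which a planted
    bidirectional gene responds up or down.  ``microarray_frac`` of
    comparisons use a reduced gene universe (``microarray_missing_frac`` of
    genes absent), exercising the presence filter.
    """

    n_genes: int = 2000
    n_comparisons: int = 40
    frac_core_up: float = 0.04
    frac_core_down: float = 0.04
    frac_bidirectional: float = 0.02
    core_effect: float = 2.0
    bidir_effect: float = 2.0
    bidir_up_frac: float = 0.3
    bidir_down_frac: float = 0.2
    noise_sd: float = 0.8
    class_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"SERD": 1.0, "SERM": 0.6}
    )
    cell_lines: Sequence[str] = ("CL1", "CL2", "CL3")
    cellline_sd: float = 0.2
    batch_sd: float = 0.2
    n_batches: int = 10
    doses_nM: Sequence[float] = (10.0, 100.0, 1000.0)
    dose_coef: float = 0.15
    durations_h: Sequence[float] = (6.0, 24.0, 48.0)
    microarray_frac: float = 0.25
    microarray_missing_frac: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        total = self.frac_core_up + self.frac_core_down + self.frac_bidirectional
        if total > 1:
            raise ValueError("role fractions sum above 1")
        if self.n_genes < 200:
            raise ValueError("n_genes must be >= 200")
        if not (0 <= self.bidir_up_frac <= 1 and 0 <= self.bidir_down_frac <= 1):
            raise ValueError("bidirectional fractions must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def strong(cls, **overrides) -> "ComparisonConfig":
        """Strong-effect configuration used for end-to-end recovery checks."""
        defaults = dict(core_effect=3.0, bidir_effect=3.0, noise_sd=0.5)
        defaults.update(overrides)
        return cls(**defaults)


def generate_comparisons(
    config: ComparisonConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, ComparisonMeta], GroundTruth]:
    """Simulate DE tables + metadata for a section of drug-treatment contrasts.

    Per gene g and comparison c:
    ``log2fc = mult(class_c) * core_effect * loading_g + cellline_effect
    + dose_coef * log10(dose_c) * loading_g + batch_draw + N(0, noise_sd)``
    where ``loading_g`` is positive for core-up genes, negative for
    core-down, zero for nulls, and sign-flipping for bidirectional genes.
    """
    config.validate()
    rng = child_rng(config.seed, "comparisons")
    genes = _gene_ids(config.n_genes)
    n_up = int(config.frac_core_up * config.n_genes)
    n_down = int(config.frac_core_down * config.n_genes)
    n_bidir = int(config.frac_bidirectional * config.n_genes)
    perm = rng.permutation(config.n_genes)
    core_up = genes[perm[:n_up]]
    core_down = genes[perm[n_up : n_up + n_down]]
    bidir = genes[perm[n_up + n_down : n_up + n_down + n_bidir]]
    magnitude = np.abs(rng.normal(1.0, 0.25, size=config.n_genes))
    loading = np.zeros(config.n_genes)
    loading[perm[:n_up]] = magnitude[perm[:n_up]]
    loading[perm[n_up : n_up + n_down]] = -magnitude[perm[n_up : n_up + n_down]]
    bidir_idx = perm[n_up + n_down : n_up + n_down + n_bidir]

    classes = list(config.class_multipliers)
    array_universe = None
    if config.microarray_missing_frac > 0:
        drop = rng.random(config.n_genes) < config.microarray_missing_frac
        array_universe = ~drop

    cell_effects = {
        cl: rng.normal(0.0, config.cellline_sd, size=config.n_genes)
        for cl in config.cell_lines
    }
    batch_ids = [f"B{i:02d}" for i in range(config.n_batches)]
    batch_effects = {
        b: rng.normal(0.0, config.batch_sd, size=config.n_genes) for b in batch_ids
    }

    tables: dict[str, pd.DataFrame] = {}
    metas: dict[str, ComparisonMeta] = {}
    for c in range(config.n_comparisons):
        cid = f"C{c:03d}"
        drug_class = classes[c % len(classes)]
        cell = config.cell_lines[(c // len(classes)) % len(config.cell_lines)]
        dose = float(rng.choice(np.asarray(config.doses_nM)))
        duration = float(rng.choice(np.asarray(config.durations_h)))
        batch = batch_ids[c % config.n_batches]
        is_array = rng.random() < config.microarray_frac

        load_c = loading.copy()
        u = rng.random(n_bidir)
        sign = np.where(
            u < config.bidir_up_frac,
            1.0,
            np.where(u < config.bidir_up_frac + config.bidir_down_frac, -1.0, 0.0),
        )
        load_c[bidir_idx] = sign * magnitude[bidir_idx] * (
            config.bidir_effect / max(config.core_effect, 1e-12)
        )
        lfc = (
            config.class_multipliers[drug_class] * config.core_effect * load_c
            + cell_effects[cell]
            + config.dose_coef * np.log10(dose) * load_c
            + batch_effects[batch]
            + rng.normal(0.0, config.noise_sd, size=config.n_genes)
        )
        keep = array_universe if (is_array and array_universe is not None) else np.ones(
            config.n_genes, dtype=bool
        )
        tables[cid] = pd.DataFrame(
            {"gene_id": genes[keep], "log2fc": lfc[keep], "padj": np.nan}
        )
        metas[cid] = ComparisonMeta(
            comparison_id=cid,
            section="modulator",
            cell_line=cell,
            modality="microarray" if is_array else "RNAseq",
            batch_id=batch,
            compound=f"{drug_class}_drug",
            compound_class=drug_class,
            dose_nM=dose,
            duration_h=duration,
        )
    truth = GroundTruth(
        seed=config.seed,
        roles={
            "core_up": sorted(core_up),
            "core_down": sorted(core_down),
            "bidirectional": sorted(bidir),
        },
        design={"config": asdict(config)},
    )
    return tables, metas, truth


# ---------------------------------------------------------------------------
# Two drug classes with partially shared effect genes (correlation design)
# ---------------------------------------------------------------------------


def generate_class_comparisons(
    n_genes: int = 2000,
    n_per_class: int = 15,
    class_names: Sequence[str] = ("classA", "classB"),
    effect: float = 2.0,
    gene_frac: float = 0.2,
    overlap: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, ComparisonMeta], GroundTruth]:
    """Two drug classes whose effect-gene sets share a chosen fraction.

    Each class regulates ``gene_frac`` of the genes; a fraction ``overlap``
    of each class's effect genes is drawn from a common pool and carries
    the *same* loading in both classes, so the noise-free design
    correlation between class-average profiles is known in closed form
    (:func:`expected_class_correlation`).
    """
    rng = child_rng(seed, "class_comparisons")
    genes = _gene_ids(n_genes)
    n_eff = int(gene_frac * n_genes)
    n_shared = int(overlap * n_eff)
    perm = rng.permutation(n_genes)
    shared = perm[:n_shared]
    only_a = perm[n_shared : n_eff]
    only_b = perm[n_eff : 2 * n_eff - n_shared]
    loading = rng.normal(0.0, 1.0, size=n_genes)

    tables: dict[str, pd.DataFrame] = {}
    metas: dict[str, ComparisonMeta] = {}
    for k, cls in enumerate(class_names):
        active = np.zeros(n_genes, dtype=bool)
        active[shared] = True
        active[only_a if k == 0 else only_b] = True
        for i in range(n_per_class):
            cid = f"{cls}_{i:02d}"
            lfc = effect * loading * active + rng.normal(0.0, noise_sd, size=n_genes)
            tables[cid] = pd.DataFrame({"gene_id": genes, "log2fc": lfc, "padj": np.nan})
            metas[cid] = ComparisonMeta(
                comparison_id=cid,
                section="modulator",
                cell_line="CL1",
                modality="RNAseq",
                batch_id=f"{cls}_B{i:02d}",
                compound=cls,
                compound_class="SERM" if k == 0 else "SERD",
                dose_nM=100.0,
                duration_h=24.0,
            )
    truth = GroundTruth(
        seed=seed,
        roles={
            "shared_effect": sorted(genes[shared]),
            "classA_only": sorted(genes[only_a]),
            "classB_only": sorted(genes[only_b]),
        },
        design={
            "effect": effect,
            "gene_frac": gene_frac,
            "overlap": overlap,
            "noise_sd": noise_sd,
            "n_per_class": n_per_class,
        },
    )
    return tables, metas, truth


def expected_class_correlation(
    effect: float,
    gene_frac: float,
    overlap: float,
    noise_sd: float,
    n_per_class: int,
) -> float:
    """Closed-form Pearson correlation of the two class-average profiles.

    With loadings ~ N(0,1) shared on the overlap, class-average log2FC for
    gene g is ``effect * l_g * 1[g in G_c] + eps`` with eps variance
    ``noise_sd^2 / n_per_class``.  Across genes:
    cov = effect^2 * f_shared, var = effect^2 * f + noise_sd^2/n, giving
    r = f_shared / (f + noise_sd^2 / (effect^2 * n)).
    """
    f = gene_frac
    f_shared = overlap * gene_frac
    noise_term = noise_sd**2 / (effect**2 * n_per_class)
    return f_shared / (f + noise_term)


# ---------------------------------------------------------------------------
# Planted percentile matrices (bidirectional-gene stated world)
# ---------------------------------------------------------------------------


def planted_percentile_matrix(
    n_genes: int = 2000,
    n_comparisons: int = 20,
    n_bidirectional: int = 40,
    up_frac: float = 0.3,
    down_frac: float = 0.2,
    up_value: float = 95.0,
    down_value: float = -95.0,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Percentile matrix with planted bidirectional genes.

    Planted genes sit at ``up_value`` in ``up_frac`` of the comparisons and
    ``down_value`` in ``down_frac``; everything else is N(0, noise_sd)
    clipped to [-100, 100].
    """
    rng = child_rng(seed, "planted_percentiles")
    genes = _gene_ids(n_genes)
    m = np.clip(rng.normal(0.0, noise_sd, size=(n_genes, n_comparisons)), -100, 100)
    n_up = int(round(up_frac * n_comparisons))
    n_down = int(round(down_frac * n_comparisons))
    bidir_idx = rng.choice(n_genes, size=n_bidirectional, replace=False)
    for g in bidir_idx:
        cols = rng.permutation(n_comparisons)
        m[g, cols[:n_up]] = up_value
        m[g, cols[n_up : n_up + n_down]] = down_value
    df = pd.DataFrame(
        m,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"C{c:03d}" for c in range(n_comparisons)],
    )
    truth = GroundTruth(
        seed=seed,
        roles={"bidirectional": sorted(genes[bidir_idx])},
        design={
            "up_frac": up_frac,
            "down_frac": down_frac,
            "up_value": up_value,
            "down_value": down_value,
            "noise_sd": noise_sd,
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# Regression design (mixed-model tests)
# ---------------------------------------------------------------------------


def generate_regression_dataset(
    n_genes: int = 100,
    n_comparisons: int = 40,
    drug_effect: float = 0.0,
    affected_frac: float = 1.0,
    noise_sd: float = 10.0,
    batch_sd: float = 8.0,
    n_batches: int = 10,
    cell_lines: Sequence[str] = ("CL1", "CL2", "CL3"),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ComparisonMeta], GroundTruth]:
    """Percentile-scale responses with a planted drug-type effect.

    Affected genes gain ``drug_effect`` percentile points in SERD-treated
    comparisons relative to SERM; batches contribute a shared random
    intercept of sd ``batch_sd``.  With ``drug_effect=0`` this is the null
    generator for calibration checks.
    """
    rng = child_rng(seed, "regression")
    genes = _gene_ids(n_genes)
    n_affected = int(round(affected_frac * n_genes))
    affected = np.zeros(n_genes, dtype=bool)
    affected[rng.choice(n_genes, size=n_affected, replace=False)] = True

    # each batch holds consecutive comparisons, so both drug types occur
    # within a batch and the drug effect is identifiable past the random
    # intercept; the remaining covariates are drawn independently to avoid
    # accidental collinearity between cyclic assignments
    batch_ids = [f"B{i:02d}" for i in range(n_batches)]
    per_batch = int(np.ceil(n_comparisons / n_batches))
    metas: dict[str, ComparisonMeta] = {}
    is_serd = np.zeros(n_comparisons, dtype=bool)
    batch_index = np.zeros(n_comparisons, dtype=int)
    for c in range(n_comparisons):
        cid = f"C{c:03d}"
        drug = "SERD" if c % 2 == 0 else "SERM"
        is_serd[c] = drug == "SERD"
        batch_index[c] = min(c // per_batch, n_batches - 1)
        metas[cid] = ComparisonMeta(
            comparison_id=cid,
            section="modulator",
            cell_line=str(rng.choice(np.asarray(cell_lines))),
            modality="RNAseq" if rng.random() < 0.75 else "microarray",
            batch_id=batch_ids[batch_index[c]],
            compound=f"{drug}_drug",
            compound_class=drug,
            dose_nM=100.0,
            duration_h=float(rng.choice(np.asarray([6.0, 24.0, 48.0]))),
        )
    y = np.empty((n_genes, n_comparisons))
    for g in range(n_genes):
        batch_draw = rng.normal(0.0, batch_sd, size=n_batches)
        y[g] = (
            (drug_effect if affected[g] else 0.0) * is_serd
            + batch_draw[batch_index]
            + rng.normal(0.0, noise_sd, size=n_comparisons)
        )
    df = pd.DataFrame(
        y, index=pd.Index(genes, name="gene_id"), columns=[f"C{c:03d}" for c in range(n_comparisons)]
    )
    truth = GroundTruth(
        seed=seed,
        roles={"drug_affected": sorted(genes[affected])},
        design={
            "drug_effect": drug_effect,
            "noise_sd": noise_sd,
            "batch_sd": batch_sd,
            "effect_term": "SERD vs SERM",
        },
    )
    return df, metas, truth


# ---------------------------------------------------------------------------
# Counts (no-replicate fallback path)
# ---------------------------------------------------------------------------


def generate_counts(
    n_genes: int = 2000,
    log2fc: np.ndarray | None = None,
    depth: float = 1e6,
    dispersion: float = 0.05,
    n_control: int = 1,
    n_treated: int = 1,
    seed: int = 0,
) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial count matrices with a designed per-gene fold change.

    Baseline abundances are log-normal; treated means are the control means
    scaled by ``2**log2fc``.  ``dispersion`` is the NB overdispersion
    (var = mu + dispersion * mu^2); dispersion -> 0 recovers Poisson.
    """
    if depth < 1e5:
        raise ValueError("mean depth must be >= 1e5")
    rng = child_rng(seed, "counts")
    genes = _gene_ids(n_genes)
    if log2fc is None:
        log2fc = np.zeros(n_genes)
    log2fc = np.asarray(log2fc, dtype=float)
    rel = np.exp(rng.normal(0.0, 1.5, size=n_genes))
    rel /= rel.sum()
    mu_control = depth * rel
    mu_treated = mu_control * 2.0**log2fc

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion <= 0:
            return rng.poisson(mu)
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam)

    cols = {}
    groups = {}
    for i in range(n_control):
        name = f"control_{i}"
        cols[name] = draw(mu_control)
        groups[name] = "control"
    for i in range(n_treated):
        name = f"treated_{i}"
        cols[name] = draw(mu_treated)
        groups[name] = "treated"
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    truth = GroundTruth(
        seed=seed,
        roles={},
        design={"depth": depth, "dispersion": dispersion, "log2fc_mean": float(log2fc.mean())},
    )
    return CountMatrix(counts=counts, groups=groups), truth


# ---------------------------------------------------------------------------
# Cohort (classification stage)
# ---------------------------------------------------------------------------


def generate_cohort(
    n_samples: int = 100,
    case_frac: float = 0.3,
    effect: float = 1.0,
    n_genes: int = 1000,
    n_up: int = 50,
    n_down: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Expression cohort with case samples shifted on planted signature genes.

    Log2 expression is N(mu_g, 1) per gene; cases gain ``effect`` (in sd
    units) on activation-set genes and lose it on repression-set genes.
    Returns (expression genes x samples, binary labels, truth).
    """
    n_cases = int(round(case_frac * n_samples))
    if n_cases < 5 or n_samples - n_cases < 5:
        raise ValueError("both classes need >= 5 samples")
    rng = child_rng(seed, "cohort")
    genes = _gene_ids(n_genes)
    perm = rng.permutation(n_genes)
    up_idx, down_idx = perm[:n_up], perm[n_up : n_up + n_down]
    mu = rng.normal(7.0, 2.0, size=n_genes)
    log2x = mu[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    labels = np.zeros(n_samples, dtype=int)
    case_cols = rng.choice(n_samples, size=n_cases, replace=False)
    labels[case_cols] = 1
    log2x[np.ix_(up_idx, case_cols)] += effect
    log2x[np.ix_(down_idx, case_cols)] -= effect
    samples = [f"S{i:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(2.0**log2x, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = GroundTruth(
        seed=seed,
        roles={"activation_set": sorted(genes[up_idx]), "repression_set": sorted(genes[down_idx])},
        design={"effect": effect, "case_frac": case_frac},
    )
    return expr, pd.Series(labels, index=samples, name="label"), truth


# ---------------------------------------------------------------------------
# Peaks (gained-binding stage)
# ---------------------------------------------------------------------------


def generate_peaks(
    chrom_sizes: Mapping[str, int] | None = None,
    n_genes: int = 200,
    n_background: int = 300,
    n_targets: int = 10,
    peaks_per_target: int = 4,
    n_extra_gained: int = 15,
    n_mutant_sets: int = 3,
    planted_max_offset: int = 10_000,
    peak_width: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[pd.DataFrame], pd.DataFrame, GroundTruth]:
    """WT and mutant peak sets on a toy genome, with peaks planted near target TSSs.

    Each mutant set is the WT background plus ``peaks_per_target`` peaks
    within ``planted_max_offset`` of every target gene's TSS, plus
    ``n_extra_gained`` unlinked gained peaks.  Returns
    (wt_peaks, [mutant_peaks...], annotation, truth).
    """
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 3_000_000, "chr2": 3_000_000}
    if min(chrom_sizes.values()) < 1_000_000:
        raise ValueError("chromosomes must be >= 1e6 bp")
    rng = child_rng(seed, "peaks")
    chroms = list(chrom_sizes)
    gene_chrom = rng.choice(len(chroms), size=n_genes)
    margin = planted_max_offset + peak_width
    tss = np.array(
        [rng.integers(margin, chrom_sizes[chroms[c]] - margin) for c in gene_chrom]
    )
    genes = _gene_ids(n_genes)
    ann = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": [chroms[c] for c in gene_chrom],
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )

    def random_peaks(n: int) -> pd.DataFrame:
        c = rng.choice(len(chroms), size=n)
        starts = np.array(
            [rng.integers(0, chrom_sizes[chroms[ci]] - peak_width) for ci in c]
        )
        return pd.DataFrame(
            {"chrom": [chroms[ci] for ci in c], "start": starts, "end": starts + peak_width}
        )

    wt = random_peaks(n_background).sort_values(["chrom", "start"]).reset_index(drop=True)
    target_idx = rng.choice(n_genes, size=n_targets, replace=False)
    mutant_sets = []
    for _ in range(n_mutant_sets):
        planted_rows = []
        for gi in target_idx:
            offsets = rng.integers(-planted_max_offset, planted_max_offset, size=peaks_per_target)
            for off in offsets:
                center = int(tss[gi] + off)
                planted_rows.append(
                    {
                        "chrom": chroms[gene_chrom[gi]],
                        "start": max(center - peak_width // 2, 0),
                        "end": center + peak_width // 2,
                    }
                )
        mut = pd.concat(
            [wt, pd.DataFrame(planted_rows), random_peaks(n_extra_gained)],
            ignore_index=True,
        )
        mutant_sets.append(mut.sort_values(["chrom", "start"]).reset_index(drop=True))
    truth = GroundTruth(
        seed=seed,
        roles={"peak_targets": sorted(genes[target_idx])},
        design={
            "n_mutant_sets": n_mutant_sets,
            "peaks_per_target": peaks_per_target,
            "planted_max_offset": planted_max_offset,
        },
    )
    return wt, mutant_sets, ann, truth
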