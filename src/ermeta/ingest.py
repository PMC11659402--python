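"""Ingestion of comparison metadata, differential-expression tables and raw counts.

A *comparison* is one treated-vs-control contrast from one experiment
(e.g. MCF7 + 100 nM fulvestrant for 24 h vs vehicle).  Upstream
differential-expression model fitting (DESeq2, limma) is out of scope:
tables arrive as gene-level log2 fold changes with adjusted p-values.
The one computation owned here is the no-replicate fallback: TMM-normalised
log2(CPM + 1) fold changes from raw counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonMeta",
    "CountMatrix",
    "SchemaError",
    "ValidationError",
    "read_metadata",
    "read_de_table",
    "write_de_table",
    "validate_de_table",
    "read_counts",
    "parse_dose_nM",
    "tmm_factors",
    "log2cpm_fold_change",
]

SECTIONS = {"E2", "modulator", "TamR", "LTED", "ESR1mut"}
COMPOUND_CLASSES = {"SERM", "SERD", "hybrid", "SERCA", "LDD", "SERD_analog", "siRNA", "none"}
MODALITIES = {"RNAseq", "microarray"}
CONSTRUCTIONS = {"GE", "OE", "natural", "none"}
RESISTANCE_SECTIONS = {"TamR", "LTED", "ESR1mut"}

#: compounds whose registry label does not distinguish tamoxifen from 4-OHT
UNSPECIFIED_TAMOXIFEN = "tamoxifen (unspecified)"


class SchemaError(ValueError):
    """A required column is missing or malformed in an input file."""


class ValidationError(ValueError):
    """Row-level content violates a type invariant."""


@dataclass(frozen=True)
class ComparisonMeta:
    """Covariates of one harmonized treated-vs-control contrast.

    ``batch_id`` groups contrasts that share a control sample set; it is
    the random-effect grouping of the per-gene mixed model.  ``dose_nM``
    and ``duration_h`` may be null only for resistance models (TamR, LTED,
    ESR1 mutant), which have no acute treatment.
    """

    comparison_id: str
    section: str
    cell_line: str
    modality: str
    batch_id: str
    compound: str | None = None
    compound_class: str = "none"
    dose_nM: float | None = None
    duration_h: float | None = None
    variant: str | None = None
    construction: str = "none"
    unspecified_tamoxifen: bool = False

    def __post_init__(self) -> None:
        if not self.comparison_id:
            raise ValidationError("comparison_id must be non-empty")
        if not self.batch_id:
            raise ValidationError(f"{self.comparison_id}: batch_id must be non-empty")
        for name, value, allowed in (
            ("section", self.section, SECTIONS),
            ("compound_class", self.compound_class, COMPOUND_CLASSES),
            ("modality", self.modality, MODALITIES),
            ("construction", self.construction, CONSTRUCTIONS),
        ):
            if value not in allowed:
                raise ValidationError(
                    f"{self.comparison_id}: {name}={value!r} not in {sorted(allowed)}"
                )
        for name, value in (("dose_nM", self.dose_nM), ("duration_h", self.duration_h)):
            if value is not None and not value >= 0:
                raise ValidationError(f"{self.comparison_id}: {name} must be >= 0")
            if value is None and self.section not in RESISTANCE_SECTIONS:
                raise ValidationError(
                    f"{self.comparison_id}: {name} may be null only for "
                    f"resistance sections {sorted(RESISTANCE_SECTIONS)}"
                )


_ENUM_CANON = {v.lower(): v for v in SECTIONS | COMPOUND_CLASSES | MODALITIES | CONSTRUCTIONS}
_ENUM_CANON.update({"rna-seq": "RNAseq", "rnaseq": "RNAseq", "array": "microarray"})

_DOSE_UNITS_TO_NM = {
    "nm": 1.0,
    "nmol/l": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "μm": 1e3,
    "umol/l": 1e3,
    "µmol/l": 1e3,
    "μmol/l": 1e3,
    "mm": 1e6,
    "pm": 1e-3,
}

_REQUIRED_META_COLUMNS = (
    "comparison_id",
    "section",
    "cell_line",
    "modality",
    "batch_id",
)


def parse_dose_nM(raw: object) -> float | None:
    """Parse a dose string like ``"100 nmol/L"`` or ``"1 uM"`` into nM.

    Bare numbers are taken to be nM already.  Unparseable values yield
    ``None`` with a logged warning rather than an error — the source
    registries are heterogeneous and a missing dose is recoverable
    downstream, a crashed ingest is not.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if isinstance(raw, (int, float)):
        return float(raw)
    text = str(raw).strip()
    if not text or text.lower() in {"na", "nan", "none", ""}:
        return None
    m = re.fullmatch(r"([-+0-9.eE]+)\s*([a-zA-Zµμ/]*)", text)
    if m is None:
        logger.warning("unparseable dose %r -> null", raw)
        return None
    try:
        value = float(m.group(1))
    except ValueError:
        logger.warning("unparseable dose %r -> null", raw)
        return None
    unit = m.group(2).lower()
    if unit == "":
        return value
    factor = _DOSE_UNITS_TO_NM.get(unit)
    if factor is None:
        logger.warning("unknown dose unit %r in %r -> null", unit, raw)
        return None
    return value * factor


def _canon_enum(value: object, default: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return default
    text = str(value).strip()
    if not text:
        return default
    return _ENUM_CANON.get(text.lower(), text)


def _opt_str(value: object) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def _opt_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_metadata(path: str | Path) -> list[ComparisonMeta]:
    """Read the comparison registry CSV into validated :class:`ComparisonMeta`.

    Required columns: comparison_id, section, cell_line, modality, batch_id.
    Optional: compound, compound_class, dose, duration_h, variant,
    construction.  Enum values are normalized case-insensitively; doses are
    unit-normalized to nM.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    dupes = df["comparison_id"][df["comparison_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate comparison_id(s): {', '.join(map(str, dupes))}")
    metas: list[ComparisonMeta] = []
    for _, row in df.iterrows():
        compound = _opt_str(row.get("compound"))
        unspec = bool(compound) and compound.strip().lower() == "tamoxifen"
        if unspec:
            compound = UNSPECIFIED_TAMOXIFEN
        metas.append(
            ComparisonMeta(
                comparison_id=str(row["comparison_id"]).strip(),
                section=_canon_enum(row["section"], "modulator"),
                cell_line=str(row["cell_line"]).strip(),
                modality=_canon_enum(row["modality"], "RNAseq"),
                batch_id=str(row["batch_id"]).strip(),
                compound=compound,
                compound_class=_canon_enum(row.get("compound_class"), "none"),
                dose_nM=parse_dose_nM(row.get("dose")),
                duration_h=_opt_float(row.get("duration_h")),
                variant=_opt_str(row.get("variant")),
                construction=_canon_enum(row.get("construction"), "none"),
                unspecified_tamoxifen=unspec,
            )
        )
    return metas


def write_metadata(metas: Iterable[ComparisonMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "comparison_id": m.comparison_id,
                "section": m.section,
                "cell_line": m.cell_line,
                "modality": m.modality,
                "batch_id": m.batch_id,
                "compound": m.compound,
                "compound_class": m.compound_class,
                "dose": m.dose_nM,
                "duration_h": m.duration_h,
                "variant": m.variant,
                "construction": m.construction,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ("gene_id", "log2fc", "padj")


def validate_de_table(de: pd.DataFrame, *, name: str = "DE table") -> pd.DataFrame:
    """Check the (gene_id, log2fc, padj) invariants and return the table."""
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s): {', '.join(missing)}")
    if de["gene_id"].duplicated().any():
        dupes = de.loc[de["gene_id"].duplicated(), "gene_id"].unique()[:5]
        raise ValidationError(f"{name}: duplicate gene_id(s), e.g. {list(dupes)}")
    if not np.isfinite(de["log2fc"].to_numpy(dtype=float)).all():
        bad = de.loc[~np.isfinite(de["log2fc"].astype(float)), "gene_id"].tolist()[:5]
        raise ValidationError(f"{name}: non-finite log2fc for gene(s) {bad}")
    padj = de["padj"].to_numpy(dtype=float)
    ok = np.isnan(padj) | ((padj >= 0) & (padj <= 1))
    if not ok.all():
        raise ValidationError(f"{name}: padj outside [0, 1]")
    return de


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return validate_de_table(de, name=str(path))


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    validate_de_table(de)[list(DE_COLUMNS)].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Counts and the no-replicate fold-change path
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) with a control/treated group map."""

    counts: pd.DataFrame
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts contain negative entries")
        unknown = set(self.groups) - set(self.counts.columns)
        if unknown:
            raise ValidationError(f"group map names unknown samples: {sorted(unknown)}")
        labels = set(self.groups.values())
        if self.groups and not labels <= {"control", "treated"}:
            raise ValidationError(f"group labels must be control/treated, got {sorted(labels)}")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups.get(s) == group]


def read_counts(path: str | Path, groups: Mapping[str, str] | None = None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, groups=dict(groups or {}))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_M: float,
    trim_A: float,
    weighted: bool,
) -> float:
    """edgeR-style doubly trimmed (weighted) mean of M-values for one sample pair."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        M = np.log2(p_obs / p_ref)
        A = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M for count data
        w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(M) & np.isfinite(A) & (A > -1e10)
    M, A, w = M[keep], A[keep], w[keep]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * trim_M) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_A) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 1.0
    if weighted:
        f = np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel])
    else:
        f = np.mean(M[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    ref_sample: str | None = None,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample defaults to the one whose upper-quartile CPM is
    closest to the mean upper quartile across samples.  Genes with zero
    counts in every sample are dropped before normalization.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValidationError("TMM needs at least 2 samples")
    zero_samples = df.columns[(df.sum(axis=0) == 0)].tolist()
    if zero_samples:
        raise ValidationError(f"all-zero sample(s): {', '.join(map(str, zero_samples))}")
    df = df.loc[df.sum(axis=1) > 0]
    x = df.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if ref_sample is None:
        uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = list(df.columns).index(ref_sample)
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_j], lib[j], lib[ref_j], trim_M, trim_A, weighted)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def log2cpm_fold_change(
    counts: CountMatrix,
    drop_all_zero: bool = True,
    **tmm_kwargs,
) -> pd.DataFrame:
    """No-replicate fold changes: treated minus control mean log2(CPM + 1).

    CPM uses TMM-scaled effective library sizes.  With replicated groups the
    group means of the log2(CPM + 1) values are differenced.  Returns a DE
    table with ``padj`` null throughout (no model is fitted).
    """
    treated = counts.samples("treated")
    control = counts.samples("control")
    if not treated or not control:
        raise ValidationError("need at least one control and one treated sample")
    df = counts.counts
    if drop_all_zero:
        df = df.loc[df.sum(axis=1) > 0]
    factors = tmm_factors(df, **tmm_kwargs)
    eff_lib = df.sum(axis=0) * factors
    cpm = df / eff_lib * 1e6
    logcpm = np.log2(cpm + 1.0)
    log2fc = logcpm[treated].mean(axis=1) - logcpm[control].mean(axis=1)
    out = pd.DataFrame(
        {"gene_id": df.index.astype(str), "log2fc": log2fc.to_numpy(), "padj": np.nan}
    )
    return validate_de_table(out.reset_index(drop=True))
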