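"""Regulatory-percentile harmonization across heterogeneous comparisons.

Every comparison, whatever its platform or model, is reduced to one
per-gene *regulatory percentile* in [-100, +100]: the most repressed gene
in that comparison is -100, the most activated is +100, unchanged genes
are 0.  Up- and down-regulated genes are ranked separately within their
own pools, so the transform is invariant to any sign-preserving monotone
rescaling of the fold changes — which is exactly what makes microarray and
RNA-seq contrasts commensurable.

The percentile matrix (genes x comparisons) is the substrate of every
downstream statistic.  A gene missing from one platform's universe is
missing, never zero.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ingest import ComparisonMeta, ValidationError, validate_de_table

logger = logging.getLogger(__name__)

__all__ = [
    "percentile_rank",
    "build_matrix",
    "presence_filter",
    "average_percentile",
    "read_matrix",
    "write_matrix",
    "validate_matrix",
]


def percentile_rank(de: pd.DataFrame, scale: str = "rank") -> pd.Series:
    """Map one comparison's fold changes to regulatory percentiles.

    With ``scale="rank"`` (default) the up-regulated pool of size ``u`` is
    rank-transformed to {100*k/u : k=1..u} (mid-ranks on ties) and the
    down-regulated pool symmetrically to negative values by magnitude rank;
    genes with log2fc == 0 stay at 0.  ``scale="fc"`` instead scales the
    fold changes themselves linearly so the pool extremes hit +/-100.

    Parameters
    ----------
    de:
        DE table with columns gene_id, log2fc (padj ignored).
    scale:
        "rank" or "fc".

    Returns
    -------
    pandas.Series
        Percentile per gene_id, in [-100, +100].
    """
    if len(de) == 0:
        raise ValidationError("empty DE table")
    validate_de_table(de)
    if scale not in {"rank", "fc"}:
        raise ValueError(f"scale must be 'rank' or 'fc', got {scale!r}")
    fc = de["log2fc"].to_numpy(dtype=float)
    pct = np.zeros(len(fc))
    up = fc > 0
    down = fc < 0
    if scale == "rank":
        if up.any():
            pct[up] = rankdata(fc[up]) / up.sum() * 100.0
        if down.any():
            pct[down] = -rankdata(-fc[down]) / down.sum() * 100.0
    else:
        if up.any():
            pct[up] = fc[up] / fc[up].max() * 100.0
        if down.any():
            pct[down] = fc[down] / np.abs(fc[down]).max() * 100.0
    return pd.Series(pct, index=pd.Index(de["gene_id"].astype(str), name="gene_id"), name="pct")


def build_matrix(
    columns: Mapping[str, pd.Series],
    metas: Mapping[str, ComparisonMeta] | None = None,
) -> pd.DataFrame:
    """Assemble percentile columns into a genes x comparisons matrix.

    The gene universe is the union across columns; a gene absent from a
    comparison is NaN in that column (missing, not zero).
    """
    ids = list(columns)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate comparison ids")
    if metas is not None:
        absent = [c for c in ids if c not in metas]
        if absent:
            raise ValidationError(f"comparison ids without metadata: {absent}")
    if not ids:
        return pd.DataFrame(index=pd.Index([], name="gene_id"))
    for cid, col in columns.items():
        vals = col.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (np.abs(finite) > 100 + 1e-9).any():
            raise ValidationError(f"column {cid}: values outside [-100, 100]")
        if col.index.duplicated().any():
            raise ValidationError(f"column {cid}: duplicate gene ids")
    m = pd.DataFrame({cid: col for cid, col in columns.items()})
    m.index.name = "gene_id"
    return m.sort_index()


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    vals = m.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (np.abs(finite) > 100 + 1e-9).any():
        raise ValidationError("percentile matrix has values outside [-100, 100]")
    return m


def _scope_columns(m: pd.DataFrame, scope: Sequence[str] | None) -> list[str]:
    if scope is None:
        return list(m.columns)
    scope = list(scope)
    unknown = [c for c in scope if c not in m.columns]
    if unknown:
        raise ValidationError(f"scope names unknown comparisons: {unknown}")
    return scope


def presence_filter(
    m: pd.DataFrame,
    min_frac: float = 0.8,
    scope: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Drop genes observed in fewer than ``min_frac`` of the scoped comparisons.

    The boundary is inclusive: a gene present in exactly ``min_frac`` of the
    comparisons is retained.  Idempotent for a fixed scope.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    cols = _scope_columns(m, scope)
    if not cols:
        raise ValidationError("empty scope")
    frac = m[cols].notna().sum(axis=1) / len(cols)
    return m.loc[frac >= min_frac - 1e-12]


def average_percentile(m: pd.DataFrame, scope: Sequence[str] | None = None) -> pd.Series:
    """Mean regulatory percentile per gene over non-missing scoped values."""
    cols = _scope_columns(m, scope)
    if not cols:
        raise ValidationError("empty scope")
    return m[cols].mean(axis=1, skipna=True).rename("avg_pct")


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    m.index = m.index.astype(str)
    m.index.name = "gene_id"
    return validate_matrix(m)
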