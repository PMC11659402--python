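"""Gene-set statistics on percentile profiles and expression matrices.

Four distinct tools live here:

* Fisher over-representation of a discrete gene call against a collection.
* Preranked GSEA on a per-gene ranking (e.g. average regulatory
  percentiles), with gene-permutation NES and sign-stratified FDR.
* A signature fold-change screen: the geometric mean of a custom gene set
  per sample, compared treated vs control across many comparisons.
* A rank-z single-sample signature scorer (a light, monotone stand-in for
  GSVA-style scoring) and the Oncotype DX weighted-impact formula on
  regulatory percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ttest_ind
from statsmodels.stats.multitest import multipletests

from .ingest import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "fisher_ora",
    "hypergeom_tail",
    "enrichment_score",
    "preranked_gsea",
    "signature_fold_change",
    "single_sample_score",
    "oncotype_weighted_impact",
    "ONCOTYPE_GROUPS",
    "ONCOTYPE_COEFFICIENTS",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with a category label (e.g. ``Hallmark``)."""

    sets: dict[str, list[str]]
    category: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted(self, universe: set[str], min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and apply size bounds."""
        out = {}
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in universe]
            if len(kept) >= min_size and (max_size is None or len(kept) <= max_size):
                out[name] = kept
        return GeneSetCollection(out, self.category)


def read_gmt(path: str | Path, category: str = "") -> GeneSetCollection:
    """Read a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    return GeneSetCollection(sets, category or Path(path).stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.category, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Fisher over-representation
# ---------------------------------------------------------------------------


def hypergeom_tail(universe: int, term: int, query: int, overlap: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    return float(hypergeom.sf(overlap - 1, universe, term, query))


def fisher_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of ``query`` in each set.

    The 2x2 table per term is (overlap, query-only, term-only, neither) on
    the given universe; p is the hypergeometric upper tail, adjusted across
    terms by Benjamini-Hochberg.  Query genes outside the universe are
    dropped with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        logger.warning("%d query gene(s) outside universe dropped", len(outside))
        q &= uni
    rows = []
    for name in sorted(collection.sets):
        term = set(collection.sets[name]) & uni
        if not term:
            continue
        a = len(q & term)
        b = len(q - term)
        c = len(term - q)
        d = len(uni) - a - b - c
        odds = (a * d) / (b * c) if b * c > 0 else (0.0 if a == 0 else np.inf)
        rows.append(
            {
                "term": name,
                "overlap": a,
                "query_size": len(q),
                "term_size": len(term),
                "odds_ratio": odds,
                "p": hypergeom_tail(len(uni), len(term), len(q), a),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = np.maximum(multipletests(out["p"], method="fdr_bh")[1], out["p"])
        out = out.sort_values(["padj", "p", "term"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


def _es_from_positions(
    positions: np.ndarray,
    values_sorted: np.ndarray,
    weight: float,
) -> np.ndarray:
    """Enrichment scores for hit-position sets against a fixed ranked list.

    ``positions`` is (B, k): 0-based positions of the set's genes in the
    descending-ranked list, one permutation per row.  The running-sum
    extrema are evaluated analytically at hit boundaries only, which is
    exact because the statistic is piecewise linear between hits.
    """
    n = values_sorted.size
    b, k = positions.shape
    if k == n:
        return np.zeros(b)
    pos = np.sort(positions, axis=1)
    w = np.abs(values_sorted[pos]) ** weight
    sumw = w.sum(axis=1, keepdims=True)
    flat = sumw[:, 0] == 0
    if flat.any():  # all hit values zero: fall back to equal hit increments
        w[flat] = 1.0
        sumw = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1) / sumw
    d = 1.0 / (n - k)
    idx = np.arange(k)[None, :]
    after = cumw - (pos - idx) * d
    before = after - w / sumw
    best = after.max(axis=1)
    worst = before.min(axis=1)
    # positive deviation wins ties (within float tolerance of an exact tie)
    return np.where(np.abs(best) >= np.abs(worst) - 1e-9, best, worst)


def enrichment_score(
    ranking: pd.Series,
    gene_set: Iterable[str],
    weight: float = 1.0,
) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score of one set in a ranking.

    Hit increments are proportional to |ranking value|^weight; misses
    decrement uniformly.  ``weight=0`` reduces to the classic unweighted KS
    statistic.  The score is the running sum's maximum deviation from zero
    (sign retained; positive deviation wins ties).
    """
    order = np.argsort(-ranking.to_numpy(), kind="stable")
    genes = ranking.index.to_numpy()[order]
    values = ranking.to_numpy()[order]
    gene_pos = {g: i for i, g in enumerate(genes)}
    hits = sorted(gene_pos[g] for g in set(gene_set) if g in gene_pos)
    if not hits:
        raise ValidationError("gene set has no overlap with the ranking")
    return float(_es_from_positions(np.array([hits]), values, weight)[0])


def preranked_gsea(
    ranking: pd.Series,
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 1000,
    n_perm: int = 1000,
    seed: int = 6,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with gene-permutation NES and sign-stratified FDR.

    Sets are restricted to the ranking's universe and filtered to
    [min_size, max_size].  For each set, ``n_perm`` random same-size gene
    sets give the null ES distribution; NES = ES / mean(|null ES| of the
    same sign); the FDR compares each observed |NES| against the pooled
    same-sign null NES distribution.  A fixed seed makes the whole table
    bit-reproducible.
    """
    vals = ranking.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("ranking contains missing values")
    if np.ptp(vals) == 0:
        raise ValidationError("degenerate ranking: all values equal")
    order = np.argsort(-vals, kind="stable")
    genes_sorted = ranking.index.to_numpy()[order]
    values_sorted = vals[order]
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    n = len(genes_sorted)
    coll = collection.restricted(set(gene_pos), min_size=min_size, max_size=max_size)
    rng = np.random.default_rng(seed)
    rows = []
    null_nes_by_term: list[np.ndarray] = []
    for name in sorted(coll.sets):
        hits = np.array(sorted(gene_pos[g] for g in set(coll.sets[name])))
        k = hits.size
        es = _es_from_positions(hits[None, :], values_sorted, weight)[0]
        perm_pos = rng.random((n_perm, n)).argpartition(k - 1, axis=1)[:, :k]
        es_null = _es_from_positions(perm_pos, values_sorted, weight)
        pos_null = es_null[es_null >= 0]
        neg_null = es_null[es_null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        if es >= 0:
            nes = es / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else np.nan
            p = (pos_null >= es).sum() / pos_null.size if pos_null.size else np.nan
        else:
            nes = es / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else np.nan
            p = (np.abs(neg_null) >= abs(es)).sum() / neg_null.size if neg_null.size else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null = np.where(
                es_null >= 0,
                es_null / mean_pos if np.isfinite(mean_pos) else np.nan,
                es_null / mean_neg if np.isfinite(mean_neg) else np.nan,
            )
        null_nes_by_term.append(nes_null[np.isfinite(nes_null)])
        rows.append({"term": name, "size": k, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows, columns=["term", "size", "es", "nes", "p"])
    if not len(out):
        out["fdr"] = []
        return out
    pooled = np.concatenate(null_nes_by_term) if null_nes_by_term else np.array([])
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]
    obs = out["nes"].to_numpy()
    fdr = np.full(len(out), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = (pooled_pos >= nes).mean() if pooled_pos.size else np.nan
            den = (obs[np.isfinite(obs) & (obs >= 0)] >= nes).mean()
        else:
            num = (pooled_neg <= nes).mean() if pooled_neg.size else np.nan
            den = (obs[np.isfinite(obs) & (obs < 0)] <= nes).mean()
        fdr[i] = min(num / den, 1.0) if den > 0 and np.isfinite(num) else np.nan
    out["fdr"] = fdr
    return out.sort_values("term").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Signature fold change (browser "Mode 2")
# ---------------------------------------------------------------------------


def _geometric_mean_signature(expr: pd.DataFrame, signature: Sequence[str]) -> pd.Series:
    present = [g for g in signature if g in expr.index]
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")
    sub = expr.loc[present].astype(float)
    if (sub.to_numpy() <= 0).any():
        offset = 1.0 - sub.to_numpy().min()
        logger.warning("non-positive expression: applying +%.3g offset", offset)
        sub = sub + offset
    return np.exp(np.log(sub).mean(axis=0))


def signature_fold_change(
    experiments: Mapping[str, tuple[pd.DataFrame, Mapping[str, str]]],
    signature: Sequence[str],
) -> pd.DataFrame:
    """Per-comparison fold change of a custom signature's geometric mean.

    ``experiments`` maps comparison id to (expression genes x samples,
    sample -> control/treated).  Per sample the signature value is the
    geometric mean of the signature genes; fold change is the ratio of
    treated to control group means; p is a two-sided Welch test on the log
    signature values, BH-adjusted across comparisons.
    """
    rows = []
    for cid, (expr, groups) in experiments.items():
        sig = _geometric_mean_signature(expr, signature)
        treated = [s for s in expr.columns if groups.get(s) == "treated"]
        control = [s for s in expr.columns if groups.get(s) == "control"]
        if not treated or not control:
            raise ValidationError(f"{cid}: need both control and treated samples")
        fc = sig[treated].mean() / sig[control].mean()
        if len(treated) > 1 and len(control) > 1:
            p = float(ttest_ind(np.log(sig[treated]), np.log(sig[control]), equal_var=False).pvalue)
            if np.isnan(p):  # zero variance in both groups
                p = 1.0 if np.isclose(fc, 1.0) else 0.0
        else:
            p = np.nan
        rows.append({"comparison_id": cid, "fold_change": float(fc), "p": p})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["padj"] = np.nan
    if mask.any():
        out.loc[mask, "padj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Single-sample signature score
# ---------------------------------------------------------------------------


def single_sample_score(
    expr: pd.DataFrame,
    gene_set: Iterable[str],
    min_genes: int = 5,
) -> pd.Series:
    """Rank-z single-sample score of a gene set (monotone GSVA stand-in).

    Within each sample, genes are rank-transformed (mid-ranks on ties) and
    standardised against the exact uniform-rank moments; the score is the
    mean standardised rank of the set genes.  Raising every set gene in a
    sample cannot decrease its score; a constant sample scores 0.
    """
    present = [g for g in set(gene_set) if g in expr.index]
    if len(present) < min_genes:
        raise ValidationError(
            f"only {len(present)} set gene(s) present, need >= {min_genes}"
        )
    n = expr.shape[0]
    ranks = expr.rank(axis=0, method="average")
    sd = np.sqrt((n**2 - 1) / 12.0)
    if sd == 0:
        return pd.Series(0.0, index=expr.columns, name="score")
    z = (ranks - (n + 1) / 2.0) / sd
    return z.loc[present].mean(axis=0).rename("score")


# ---------------------------------------------------------------------------
# Oncotype DX weighted impact
# ---------------------------------------------------------------------------

#: 21-gene recurrence-score panel groups restricted to the genes retained
#: after cross-comparison filtering (CTSL2 and GUSB excluded).
ONCOTYPE_GROUPS: dict[str, tuple[str, ...]] = {
    "HER2": ("GRB7", "ERBB2"),
    "ER": ("ESR1", "PGR", "BCL2", "SCUBE2"),
    "Proliferation": ("MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2"),
    "Invasion": ("MMP11",),
    "CD68": ("CD68",),
    "GSTM1": ("GSTM1",),
    "BAG1": ("BAG1",),
}

ONCOTYPE_COEFFICIENTS: dict[str, float] = {
    "HER2": 0.47,
    "ER": -0.34,
    "Proliferation": 1.04,
    "Invasion": 0.10,
    "CD68": 0.05,
    "GSTM1": -0.08,
    "BAG1": -0.07,
}


def oncotype_weighted_impact(
    percentiles: Mapping[str, float],
    groups: Mapping[str, Sequence[str]] = ONCOTYPE_GROUPS,
    coefficients: Mapping[str, float] = ONCOTYPE_COEFFICIENTS,
) -> float:
    """Weighted impact of regulatory percentiles on the recurrence score.

    Each gene group's mean regulatory percentile is combined with the
    published recurrence-score coefficients:
    0.47*HER2 - 0.34*ER + 1.04*Proliferation + 0.10*Invasion
    + 0.05*CD68 - 0.08*GSTM1 - 0.07*BAG1.
    """
    total = 0.0
    for group, genes in groups.items():
        values = [percentiles[g] for g in genes if g in percentiles]
        if not values:
            raise ValidationError(f"no percentile available for group {group!r}")
        total += coefficients[group] * float(np.mean(values))
    return total
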