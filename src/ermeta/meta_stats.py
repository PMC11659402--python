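"""Cross-comparison statistics on the regulatory-percentile matrix.

Heterogeneity, correlation structure, concordance/discordance calls,
bidirectional and consensus genes, ligand-dependence gating, a per-gene
mixed-effect regression on the comparison covariates, and percentile-profile
similarity search.

Consistency denominators throughout are the comparisons where the gene is
*non-missing* — platform gene-universe differences would otherwise penalise
array-absent genes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .harmonize import _scope_columns
from .ingest import ComparisonMeta, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCallSet",
    "MixedModelResult",
    "heterogeneity_cv",
    "compare_heterogeneity",
    "group_average_profiles",
    "pairwise_correlation",
    "concordance_quadrants",
    "discordance_genes",
    "bidirectional_genes",
    "consensus_targets",
    "ligand_dependence_gate",
    "fit_gene_mixed_model",
    "similar_genes",
    "intersect_sets",
]


@dataclass(frozen=True)
class GeneCallSet:
    """A named gene call with the thresholds that produced it."""

    label: str
    genes: frozenset[str]
    params: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class MixedModelResult:
    """Per-gene mixed-model fit: one coefficient and p-value per fixed term."""

    gene_id: str
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    converged: bool
    degenerate: bool = False
    dropped_terms: tuple[str, ...] = ()
    group_var: float = float("nan")


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------


def heterogeneity_cv(
    m: pd.DataFrame,
    scope: Sequence[str] | None = None,
    min_obs: int = 3,
) -> tuple[pd.Series, list[str]]:
    """Per-gene log10(CV^2) of regulatory percentiles across comparisons.

    CV = sample sd / |mean|.  Genes with zero mean or zero variance (or
    fewer than ``min_obs`` values) are excluded and returned separately.

    Returns
    -------
    (statistic, excluded):
        ``statistic`` — log10((sd/|mean|)^2) per retained gene;
        ``excluded`` — gene ids dropped as degenerate.
    """
    cols = _scope_columns(m, scope)
    if len(cols) < min_obs:
        raise ValidationError(f"scope has {len(cols)} comparisons, need >= {min_obs}")
    sub = m[cols]
    n = sub.notna().sum(axis=1)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    ok = (n >= min_obs) & (mean != 0) & (sd > 0)
    stat = np.log10((sd[ok] / mean[ok].abs()) ** 2).rename("log10_cv2")
    return stat, list(m.index[~ok])


def compare_heterogeneity(stat_a: pd.Series, stat_b: pd.Series) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing two heterogeneity distributions."""
    res = mannwhitneyu(stat_a.dropna(), stat_b.dropna(), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Correlation structure
# ---------------------------------------------------------------------------


def group_average_profiles(
    m: pd.DataFrame,
    metas: Mapping[str, ComparisonMeta],
    by: str = "compound",
) -> pd.DataFrame:
    """Average-percentile vector per group (compound, cell line, or comparison)."""
    if by == "comparison":
        return m.copy()
    groups: dict[str, list[str]] = {}
    for cid in m.columns:
        meta = metas.get(cid)
        if meta is None:
            raise ValidationError(f"no metadata for comparison {cid}")
        key = getattr(meta, "cell_line" if by == "cell_line" else "compound")
        if key is None:
            continue
        groups.setdefault(str(key), []).append(cid)
    return pd.DataFrame({g: m[cols].mean(axis=1) for g, cols in sorted(groups.items())})


def pairwise_correlation(
    profiles: pd.DataFrame,
    min_shared_genes: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between group profiles, with a clustering leaf order.

    Correlations use pairwise-complete genes.  Hierarchical clustering is
    average linkage on distance 1 - r; the returned leaf order is the
    dendrogram ordering used for heatmaps.
    """
    cols = list(profiles.columns)
    corr = profiles.corr(method="pearson", min_periods=min_shared_genes)
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().any().any():
        logger.warning("correlation matrix has missing cells (too few shared genes)")
    if len(cols) > 2:
        d = 1.0 - corr.fillna(0.0).to_numpy()
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        order = leaves_list(linkage(squareform(d, checks=False), method="average"))
        leaf_order = [cols[i] for i in order]
    else:
        leaf_order = cols
    return corr, leaf_order


# ---------------------------------------------------------------------------
# Concordance / discordance calls
# ---------------------------------------------------------------------------


def _shared(avg_x: pd.Series, avg_y: pd.Series) -> pd.DataFrame:
    df = pd.concat({"x": avg_x, "y": avg_y}, axis=1).dropna()
    return df


def concordance_quadrants(
    avg_x: pd.Series,
    avg_y: pd.Series,
    cut: float = 25.0,
) -> dict[str, GeneCallSet]:
    """Quadrant calls on two average-percentile vectors at +/-cut (inclusive)."""
    df = _shared(avg_x, avg_y)
    up_x, up_y = df["x"] >= cut, df["y"] >= cut
    dn_x, dn_y = df["x"] <= -cut, df["y"] <= -cut
    params = {"cut": cut}
    return {
        "up_up": GeneCallSet("up_up", frozenset(df.index[up_x & up_y]), params),
        "down_down": GeneCallSet("down_down", frozenset(df.index[dn_x & dn_y]), params),
        "up_down": GeneCallSet("up_down", frozenset(df.index[up_x & dn_y]), params),
        "down_up": GeneCallSet("down_up", frozenset(df.index[dn_x & up_y]), params),
    }


def discordance_genes(
    avg_a: pd.Series,
    avg_b: pd.Series,
    delta_cut: float = 70.0,
) -> tuple[GeneCallSet, GeneCallSet]:
    """Genes preferentially regulated in one condition: delta percentile > cut (strict)."""
    if delta_cut <= 0:
        raise ValueError("delta_cut must be positive")
    df = _shared(avg_a, avg_b)
    delta = df["x"] - df["y"]
    params = {"delta_cut": delta_cut}
    a_pref = GeneCallSet("a_preferential", frozenset(df.index[delta > delta_cut]), params)
    b_pref = GeneCallSet("b_preferential", frozenset(df.index[-delta > delta_cut]), params)
    return a_pref, b_pref


# ---------------------------------------------------------------------------
# Bidirectional and consensus genes
# ---------------------------------------------------------------------------


def _direction_fractions(
    m: pd.DataFrame,
    cols: list[str],
    top_frac: float,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Fractions of non-missing scoped comparisons in the top up/down decile."""
    sub = m[cols]
    thresh = 100.0 * (1.0 - top_frac)
    n = sub.notna().sum(axis=1)
    f_up = (sub >= thresh - 1e-9).sum(axis=1) / n
    f_down = (sub <= -thresh + 1e-9).sum(axis=1) / n
    return f_up, f_down, n


def bidirectional_genes(
    m: pd.DataFrame,
    scope: Sequence[str] | None = None,
    top_frac: float = 0.10,
    min_frac: float = 0.15,
) -> GeneCallSet:
    """Genes in the top decile of up-regulation in some comparisons and of
    down-regulation in others, each in at least ``min_frac`` of comparisons.

    Boundaries are inclusive ("at least").  The denominator counts only
    comparisons where the gene is observed.
    """
    cols = _scope_columns(m, scope)
    if len(cols) < 5:
        raise ValidationError(f"scope has {len(cols)} comparisons, need >= 5")
    f_up, f_down, n = _direction_fractions(m, cols, top_frac)
    called = (f_up >= min_frac - 1e-12) & (f_down >= min_frac - 1e-12) & (n > 0)
    return GeneCallSet(
        "bidirectional",
        frozenset(m.index[called]),
        {"top_frac": top_frac, "min_frac": min_frac, "n_comparisons": len(cols)},
    )


def consensus_targets(
    m: pd.DataFrame,
    scope: Sequence[str] | None = None,
    direction: str = "up",
    top_frac: float = 0.10,
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Consensus targets: genes in the top regulated decile in at least
    ``min_frac`` of comparisons, ranked by that consistency fraction.

    Ties in consistency are broken by average percentile (more extreme in
    the called direction first).

    Returns
    -------
    DataFrame with columns ``consistency`` (fraction of non-missing
    comparisons in the top decile), ``avg_pct``, ``n_obs``; one row per
    called gene, in rank order.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    cols = _scope_columns(m, scope)
    if not cols:
        raise ValidationError("empty scope")
    f_up, f_down, n = _direction_fractions(m, cols, top_frac)
    frac = f_up if direction == "up" else f_down
    avg = m[cols].mean(axis=1)
    called = (frac >= min_frac - 1e-12) & (n > 0)
    out = pd.DataFrame(
        {"consistency": frac[called], "avg_pct": avg[called], "n_obs": n[called]}
    )
    sort_avg = out["avg_pct"] if direction == "up" else -out["avg_pct"]
    out = out.assign(_tie=sort_avg).sort_values(
        ["consistency", "_tie"], ascending=[False, False]
    )
    return out.drop(columns="_tie")


def ligand_dependence_gate(
    avg_model: pd.Series,
    avg_e2: pd.Series,
    high_cut: float = 50.0,
    null_band: float = 15.0,
) -> dict[str, GeneCallSet]:
    """Classify genes by ligand dependence of their regulation.

    Ligand-independent up/down: average percentile beyond +/-``high_cut``
    in both the constitutive model and the E2-treated condition.  De novo:
    activated in the model (> ``high_cut``) while essentially unregulated
    by E2 (within +/-``null_band``).
    """
    if high_cut <= null_band:
        raise ValueError("high_cut must exceed null_band")
    df = _shared(avg_model, avg_e2)
    model, e2 = df["x"], df["y"]
    params = {"high_cut": high_cut, "null_band": null_band}
    return {
        "ligand_independent_up": GeneCallSet(
            "ligand_independent_up",
            frozenset(df.index[(model > high_cut) & (e2 > high_cut)]),
            params,
        ),
        "ligand_independent_down": GeneCallSet(
            "ligand_independent_down",
            frozenset(df.index[(model < -high_cut) & (e2 < -high_cut)]),
            params,
        ),
        "de_novo": GeneCallSet(
            "de_novo",
            frozenset(df.index[(model > high_cut) & (e2.abs() <= null_band)]),
            params,
        ),
    }


# ---------------------------------------------------------------------------
# Per-gene mixed-effect regression
# ---------------------------------------------------------------------------


def _design_frame(
    y: pd.Series, metas: Mapping[str, ComparisonMeta]
) -> pd.DataFrame:
    rows = []
    for cid, pct in y.dropna().items():
        meta = metas.get(cid)
        if meta is None:
            raise ValidationError(f"no metadata for comparison {cid}")
        rows.append(
            {
                "pct": float(pct),
                "cell_line": meta.cell_line,
                "modality": meta.modality,
                "drug_type": meta.compound_class,
                "duration": meta.duration_h,
                "batch_id": meta.batch_id,
            }
        )
    return pd.DataFrame(rows)


def fit_gene_mixed_model(
    y: pd.Series,
    metas: Mapping[str, ComparisonMeta],
    gene_id: str = "",
) -> MixedModelResult:
    """Mixed-effect regression of one gene's percentile on comparison covariates.

    Fixed effects: cell line, modality (sequencing technique), drug type,
    treatment duration (hours, continuous) and the drug x duration
    interaction; random intercept per batch.  Duration is mean-centered so
    the drug-type main effect is the effect at the average duration rather
    than an extrapolation to 0 h.  Categorical terms left with a single
    level are dropped with a warning.  Non-convergence and singular designs
    are flagged on the result, never raised.
    """
    df = _design_frame(y, metas)
    if len(df) < 10:
        raise ValidationError(f"gene {gene_id}: {len(df)} observations, need >= 10")
    if df["duration"].notna().all():
        df["duration"] = df["duration"] - df["duration"].mean()
    if df["pct"].nunique() <= 1:
        return MixedModelResult(gene_id, {}, {}, converged=False, degenerate=True)
    dropped = []
    terms = []
    for cat in ("cell_line", "modality", "drug_type"):
        if df[cat].nunique() >= 2:
            terms.append(f"C({cat})" if cat != "drug_type" else "C(drug_type)")
        else:
            dropped.append(cat)
            logger.warning("gene %s: term %s has one level, dropped", gene_id, cat)
    has_duration = df["duration"].notna().all() and df["duration"].nunique() >= 2
    if has_duration:
        if "C(drug_type)" in terms:
            terms.append("C(drug_type) * duration")
            terms.remove("C(drug_type)")
        else:
            terms.append("duration")
    elif "duration" not in dropped:
        dropped.append("duration")
    if not terms:
        return MixedModelResult(
            gene_id, {}, {}, converged=False, degenerate=True, dropped_terms=tuple(dropped)
        )
    formula = "pct ~ " + " + ".join(terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["batch_id"])
            try:
                fit = model.fit(reml=True, maxiter=200)
            except np.linalg.LinAlgError:
                fit = model.fit(reml=True, method="powell", maxiter=500)
        coefs = {k: float(v) for k, v in fit.fe_params.items()}
        pvals = {k: float(fit.pvalues[k]) for k in fit.fe_params.index}
        converged = bool(getattr(fit, "converged", True))
        group_var = float(np.atleast_2d(fit.cov_re)[0, 0]) if fit.cov_re is not None else np.nan
        return MixedModelResult(
            gene_id,
            coefs,
            pvals,
            converged=converged,
            dropped_terms=tuple(dropped),
            group_var=group_var,
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("gene %s: mixed model failed (%s)", gene_id, exc)
        return MixedModelResult(
            gene_id, {}, {}, converged=False, degenerate=True, dropped_terms=tuple(dropped)
        )


def fit_all_mixed_models(
    m: pd.DataFrame,
    metas: Mapping[str, ComparisonMeta],
    genes: Sequence[str] | None = None,
    adjust_term: str | None = None,
) -> pd.DataFrame:
    """Fit the per-gene mixed model across genes; optional BH adjustment of one term.

    Returns a long DataFrame (gene_id, term, coefficient, p, converged) with
    a ``padj`` column for ``adjust_term`` if requested.
    """
    rows = []
    for g in genes if genes is not None else m.index:
        res = fit_gene_mixed_model(m.loc[g], metas, gene_id=str(g))
        for term, coef in res.coefficients.items():
            rows.append(
                {
                    "gene_id": res.gene_id,
                    "term": term,
                    "coefficient": coef,
                    "p": res.pvalues.get(term, np.nan),
                    "converged": res.converged,
                }
            )
        if not res.coefficients:
            rows.append(
                {"gene_id": res.gene_id, "term": None, "coefficient": np.nan,
                 "p": np.nan, "converged": res.converged}
            )
    out = pd.DataFrame(rows)
    if adjust_term is not None and len(out):
        mask = (out["term"] == adjust_term) & out["p"].notna()
        out["padj"] = np.nan
        if mask.any():
            out.loc[mask, "padj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Similarity search
# ---------------------------------------------------------------------------


def similar_genes(
    m: pd.DataFrame,
    query_gene: str,
    scope: Sequence[str] | None = None,
    r_cut: float | None = None,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Rank all other genes by Pearson correlation of their percentile profile
    with the query gene's, with a BH-adjusted two-sided correlation test.
    """
    cols = _scope_columns(m, scope)
    if query_gene not in m.index:
        raise ValidationError(f"query gene {query_gene!r} not in matrix")
    q = m.loc[query_gene, cols].astype(float)
    if q.notna().sum() < min_obs:
        raise ValidationError(f"query gene has < {min_obs} non-missing values")
    sub = m.loc[m.index != query_gene, cols].astype(float)
    qv = q.to_numpy()
    x = sub.to_numpy()
    both = np.isfinite(x) & np.isfinite(qv)[None, :]
    n = both.sum(axis=1).astype(float)
    xq = np.where(both, x * qv[None, :], 0.0)
    sx = np.where(both, x, 0.0).sum(axis=1)
    sq = np.where(both, qv[None, :], 0.0).sum(axis=1)
    sxx = np.where(both, x * x, 0.0).sum(axis=1)
    sqq = np.where(both, qv[None, :] ** 2, 0.0).sum(axis=1)
    sxq = xq.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxq - sx * sq / n
        var_x = sxx - sx**2 / n
        var_q = sqq - sq**2 / n
        r = cov / np.sqrt(var_x * var_q)
        r = np.clip(r, -1.0, 1.0)
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * t_dist.sf(np.abs(tstat), np.maximum(n - 2, 1))
    out = pd.DataFrame({"r": r, "p": p, "n_obs": n.astype(int)}, index=sub.index)
    out = out[(out["n_obs"] >= min_obs) & out["r"].notna()]
    out["padj"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    out = out.sort_values("r", ascending=False)
    if r_cut is not None:
        out = out[out["r"] >= r_cut]
    return out


# ---------------------------------------------------------------------------
# Set intersections
# ---------------------------------------------------------------------------


def intersect_sets(sets: Mapping[str, Iterable[str]]) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Exact region counts for a family of named sets (Venn-style).

    Returns
    -------
    (membership, regions):
        ``membership`` — boolean genes x sets table, genes sorted;
        ``regions`` — for every non-empty combination of set names (as a
        sorted tuple), the number of elements in exactly those sets.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 sets")
    names = list(sets)
    as_sets = {k: set(v) for k, v in sets.items()}
    universe = sorted(set().union(*as_sets.values()))
    membership = pd.DataFrame(
        {k: [g in as_sets[k] for g in universe] for k in names},
        index=pd.Index(universe, name="gene_id"),
    )
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = membership[list(combo)].all(axis=1)
            outside = ~membership[[k for k in names if k not in combo]].any(axis=1) \
                if len(combo) < len(names) else pd.Series(True, index=membership.index)
            regions[tuple(sorted(combo))] = int((inside & outside).sum())
    return membership, regions
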