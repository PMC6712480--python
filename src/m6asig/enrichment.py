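"""Differential expression, Venn overlaps, and gene set enrichment (GSEA).

The enrichment engine is the classic two-class, phenotype-permutation GSEA:
genes are ranked by signal-to-noise ratio between the high and low groups,
a weighted Kolmogorov-Smirnov running sum gives the enrichment score (ES),
and label permutations provide the null for the normalized score (NES),
nominal P, and the signed-pool FDR q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .cohort_io import ExpressionMatrix, GeneSetCollection

SD_FLOOR_FRAC = 0.2  # signal-to-noise SD floor, as a fraction of |mean|


def diff_expr(expr: ExpressionMatrix, labels, threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test, high vs low group.

    ``labels`` is boolean-like over samples (True = high). Genes constant in
    both groups get NaN statistics and ``degenerate=True`` instead of a
    crash. Returns columns: mean_diff, t, p_value, deg, degenerate.
    """
    lab = np.asarray(labels, dtype=bool)
    x = expr.values.to_numpy(dtype=float)
    hi, lo = x[:, lab], x[:, ~lab]
    if hi.shape[1] < 2 or lo.shape[1] < 2:
        raise ValidationError("each group needs >=2 samples")
    n1, n0 = hi.shape[1], lo.shape[1]
    m1, m0 = hi.mean(axis=1), lo.mean(axis=1)
    v1 = hi.var(axis=1, ddof=1)
    v0 = lo.var(axis=1, ddof=1)
    se2 = v1 / n1 + v0 / n0
    degen = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
    t[degen] = np.nan
    p[degen] = np.nan
    out = pd.DataFrame({
        "mean_diff": m1 - m0, "t": t, "p_value": p,
        "deg": (p < threshold) & ~degen, "degenerate": degen,
    }, index=expr.genes)
    return out


def venn_counts(set_w, set_r, set_e) -> dict[str, int]:
    """Counts of the seven intersection regions of three gene sets."""
    w, r, e = set(set_w), set(set_r), set(set_e)
    return {
        "W_only": len(w - r - e),
        "R_only": len(r - w - e),
        "E_only": len(e - w - r),
        "WR": len((w & r) - e),
        "WE": len((w & e) - r),
        "RE": len((r & e) - w),
        "WRE": len(w & r & e),
    }


def _signal_to_noise(x: np.ndarray, lab: np.ndarray) -> np.ndarray:
    hi, lo = x[:, lab], x[:, ~lab]
    m1, m0 = hi.mean(axis=1), lo.mean(axis=1)
    s1 = hi.std(axis=1, ddof=1)
    s0 = lo.std(axis=1, ddof=1)
    # SD floor of the original GSEA convention, absolute floor when mean = 0
    f1 = np.maximum(SD_FLOOR_FRAC * np.abs(m1), SD_FLOOR_FRAC * (m1 == 0))
    f0 = np.maximum(SD_FLOOR_FRAC * np.abs(m0), SD_FLOOR_FRAC * (m0 == 0))
    return (m1 - m0) / (np.maximum(s1, f1) + np.maximum(s0, f0))


def _t_metric(x: np.ndarray, lab: np.ndarray) -> np.ndarray:
    hi, lo = x[:, lab], x[:, ~lab]
    n1, n0 = hi.shape[1], lo.shape[1]
    se2 = hi.var(axis=1, ddof=1) / n1 + lo.var(axis=1, ddof=1) / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (hi.mean(axis=1) - lo.mean(axis=1)) / np.sqrt(se2)
    return np.where(np.isfinite(t), t, 0.0)


_METRICS = {"s2n": _signal_to_noise, "t": _t_metric}


def rank_genes(expr: ExpressionMatrix, labels, metric: str = "s2n") -> pd.Series:
    """Genes sorted descending by the ranking metric (high vs low group).

    Ties are broken lexicographically by gene symbol, making the ranking
    deterministic.
    """
    lab = np.asarray(labels, dtype=bool)
    if lab.sum() < 3 or (~lab).sum() < 3:
        raise ValidationError("each group needs >=3 samples for ranking")
    if metric not in _METRICS:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    scores = _METRICS[metric](expr.values.to_numpy(dtype=float), lab)
    s = pd.Series(scores, index=expr.genes, name=metric)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and its running-sum profile.

    Hit steps increment proportionally to |score|^weight (normalized over
    the set's hits); miss steps decrement uniformly. ES is the running-sum
    value of maximum magnitude.
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(set(gene_set)))
    n_hit = int(hit.sum())
    n = genes.size
    if n_hit == 0:
        raise ValidationError("gene set has empty intersection with the ranking")
    w = np.abs(scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all hit scores exactly zero: fall back to equal steps
        w_hit = hit.astype(float)
        total = float(n_hit)
    steps = w_hit / total
    if n_hit < n:
        steps = steps - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _leading_edge(ranked: pd.Series, gene_set, running: np.ndarray,
                  es: float) -> list[str]:
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, list(set(gene_set)))
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        sel = hit[: peak + 1]
        return list(genes[: peak + 1][sel])
    sel = hit[peak:]
    return list(genes[peak:][sel])


@dataclass
class EnrichmentResult:
    """GSEA summary for one gene set."""

    name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0


def gsea(
    expr: ExpressionMatrix,
    labels,
    gene_sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "s2n",
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA over a gene-set collection.

    Group labels are permuted ``n_perm`` times; the ranking and every set's
    ES are recomputed per permutation. NES divides each ES by the mean
    magnitude of same-sign permuted ES of its own set; nominal P is the
    fraction of same-sign permuted ES at least as extreme; FDR q pools
    signed NES over all sets and permutations (the original convention).
    Fully reproducible given ``seed``.
    """
    lab = np.asarray(labels, dtype=bool)
    if lab.sum() < 3 or (~lab).sum() < 3:
        raise ValidationError("each group needs >=3 samples to permute")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    ranked = rank_genes(expr, lab, metric=metric)
    names = list(gene_sets.sets)
    obs_es = {}
    obs_lead = {}
    for name in names:
        es, running = enrichment_score(ranked, gene_sets[name], weight)
        obs_es[name] = es
        obs_lead[name] = _leading_edge(ranked, gene_sets[name], running, es)

    rng = np.random.default_rng(seed)
    x = expr.values.to_numpy(dtype=float)
    gene_arr = np.array(expr.genes)
    hit_masks = {n_: np.isin(gene_arr, list(set(gene_sets[n_]))) for n_ in names}
    perm_es = np.empty((n_perm, len(names)))
    metric_fn = _METRICS[metric]
    for j in range(n_perm):
        plab = rng.permutation(lab)
        scores = metric_fn(x, plab)
        order = np.lexsort((gene_arr, -scores))
        s_sorted = scores[order]
        w = np.abs(s_sorted) ** weight
        for i, name in enumerate(names):
            hit = hit_masks[name][order]
            n_hit = hit.sum()
            w_hit = np.where(hit, w, 0.0)
            total = w_hit.sum()
            if total == 0:
                w_hit = hit.astype(float)
                total = float(n_hit)
            steps = w_hit / total
            if n_hit < gene_arr.size:
                steps = steps - (~hit) / (gene_arr.size - n_hit)
            running = np.cumsum(steps)
            perm_es[j, i] = running[np.argmax(np.abs(running))]

    # per-set normalization by same-sign permuted ES magnitude
    nes = np.empty(len(names))
    nominal_p = np.empty(len(names))
    perm_nes = np.full_like(perm_es, np.nan)
    for i, name in enumerate(names):
        es = obs_es[name]
        col = perm_es[:, i]
        pos, neg = col[col >= 0], col[col < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        perm_nes[:, i] = np.where(col >= 0,
                                  col / mean_pos if pos.size else np.nan,
                                  col / mean_neg if neg.size else np.nan)
        if es >= 0:
            denom = mean_pos
            same = pos
            hits = (pos >= es).sum()
        else:
            denom = mean_neg
            same = neg
            hits = (neg <= es).sum()
        nes[i] = es / denom if np.isfinite(denom) and denom > 0 else 0.0
        nominal_p[i] = (hits + 1) / (same.size + 1) if same.size else 1.0

    fdr = _fdr_signed_pool(nes, perm_nes)
    return [
        EnrichmentResult(
            name=name, size=int(hit_masks[name].sum()), es=obs_es[name],
            nes=float(nes[i]), nominal_p=float(nominal_p[i]),
            fdr_q=float(fdr[i]), leading_edge=obs_lead[name], n_perm=n_perm,
        )
        for i, name in enumerate(names)
    ]


def _fdr_signed_pool(nes: np.ndarray, perm_nes: np.ndarray) -> np.ndarray:
    """FDR q by pooling signed NES over all sets and permutations."""
    pool = perm_nes[np.isfinite(perm_nes)]
    q = np.ones_like(nes)
    for i, v in enumerate(nes):
        if v >= 0:
            null_frac = (pool >= v).mean() / max((pool >= 0).mean(), 1e-12)
            obs_frac = (nes >= v).mean() / max((nes >= 0).mean(), 1e-12)
        else:
            null_frac = (pool <= v).mean() / max((pool < 0).mean(), 1e-12)
            obs_frac = (nes <= v).mean() / max((nes < 0).mean(), 1e-12)
        q[i] = min(1.0, null_frac / max(obs_frac, 1e-12))
    return q


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set": r.name, "size": r.size, "es": r.es, "nes": r.nes,
        "nominal_p": r.nominal_p, "fdr_q": r.fdr_q,
        "leading_edge": ",".join(r.leading_edge), "n_perm": r.n_perm,
    } for r in results])
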