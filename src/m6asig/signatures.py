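"""Writer/reader/eraser (W/R/E) signature computation and correlations.

Each signature is the geometric mean of its regulator group's expression:
W over METTL3/METTL14, R over YTHDF1/YTHDF2/YTHDF3, E over ALKBH5/FTO.
Geometric means are evaluated in log space; when the matrix contains zeros
a pseudocount of half the smallest positive value is added so that the
result stays strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .cohort_io import ERASER_GENES, READER_GENES, WRITER_GENES, ExpressionMatrix


def _pseudocount(expr: ExpressionMatrix) -> float:
    arr = expr.values.to_numpy(dtype=float)
    if (arr > 0).all():
        return 0.0
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValidationError(
            "expression matrix is all zero; geometric signatures undefined"
        )
    return float(pos.min()) / 2.0


def geometric_signature(
    expr: ExpressionMatrix,
    genes: list[str],
    pseudocount: float | str = "auto",
) -> pd.Series:
    """Per-sample geometric mean of ``genes``.

    ``pseudocount="auto"`` uses 0 when every matrix value is positive, and
    half the smallest positive value otherwise. An all-zero gene row with an
    explicit zero pseudocount is rejected rather than returning 0.
    """
    sub = expr.subset_genes(genes).to_numpy(dtype=float)
    eps = _pseudocount(expr) if pseudocount == "auto" else float(pseudocount)
    if eps == 0.0 and (sub == 0).any():
        zero_gene = [g for g in genes if (expr.subset_genes([g]).to_numpy() == 0).any()]
        raise ValidationError(
            f"gene(s) {zero_gene} contain zeros; a positive pseudocount is "
            "required for the geometric mean (use pseudocount='auto')"
        )
    vals = np.exp(np.mean(np.log(sub + eps), axis=0))
    return pd.Series(vals, index=expr.samples, name="signature")


@dataclass
class SignatureTable:
    """Per-sample W/R/E signature values (strictly positive)."""

    data: pd.DataFrame  # index = samples, columns = W, R, E

    def __post_init__(self) -> None:
        arr = self.data[["W", "R", "E"]].to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise ValidationError("signatures must be strictly positive and finite")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def __getitem__(self, key: str) -> pd.Series:
        return self.data[key]


def compute_wre(
    expr: ExpressionMatrix,
    pseudocount: float | str = "auto",
    log_transform: bool = False,
) -> SignatureTable:
    """W/R/E signatures for every sample of ``expr``.

    ``log_transform=True`` applies log2(x+1) to the matrix before averaging
    (geometric mean of log-scale quantities); the default is the raw-scale
    geometric mean.
    """
    if log_transform:
        expr = ExpressionMatrix(np.log2(expr.values + 1.0) + 1e-9)
    groups = {"W": WRITER_GENES, "R": READER_GENES, "E": ERASER_GENES}
    cols = {
        name: geometric_signature(expr, list(genes), pseudocount)
        for name, genes in groups.items()
    }
    return SignatureTable(pd.DataFrame(cols))


@dataclass
class CorrelationReport:
    """A pairwise correlation with its two-sided P value."""

    pair: str
    method: str
    coefficient: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance in an input


def correlate(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    method: str = "pearson",
    pair: str = "",
) -> CorrelationReport:
    """Pearson or Spearman correlation with a two-sided t-approximation P.

    Missing (NaN) pairs are dropped; >=3 complete pairs are required. A
    zero-variance input yields a flagged (degenerate) report rather than a
    NaN crash.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("correlation requires >=3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport(pair, method, float("nan"), float("nan"),
                                 int(x.size), degenerate=True)
    if method.lower() == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method.lower() == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationReport(pair, method, float(r), float(p), int(x.size))


def signature_correlations(
    sig: SignatureTable, method: str = "pearson"
) -> pd.DataFrame:
    """All pairwise W/R/E correlations as a tidy table."""
    rows = []
    names = ["W", "R", "E"]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rep = correlate(sig[a], sig[b], method=method, pair=f"{a}-{b}")
            rows.append({
                "pair": rep.pair, "method": rep.method,
                "coefficient": rep.coefficient, "p_value": rep.p_value,
                "n": rep.n,
            })
    return pd.DataFrame(rows)
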