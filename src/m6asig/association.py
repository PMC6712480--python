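"""Mutation-frequency and clinical-index associations with m6A indications.

Low- vs high-m6A-indication groups are compared per stratification scheme:
smoothed mutation-frequency fold changes with cross-cohort UP/DN consensus
calls, contingency tests on clinical indexes (Fisher exact for 2x2,
chi-square otherwise, with an optional margin-fixed Monte-Carlo exact test
for sparse tables), and Welch t comparisons for continuous markers such as
tumor mutational burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .cohort_io import MISSING, ClinicalTable, MutationTable
from .stratification import SCHEMES, StrataAssignment

#: smoothing constant for mutation-frequency fold changes
FC_ALPHA = 0.5


def filter_genes_by_frequency(
    mut_a: MutationTable, mut_b: MutationTable, threshold: float = 0.01
) -> list[str]:
    """Genes with mutated-sample fraction strictly above ``threshold`` in
    BOTH cohorts, sorted lexicographically."""
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must be in [0, 1)")
    out = []
    freq_a = mut_a.binary_matrix.mean(axis=0)
    freq_b = mut_b.binary_matrix.mean(axis=0)
    for gene in sorted(set(freq_a.index) & set(freq_b.index)):
        if freq_a[gene] > threshold and freq_b[gene] > threshold:
            out.append(gene)
    return out


def _indication_groups(assignment: StrataAssignment) -> tuple[list[str], list[str]]:
    low = assignment.indication_samples("low")
    high = assignment.indication_samples("high")
    if not low or not high:
        raise ValidationError(
            f"scheme {assignment.scheme}: empty low or high indication group"
        )
    return low, high


def foldchange_low_vs_high(
    mut: MutationTable,
    assignments: dict[str, StrataAssignment],
    genes: list[str] | None = None,
    alpha: float = FC_ALPHA,
) -> pd.DataFrame:
    """Smoothed mutation-frequency fold change (low / high indication) per
    gene and stratification scheme.

    FC = ((m_low + a)/(n_low + 2a)) / ((m_high + a)/(n_high + 2a)); samples
    with intermediate indication are excluded from both groups.
    """
    binmat = mut.binary_matrix
    if genes is None:
        genes = list(binmat.columns)
    cols = {}
    for scheme in SCHEMES:
        if scheme not in assignments:
            continue
        low, high = _indication_groups(assignments[scheme])
        m_low = binmat.loc[low, genes].sum(axis=0)
        m_high = binmat.loc[high, genes].sum(axis=0)
        f_low = (m_low + alpha) / (len(low) + 2 * alpha)
        f_high = (m_high + alpha) / (len(high) + 2 * alpha)
        cols[scheme] = f_low / f_high
    return pd.DataFrame(cols, index=genes)


def cross_cohort_intersect(
    fc_a: pd.DataFrame, fc_b: pd.DataFrame, consensus_frac: float = 4 / 7
) -> pd.DataFrame:
    """Per-gene, per-scheme UP/DN/discordant calls across two cohorts.

    UP iff FC > 1 in both cohorts, DN iff FC < 1 in both, else discordant.
    The consensus call is UP (DN) when at least ``consensus_frac`` of the
    shared schemes are UP (DN).
    """
    shared_genes = sorted(set(fc_a.index) & set(fc_b.index))
    if not shared_genes:
        raise ValidationError("cohorts share no genes")
    shared_schemes = [s for s in SCHEMES if s in fc_a.columns and s in fc_b.columns]
    a = fc_a.loc[shared_genes, shared_schemes]
    b = fc_b.loc[shared_genes, shared_schemes]
    calls = pd.DataFrame("discordant", index=shared_genes, columns=shared_schemes)
    calls = calls.mask((a > 1) & (b > 1), "UP").mask((a < 1) & (b < 1), "DN")
    need = consensus_frac * len(shared_schemes)
    n_up = (calls == "UP").sum(axis=1)
    n_dn = (calls == "DN").sum(axis=1)
    consensus = pd.Series("discordant", index=shared_genes)
    consensus[n_up >= need] = "UP"
    consensus[n_dn >= need] = "DN"
    calls["consensus"] = consensus
    return calls


def variant_frequency(
    mut: MutationTable, gene: str, protein_change: str,
    assignment: StrataAssignment,
) -> pd.DataFrame:
    """Fraction of samples carrying the exact variant per indication group."""
    if not protein_change:
        raise ValidationError("protein_change must be non-empty")
    carriers = set(mut.variant_carriers(gene, protein_change))
    ind = assignment.indication()
    rows = []
    for which in ("low", "high"):
        members = [s for s in ind.index[ind == which]]
        n_car = sum(1 for s in members if s in carriers)
        rows.append({
            "indication": which, "n": len(members), "n_carrier": n_car,
            "frequency": n_car / len(members) if members else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency tests


@dataclass
class ContingencyResult:
    variable: str
    table: np.ndarray
    test: str                     # fisher_2x2 | chi_square | exact_mc
    statistic: float | None
    p_value: float
    low_expected: bool = False    # chi-square: some expected count < 5


def _check_margins(table: np.ndarray) -> None:
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValidationError("contingency table must hold nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("contingency test undefined: zero row/column margin")


def fisher_exact_2x2(table, variable: str = "") -> ContingencyResult:
    """Two-sided Fisher exact test (sum of point probabilities <= observed)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2x2 table")
    _check_margins(t)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return ContingencyResult(variable, t, "fisher_2x2", float(odds), float(p))


def chi_square(table, variable: str = "") -> ContingencyResult:
    """Pearson chi-square without continuity correction."""
    t = np.asarray(table, dtype=int)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("chi-square requires an r x c table with r,c >= 2")
    _check_margins(t)
    res = stats.chi2_contingency(t, correction=False)
    return ContingencyResult(variable, t, "chi_square", float(res.statistic),
                             float(res.pvalue),
                             low_expected=bool((res.expected_freq < 5).any()))


def _log_table_prob(t: np.ndarray) -> float:
    """Log probability of an r x c table under fixed margins."""
    from scipy.special import gammaln

    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(t + 1).sum()
    )


def exact_mc(table, n_draws: int = 10000, seed: int = 0,
             variable: str = "") -> ContingencyResult:
    """Monte-Carlo exact test: fraction of margin-preserving tables with
    point probability <= the observed one (with +1 continuity)."""
    t = np.asarray(table, dtype=int)
    _check_margins(t)
    if n_draws < 1000:
        raise ValidationError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(t.sum(axis=1), t.sum(axis=0))
    draws = sampler.rvs(size=n_draws, random_state=rng).astype(int)
    obs_lp = _log_table_prob(t)
    draw_lp = np.array([_log_table_prob(d) for d in draws])
    hits = int((draw_lp <= obs_lp + 1e-9).sum())
    p = (hits + 1) / (n_draws + 1)
    return ContingencyResult(variable, t, "exact_mc", None, float(p))


# ---------------------------------------------------------------------------
# clinical-index associations

#: categorical variables tested between indication groups, in table order
CLINICAL_VARIABLES = ("gender", "age", "lauren", "t_stage", "n_stage",
                      "m_stage", "stage", "msi", "ebv")

AGE_CUT = 60.0  # years; dichotomized as <=60 vs >60


def _observed_table(clinical: ClinicalTable, variable: str,
                    low: list[str], high: list[str]) -> tuple[np.ndarray, list[str]]:
    d = clinical.data
    if variable == "age":
        col = d["age_years"]
        values = col.map(
            lambda a: MISSING if pd.isna(a) else ("<=60" if a <= AGE_CUT else ">60"))
        categories = ["<=60", ">60"]
    else:
        if variable not in d.columns:
            raise ValidationError(f"variable {variable!r} absent from clinical table")
        values = d[variable].astype(str)
        categories = [c for c in values.unique() if c != MISSING]
        categories = sorted(categories)
    rows = []
    kept = []
    for cat in categories:
        n_low = int((values.loc[low] == cat).sum())
        n_high = int((values.loc[high] == cat).sum())
        if n_low + n_high > 0:
            rows.append([n_low, n_high])
            kept.append(cat)
    table = np.asarray(rows, dtype=int)
    if table.size == 0 or (values.loc[low] == MISSING).all() or \
            (values.loc[high] == MISSING).all():
        raise ValidationError(
            f"variable {variable!r}: all values missing in an indication group")
    return table, kept


def clinical_association(
    clinical: ClinicalTable,
    assignment: StrataAssignment,
    variables: tuple[str, ...] = CLINICAL_VARIABLES,
    use_exact_mc: bool = False,
    mc_seed: int = 0,
    overrides: dict[str, str] | None = None,
) -> list[ContingencyResult]:
    """Contingency tests of clinical indexes between the low- and high-m6A
    indication groups of one stratification scheme.

    Missing (``n/a``) values are excluded per variable, not per sample. The
    default dispatch is Fisher exact for 2x2 tables and chi-square for
    larger ones; ``use_exact_mc`` switches sparse larger tables (an expected
    count below 5) to the margin-fixed Monte-Carlo exact test. ``overrides``
    maps a variable name to an explicit test name.
    """
    low, high = _indication_groups(assignment)
    overrides = overrides or {}
    results = []
    for var in variables:
        table, _cats = _observed_table(clinical, var, low, high)
        choice = overrides.get(var)
        if choice is None:
            choice = "fisher_2x2" if table.shape == (2, 2) else "chi_square"
        if choice == "fisher_2x2":
            res = fisher_exact_2x2(table, var)
        elif choice == "chi_square":
            res = chi_square(table, var)
            if res.low_expected and use_exact_mc:
                res = exact_mc(table, seed=mc_seed, variable=var)
        elif choice == "exact_mc":
            res = exact_mc(table, seed=mc_seed, variable=var)
        else:
            raise ValidationError(f"unknown test {choice!r} for variable {var!r}")
        results.append(res)
    return results


def group_mean_compare(values, labels) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between binary groups.

    ``labels`` is boolean-like (True = first group); returns (t, P).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    a = v[lab & np.isfinite(v)]
    b = v[~lab & np.isfinite(v)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >=2 non-missing values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
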