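"""Median dichotomization and the single/double/triple stratification taxonomy.

Seven schemes are defined over the W/R/E signatures:

* single — ``W``, ``R``, ``E``: low/high at the per-cohort median;
* double — ``WE``, ``RE``, ``WR``: the 2x2 cross-classification of two
  single splits (labels like ``W^L E^H``);
* triple — ``WRE``: six groups keyed by how many of W and R are high
  (``dL`` double-low, ``sH`` single-high, ``dH`` double-high) crossed with
  the E level (labels like ``WR^dH E^L``).

Each stratum carries an m6A *indication*: strata expected to have low m6A
(low writers/readers or high erasers) are ``low``, the opposite corner is
``high``, every other composite is ``intermediate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError

SCHEMES = ("W", "R", "E", "WE", "RE", "WR", "WRE")

#: strata the analysis treats as indicating low m6A modification
LOW_INDICATION = frozenset({
    "W^L", "R^L", "E^H",
    "W^L E^H", "R^L E^H", "W^L R^L",
    "WR^dL E^H",
})

#: strata indicating high m6A modification
HIGH_INDICATION = frozenset({
    "W^H", "R^H", "E^L",
    "W^H E^L", "R^H E^L", "W^H R^H",
    "WR^dH E^L",
})

#: every label of every scheme (2+2+2 single, 4+4+4 double, 6 triple)
ALL_LABELS: dict[str, tuple[str, ...]] = {
    "W": ("W^L", "W^H"),
    "R": ("R^L", "R^H"),
    "E": ("E^L", "E^H"),
    "WE": ("W^L E^L", "W^L E^H", "W^H E^L", "W^H E^H"),
    "RE": ("R^L E^L", "R^L E^H", "R^H E^L", "R^H E^H"),
    "WR": ("W^L R^L", "W^L R^H", "W^H R^L", "W^H R^H"),
    "WRE": ("WR^dL E^L", "WR^dL E^H", "WR^sH E^L",
            "WR^sH E^H", "WR^dH E^L", "WR^dH E^H"),
}


@dataclass
class StrataAssignment:
    """Per-sample stratum labels for one scheme, plus the cutoffs used."""

    scheme: str
    labels: pd.Series  # index = samples, values = label strings
    cutoffs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        bad = set(self.labels) - set(ALL_LABELS[self.scheme])
        if bad:
            raise ValidationError(
                f"label(s) {sorted(bad)} invalid for scheme {self.scheme}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def indication(self) -> pd.Series:
        """Per-sample low/high/intermediate m6A indication."""
        return self.labels.map(indication_of)

    def indication_samples(self, which: str) -> list[str]:
        ind = self.indication()
        return list(ind.index[ind == which])


def indication_of(label: str) -> str:
    """m6A indication (low/high/intermediate) of a stratum label."""
    if label in LOW_INDICATION:
        return "low"
    if label in HIGH_INDICATION:
        return "high"
    for labels in ALL_LABELS.values():
        if label in labels:
            return "intermediate"
    raise ValidationError(f"unknown stratum label {label!r}")


def median_split(values: pd.Series) -> tuple[pd.Series, float]:
    """Dichotomize at the median: high iff value > median, ties -> low."""
    v = pd.Series(values).astype(float)
    if v.size < 2:
        raise ValidationError("median split requires >=2 samples")
    if not np.isfinite(v.to_numpy()).all():
        raise ValidationError("median split requires finite values")
    if v.nunique() == 1:
        raise ValidationError("all values identical; median dichotomy degenerate")
    cutoff = float(v.median())
    labels = pd.Series(np.where(v > cutoff, "H", "L"), index=v.index)
    return labels, cutoff


def single_stratify(values: pd.Series, scheme: str) -> StrataAssignment:
    """Median-split one signature into ``{scheme}^L`` / ``{scheme}^H``."""
    if scheme not in ("W", "R", "E"):
        raise ValidationError(f"single stratification scheme must be W/R/E, got {scheme!r}")
    hl, cutoff = median_split(values)
    return StrataAssignment(scheme, scheme + "^" + hl, {scheme: cutoff})


def _check_same_samples(*labelings: pd.Series) -> None:
    base = set(labelings[0].index)
    for other in labelings[1:]:
        diff = base ^ set(other.index)
        if diff:
            raise ValidationError(f"sample sets differ: {sorted(diff)[:5]}")


def double_stratify(a: pd.Series, b: pd.Series, scheme: str) -> StrataAssignment:
    """Cross-classify two binary (L/H) labelings into a four-group scheme."""
    if scheme not in ("WE", "RE", "WR"):
        raise ValidationError(f"double scheme must be WE/RE/WR, got {scheme!r}")
    _check_same_samples(a, b)
    b = b.loc[a.index]
    first, second = scheme[0], scheme[1]
    labels = first + "^" + a + " " + second + "^" + b
    return StrataAssignment(scheme, labels)


def triple_stratify(w: pd.Series, r: pd.Series, e: pd.Series) -> StrataAssignment:
    """Six-group WRE scheme: (#high among W,R) in {dL, sH, dH} x E level."""
    _check_same_samples(w, r, e)
    r = r.loc[w.index]
    e = e.loc[w.index]
    n_high = (w == "H").astype(int) + (r == "H").astype(int)
    wr = n_high.map({0: "dL", 1: "sH", 2: "dH"})
    labels = "WR^" + wr + " E^" + e
    return StrataAssignment("WRE", labels)


def stratify_all(sig, schemes: tuple[str, ...] = SCHEMES) -> dict[str, StrataAssignment]:
    """All requested schemes from a SignatureTable (per-cohort medians)."""
    hl = {}
    cutoffs = {}
    for s in ("W", "R", "E"):
        hl[s], cutoffs[s] = median_split(sig[s])
    out: dict[str, StrataAssignment] = {}
    for scheme in schemes:
        if scheme in ("W", "R", "E"):
            out[scheme] = StrataAssignment(
                scheme, scheme + "^" + hl[scheme], {scheme: cutoffs[scheme]})
        elif scheme in ("WE", "RE", "WR"):
            a, b = scheme[0], scheme[1]
            asg = double_stratify(hl[a], hl[b], scheme)
            asg.cutoffs = {a: cutoffs[a], b: cutoffs[b]}
            out[scheme] = asg
        elif scheme == "WRE":
            asg = triple_stratify(hl["W"], hl["R"], hl["E"])
            asg.cutoffs = dict(cutoffs)
            out[scheme] = asg
        else:
            raise ValidationError(f"unknown scheme {scheme!r}")
    return out


@dataclass
class CutoffScanResult:
    """Result of the minimum-log-rank-P threshold scan for one signature.

    The scan replaces the original ROC-based cutoff choice with an explicit
    objective: among thresholds leaving both groups at least
    ``min_group_frac`` of the cohort, pick the one minimizing the two-group
    log-rank P. ``scan`` holds the full threshold/P curve so alternative
    selection rules can be applied downstream, and ``n_candidates`` supports
    a Bonferroni-style correction for the search.
    """

    cutoff: float
    p_value: float
    labels: pd.Series
    scan: pd.DataFrame  # columns: cutoff, p_value, n_low, n_high
    n_candidates: int

    @property
    def bonferroni_p(self) -> float:
        return min(1.0, self.p_value * self.n_candidates)


def best_cutoff_scan(
    values: pd.Series,
    os_months: pd.Series,
    os_event: pd.Series,
    min_group_frac: float = 0.10,
) -> CutoffScanResult:
    """Scan signature thresholds for the minimum two-group log-rank P."""
    from .survival import logrank  # local import to avoid a cycle

    v = pd.Series(values).astype(float)
    if v.size < 20:
        raise ValidationError("cutoff scan requires >=20 samples with survival data")
    os_months = pd.Series(os_months, index=v.index).astype(float)
    os_event = pd.Series(os_event, index=v.index).astype(int)
    n = v.size
    floor = max(1, int(np.ceil(min_group_frac * n)))
    sorted_vals = np.sort(v.unique())
    rows = []
    best = None
    for cut in sorted_vals:
        high = v > cut
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < floor or n_low < floor:
            continue
        groups = pd.Series(np.where(high, "high", "low"), index=v.index)
        res = logrank(os_months, os_event, groups)
        rows.append({"cutoff": float(cut), "p_value": res.p_value,
                     "n_low": n_low, "n_high": n_high})
        if best is None or res.p_value < best[1]:
            best = (float(cut), res.p_value)
    if best is None:
        raise ValidationError(
            f"no cutoff leaves both groups >= {floor} samples; "
            "widen bounds or lower min_group_frac"
        )
    cutoff, p = best
    labels = pd.Series(np.where(v > cutoff, "H", "L"), index=v.index)
    return CutoffScanResult(cutoff, p, labels, pd.DataFrame(rows), len(rows))
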