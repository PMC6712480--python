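"""Reading, writing and validation of on-disk cohort artifacts.

All tabular artifacts are tab-delimited UTF-8 text with a header row; gene
sets use the standard GMT dialect (name TAB description TAB gene...). The
single missing-data token is the literal string ``n/a``; empty cells are
treated identically. Gene symbols are matched case-insensitively and stored
uppercase, so protein-level and RNA-level cohorts with different symbol
casing resolve to the same genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ParseError, ValidationError

#: The seven canonical m6A regulators, grouped by function.
WRITER_GENES = ("METTL3", "METTL14")
READER_GENES = ("YTHDF1", "YTHDF2", "YTHDF3")
ERASER_GENES = ("ALKBH5", "FTO")
REGULATOR_GENES = WRITER_GENES + READER_GENES + ERASER_GENES

MISSING = "n/a"

# canonical categories for the clinical table (lower-case keys for matching)
_CLINICAL_ENUMS = {
    "gender": ("Male", "Female"),
    "lauren": ("Diffuse", "Intestinal", "Others"),
    "t_stage": ("t1", "t2", "t3", "t4"),
    "n_stage": ("n0", "n1", "n2", "n3"),
    "m_stage": ("m0", "m1"),
    "stage": ("I", "II", "III", "IV"),
    "msi": ("MSI-H", "MSI-L", "MSS"),
    "ebv": ("neg", "pos"),
}

CLINICAL_COLUMNS = (
    "os_months", "os_event", "gender", "age_years", "lauren",
    "t_stage", "n_stage", "m_stage", "stage", "tmb", "msi", "ebv",
)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with strictly nonnegative values.

    Units are arbitrary linear expression quantities (protein intensities or
    normalized RNA levels); the loader never rescales, and any log transform
    is an explicit downstream step.
    """

    values: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene ID: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: list[str]) -> pd.DataFrame:
        """Rows for ``genes`` (canonical uppercase match); error if absent."""
        missing = [g for g in genes if g.upper() not in self.values.index]
        if missing:
            raise ValidationError(f"gene(s) not in expression matrix: {missing}")
        return self.values.loc[[g.upper() for g in genes]]


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and categorical clinical indexes."""

    data: pd.DataFrame  # index = sample IDs, columns = CLINICAL_COLUMNS

    def __post_init__(self) -> None:
        d = self.data
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        for col in d.columns:
            if col not in _CLINICAL_ENUMS:  # numeric columns held as float
                d[col] = d[col].astype(float)
        for col in d.columns:
            if col in _CLINICAL_ENUMS:
                allowed = set(_CLINICAL_ENUMS[col]) | {MISSING}
                bad = set(d[col].astype(str)) - allowed
                if bad:
                    raise ValidationError(
                        f"unknown {col} value(s) {sorted(bad)}; "
                        f"allowed: {sorted(allowed)}"
                    )
        if "os_event" in d.columns and "os_months" in d.columns:
            has_event = d["os_event"].notna()
            if (has_event & d["os_months"].isna()).any():
                bad = d.index[has_event & d["os_months"].isna()][0]
                raise ValidationError(
                    f"sample {bad!r} has os_event but no os_months"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def survival(self) -> tuple[pd.Series, pd.Series]:
        """(os_months, os_event) restricted to samples with both present."""
        d = self.data
        ok = d["os_months"].notna() & d["os_event"].notna()
        return d.loc[ok, "os_months"].astype(float), d.loc[ok, "os_event"].astype(int)


@dataclass
class MutationTable:
    """MAF-lite mutation records plus the derived binary sample-x-gene matrix."""

    records: pd.DataFrame  # columns: sample, gene, protein_change
    samples: list[str] = field(default_factory=list)  # full cohort sample list

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = sorted(self.records["sample"].unique())
        known = set(self.samples)
        unknown = set(self.records["sample"]) - known
        if unknown:
            raise ValidationError(
                f"mutation record(s) for unknown sample(s): {sorted(unknown)[:5]}"
            )

    @property
    def binary_matrix(self) -> pd.DataFrame:
        """sample x gene indicator: 1 iff >=1 record exists for the pair."""
        genes = sorted(self.records["gene"].unique())
        mat = pd.DataFrame(0, index=self.samples, columns=genes, dtype=int)
        if len(self.records):
            hit = self.records.drop_duplicates(["sample", "gene"])
            mat.values[
                mat.index.get_indexer(hit["sample"]),
                mat.columns.get_indexer(hit["gene"]),
            ] = 1
        return mat

    def variant_carriers(self, gene: str, protein_change: str) -> list[str]:
        """Samples carrying the exact (gene, protein_change) variant."""
        r = self.records
        hit = r[(r["gene"] == gene.upper()) & (r["protein_change"] == protein_change)]
        return sorted(hit["sample"].unique())


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-style)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers


def read_expression(path) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    try:
        vals = df.astype(float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric expression value {cell!r} at "
                        f"gene {gene!r}, sample {sample!r}"
                    ) from exc
        raise ParseError(str(exc)) from exc
    arr = vals.to_numpy()
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"negative expression value at gene {vals.index[g]!r}, "
            f"sample {vals.columns[s]!r}"
        )
    return ExpressionMatrix(vals)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def _normalize_category(col: str, raw: str) -> str:
    """Case-insensitive match of a raw cell against the canonical enum."""
    if raw is None or str(raw).strip() in ("", MISSING, "NA", "nan", "None"):
        return MISSING
    for canon in _CLINICAL_ENUMS[col]:
        if str(raw).strip().lower() == canon.lower():
            return canon
    raise ValidationError(
        f"unknown {col} value {raw!r}; allowed: {list(_CLINICAL_ENUMS[col])}"
    )


def read_clinical(path) -> ClinicalTable:
    """Read the per-sample clinical TSV ('sample' column + CLINICAL_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    out = pd.DataFrame(index=df.index)
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            out[col] = MISSING if col in _CLINICAL_ENUMS else np.nan
            continue
        raw = df[col]
        if col in _CLINICAL_ENUMS:
            out[col] = [_normalize_category(col, v) for v in raw]
        else:  # numeric: os_months, os_event, age_years, tmb
            out[col] = [
                np.nan if str(v).strip() in ("", MISSING, "NA", "nan", "None")
                else float(v)
                for v in raw
            ]
    return ClinicalTable(out)


def write_clinical(clin: ClinicalTable, path) -> None:
    d = clin.data.copy()
    for col in d.columns:
        if col not in _CLINICAL_ENUMS:
            d[col] = d[col].map(lambda v: MISSING if pd.isna(v) else repr(float(v)))
    d.index.name = "sample"
    d.to_csv(path, sep="\t")


def read_mutations(path, samples: list[str] | None = None,
                   allow_extra: bool = False) -> MutationTable:
    """Read a MAF-lite TSV (columns: sample, gene, protein_change).

    ``samples`` is the full cohort sample list; records for samples outside
    it raise unless ``allow_extra``, in which case they are dropped with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df["gene"] = df["gene"].str.upper()
    if samples is not None:
        extra = set(df["sample"]) - set(samples)
        if extra:
            if not allow_extra:
                raise ValidationError(
                    f"mutation record(s) for unknown sample(s): {sorted(extra)[:5]}"
                )
            warnings.warn(f"dropping records for {len(extra)} unknown sample(s)")
            df = df[df["sample"].isin(samples)]
    return MutationTable(df.reset_index(drop=True),
                         samples=list(samples) if samples is not None else [])


def write_mutations(mut: MutationTable, path) -> None:
    mut.records.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (one set per line, >=3 tab fields)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno}: expected >=3 tab fields")
            name, description = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in genes:
                    genes.append(g)
            sets[name] = genes
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in gsc.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
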