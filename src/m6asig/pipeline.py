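"""End-to-end orchestration: signatures -> stratification -> survival ->
association -> enrichment, from a config, with a reproducible manifest.

Every numeric output is written as TSV for diffability; the manifest echoes
the full config, the seed, package version, and a checksum per artifact, so
a run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._errors import M6ASigError, ValidationError
from . import cohort_io
from .cohort_io import ExpressionMatrix
from .signatures import compute_wre, signature_correlations
from .stratification import SCHEMES, stratify_all, best_cutoff_scan
from .survival import compare_strata_survival
from .association import (
    clinical_association, cross_cohort_intersect, filter_genes_by_frequency,
    foldchange_low_vs_high, group_mean_compare,
)
from .enrichment import diff_expr, gsea, results_frame
from .synthetic import SimulationParams, generate_cohort, write_cohort

log = logging.getLogger("m6asig")

#: the two most diverse WRE corners, compared throughout the analysis
EXTREME_PAIR = ("WR^dL E^H", "WR^dH E^L")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_paths`` (expression/clinical/mutations/gene_sets
    file paths) or ``synthetic`` (SimulationParams keyword mapping) must be
    given.
    """

    out_dir: str
    input_paths: dict | None = None
    synthetic: dict | None = None
    schemes: tuple = SCHEMES
    cutoff_mode: str = "median"           # median | scan
    deg_threshold: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    log_transform: bool = False

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of input_paths or synthetic must be provided")
        if self.cutoff_mode not in ("median", "scan"):
            raise ValidationError("cutoff_mode must be 'median' or 'scan'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ReportBundle:
    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    complete: bool = False


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        params = SimulationParams(**{"seed": config.seed, **config.synthetic})
        cohort = generate_cohort(params)
        return cohort.expression, cohort.clinical, cohort.mutations, cohort.gene_sets
    paths = config.input_paths
    expr = cohort_io.read_expression(paths["expression"])
    clin = cohort_io.read_clinical(paths["clinical"])
    mut = cohort_io.read_mutations(paths["mutations"], samples=expr.samples,
                                   allow_extra=bool(paths.get("allow_extra")))
    gsc = cohort_io.read_gmt(paths["gene_sets"]) if paths.get("gene_sets") else None
    return expr, clin, mut, gsc


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write the report bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out)
    stage = "load"
    try:
        expr, clin, mut, gsc = _load_inputs(config)
        if config.synthetic is not None:
            stage = "simulate"
            params = SimulationParams(**{"seed": config.seed, **config.synthetic})
            write_cohort(generate_cohort(params), out / "cohort")

        stage = "signatures"
        sig = compute_wre(expr, log_transform=config.log_transform)
        _write(bundle, "signatures", sig.data.rename_axis("sample"))
        _write(bundle, "signature_correlations", signature_correlations(sig))

        stage = "stratify"
        assignments = stratify_all(sig, tuple(config.schemes))
        rows = []
        for scheme, asg in assignments.items():
            ind = asg.indication()
            for s in asg.samples:
                rows.append({"sample": s, "scheme": scheme,
                             "label": asg.labels[s], "indication": ind[s]})
        _write(bundle, "strata", pd.DataFrame(rows))
        if config.cutoff_mode == "scan":
            os_m, os_e = clin.survival()
            for s in ("W", "R", "E"):
                if s in assignments:
                    scan = best_cutoff_scan(sig[s].loc[os_m.index], os_m, os_e)
                    _write(bundle, f"cutoff_scan_{s}", scan.scan)

        stage = "survival"
        surv_rows = []
        for scheme, asg in assignments.items():
            res, _ = compare_strata_survival(clin, asg)
            surv_rows.append({"scheme": scheme, "comparison": "omnibus",
                              "statistic": res.statistic, "df": res.df,
                              "p_value": res.p_value})
        if "WRE" in assignments and set(EXTREME_PAIR) <= set(assignments["WRE"].labels):
            res, curves = compare_strata_survival(clin, assignments["WRE"],
                                                  pair=EXTREME_PAIR)
            surv_rows.append({"scheme": "WRE", "comparison": "extreme_pair",
                              "statistic": res.statistic, "df": res.df,
                              "p_value": res.p_value})
            for lab, c in curves.items():
                safe = lab.replace("^", "").replace(" ", "_")
                _write(bundle, f"km_{safe}", c.as_frame())
        _write(bundle, "survival_tests", pd.DataFrame(surv_rows))

        stage = "associate"
        fc = foldchange_low_vs_high(mut, assignments)
        _write(bundle, "mutation_foldchange", fc.rename_axis("gene"))
        if "WRE" in assignments:
            from .association import CLINICAL_VARIABLES

            assoc_rows = []
            for var in CLINICAL_VARIABLES:
                # degenerate variables (e.g. a category absent from the
                # cohort) are reported as untestable, not fatal
                try:
                    r = clinical_association(clin, assignments["WRE"],
                                             variables=(var,))[0]
                    assoc_rows.append({
                        "variable": r.variable, "test": r.test,
                        "statistic": r.statistic, "p_value": r.p_value,
                        "table": json.dumps(r.table.tolist()),
                    })
                except ValidationError as exc:
                    assoc_rows.append({"variable": var, "test": "none",
                                       "statistic": None, "p_value": None,
                                       "table": str(exc)})
            _write(bundle, "clinical_association", pd.DataFrame(assoc_rows))
            ind = assignments["WRE"].indication()
            tmb = clin.data["tmb"]
            keep = ind.isin(["low", "high"]) & tmb.notna()
            if keep.sum() >= 4:
                t, p = group_mean_compare(tmb[keep], ind[keep] == "low")
                _write(bundle, "tmb_comparison", pd.DataFrame(
                    [{"contrast": "low_vs_high_indication", "t": t, "p_value": p}]))

        stage = "enrich"
        if "WRE" in assignments:
            ind = assignments["WRE"].indication()
            keep = ind.isin(["low", "high"])
            labels = (ind[keep] == "high").to_numpy()
            sub = ExpressionMatrix(expr.values.loc[:, keep[keep].index])
            deg = diff_expr(sub, labels, threshold=config.deg_threshold)
            _write(bundle, "diff_expr", deg.rename_axis("gene"))
            if gsc is not None and labels.sum() >= 3 and (~labels).sum() >= 3:
                res = gsea(sub, labels, gsc, n_perm=config.n_perm,
                           seed=config.seed)
                _write(bundle, "enrichment", results_frame(res))

        stage = "manifest"
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
            "seed": config.seed,
            "package": "m6asig 0.1.0",
            "artifacts": {k: {"path": str(v), "sha256": _sha256(v)}
                          for k, v in bundle.artifacts.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle.summary = {"n_samples": len(expr.samples),
                          "n_genes": len(expr.genes),
                          "artifacts": sorted(bundle.artifacts)}
        (out / "summary.json").write_text(json.dumps(bundle.summary, indent=2))
        bundle.complete = True
    except M6ASigError as exc:
        (out / "INCOMPLETE").write_text(f"stage {stage} failed: {exc}\n")
        raise M6ASigError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def _write(bundle: ReportBundle, name: str, frame: pd.DataFrame) -> None:
    path = bundle.out_dir / f"{name}.tsv"
    frame.to_csv(path, sep="\t",
                 index=frame.index.name is not None)
    bundle.artifacts[name] = path
    log.info("wrote %s", path)
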