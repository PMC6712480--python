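"""Synthetic gastric-cancer cohort generator with a known ground truth.

A single latent per-sample m6A level drives every data layer, so the sign
structure the analysis assumes holds by construction:

* regulator expression — writer and reader blocks load positively on the
  latent factor, the eraser block negatively, with extra within-block
  correlation (log-normal values, strictly positive);
* survival — exponential with the hazard multiplied by ``hr_low_vs_high``
  for the lowest latent tertile (low m6A does worse), independent censoring;
* driver mutations — Bernoulli with the odds multiplied in low-latent
  samples; one CDH1 variant (p.D254Y) concentrated in low-m6A carriers;
* clinical covariates — diffuse Lauren subtype, advanced T/N/stage and
  higher MSI/TMB shifted along the latent level; EBV independent;
* background genes — an "oncogenic" subset anti-correlated with the latent
  factor (for enrichment tests), the rest independent noise.

All randomness flows from one root seed through named substreams, so
regeneration with the same parameters is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from . import cohort_io
from .cohort_io import (
    ClinicalTable, ExpressionMatrix, GeneSetCollection, MutationTable,
    REGULATOR_GENES, WRITER_GENES, READER_GENES, ERASER_GENES,
)

#: driver genes reported as enriched under low m6A, spiked by default
DEFAULT_DRIVERS = (
    ("CDH1", 0.15, 3.0), ("AR", 0.12, 3.0), ("GLI3", 0.12, 3.0),
    ("SETBP1", 0.10, 3.0), ("RHOA", 0.12, 3.0), ("MUC6", 0.12, 3.0),
    ("TP53", 0.30, 3.0),
)


@dataclass
class SimulationParams:
    """Knobs of the cohort simulator (defaults = the emulated study design)."""

    n_samples: int = 600
    regulator_means: tuple = tuple([100.0] * 7)   # linear-scale medians
    regulator_sigma: float = 0.5                  # log-scale SD
    within_block_rho: float = 0.6                 # corr inside W/R/E blocks
    wr_rho: float = 0.4                           # W-block vs R-block corr
    we_rho: float = -0.4                          # W/R blocks vs E block corr
    n_background_genes: int = 200
    n_enriched_genes: int = 40                    # anti-correlated spike set
    background_loading: float = 0.5
    hazard_scale: float = 30.0                    # months; baseline 1/hazard
    hr_low_vs_high: float = 2.5                   # lowest latent tertile
    censor_rate: float = 0.3
    driver_genes: tuple = DEFAULT_DRIVERS
    n_passenger_genes: int = 30
    passenger_rate: float = 0.05
    clinical_shift: float = 1.0                   # latent effect on categories
    tmb_shift: float = 0.5                        # latent effect on log TMB
    seed: int = 0

    def block_loadings(self) -> dict[str, float]:
        """Latent-factor loadings per block; errors if not positive definite."""
        if not 0 < self.wr_rho < 1:
            raise ValidationError("wr_rho must be in (0, 1)")
        l_w = np.sqrt(self.wr_rho)
        l_e = self.we_rho / l_w
        for name, l in (("W/R", l_w), ("E", abs(l_e))):
            if l**2 > self.within_block_rho + 1e-12:
                raise ValidationError(
                    f"correlation structure not positive definite: {name} "
                    f"loading^2 ({l**2:.3f}) exceeds within_block_rho "
                    f"({self.within_block_rho}); lower |wr_rho|/|we_rho| or "
                    "raise within_block_rho"
                )
        if not 0 <= self.within_block_rho < 1:
            raise ValidationError("within_block_rho must be in [0, 1)")
        return {"W": float(l_w), "R": float(l_w), "E": float(l_e)}


@dataclass
class SyntheticCohort:
    """Generated cohort plus its hidden ground truth."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    gene_sets: GeneSetCollection
    truth: pd.DataFrame            # per-sample latent level, tertile, hazard
    spiked_drivers: list[str]
    spiked_set: str                # name of the anti-correlated gene set
    params: SimulationParams


def _softmax_probs(base: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Category probabilities with log-odds shifted per sample.

    ``base`` is (k,) baseline probabilities; ``shift`` is (n, k) additive
    log-odds offsets. Returns (n, k).
    """
    logit = np.log(base)[None, :] + shift
    p = np.exp(logit - logit.max(axis=1, keepdims=True))
    return p / p.sum(axis=1, keepdims=True)


def _draw_categories(rng, probs: np.ndarray, cats: list[str]) -> np.ndarray:
    u = rng.random(probs.shape[0])
    cum = probs.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(cats, dtype=object)[idx]


def generate_cohort(params: SimulationParams | None = None) -> SyntheticCohort:
    """Simulate one cohort from ``params`` (defaults when omitted)."""
    p = params or SimulationParams()
    loadings = p.block_loadings()
    n = p.n_samples
    if n < 2:
        raise ValidationError("n_samples must be >= 2")
    streams = np.random.SeedSequence(p.seed).spawn(5)
    rng_expr = np.random.default_rng(streams[0])
    rng_surv = np.random.default_rng(streams[1])
    rng_mut = np.random.default_rng(streams[2])
    rng_clin = np.random.default_rng(streams[3])

    samples = [f"S{i:04d}" for i in range(n)]
    latent = rng_expr.standard_normal(n)

    # --- regulator expression -------------------------------------------
    blocks = {"W": WRITER_GENES, "R": READER_GENES, "E": ERASER_GENES}
    rows = {}
    means = dict(zip(REGULATOR_GENES, p.regulator_means))
    for block, genes in blocks.items():
        l = loadings[block]
        b = np.sqrt(max(p.within_block_rho - l**2, 0.0))
        c = np.sqrt(max(1.0 - p.within_block_rho, 0.0))
        shared = rng_expr.standard_normal(n)
        for g in genes:
            z = l * latent + b * shared + c * rng_expr.standard_normal(n)
            rows[g] = means[g] * np.exp(p.regulator_sigma * z)

    # --- background genes (spiked anti-correlated subset first) ---------
    spiked_genes = [f"ONCOG{i:03d}" for i in range(p.n_enriched_genes)]
    bl = p.background_loading
    for g in spiked_genes:
        z = -bl * latent + np.sqrt(1 - bl**2) * rng_expr.standard_normal(n)
        rows[g] = 50.0 * np.exp(0.5 * z)
    n_noise = p.n_background_genes - p.n_enriched_genes
    for i in range(max(n_noise, 0)):
        rows[f"BG{i:03d}"] = 50.0 * np.exp(0.5 * rng_expr.standard_normal(n))
    expr = ExpressionMatrix(pd.DataFrame(rows, index=samples).T)

    # --- survival --------------------------------------------------------
    tertile = pd.qcut(latent, 3, labels=["low", "mid", "high"]).astype(str)
    base_hazard = 1.0 / p.hazard_scale
    hazard = np.where(tertile == "low", base_hazard * p.hr_low_vs_high,
                      base_hazard)
    t_event = rng_surv.exponential(1.0 / hazard)
    if p.censor_rate > 0:
        # independent censoring, uniform over [0, W]; W solved so the
        # marginal censored fraction matches censor_rate at the mean hazard
        lam = float(hazard.mean())
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = (1.0 - np.exp(-mid)) / mid
            lo, hi = (mid, hi) if frac > p.censor_rate else (lo, mid)
        window = 0.5 * (lo + hi) / lam
        c_time = rng_surv.random(n) * window
    else:
        c_time = np.full(n, np.inf)
    censored = t_event > c_time
    t_obs = np.where(censored, c_time, t_event)
    os_event = (~censored).astype(int)

    # --- mutations -------------------------------------------------------
    records = []
    low_mask = tertile == "low"
    spiked_drivers = [g for g, _, mult in p.driver_genes if mult != 1.0]
    for gene, p0, mult in p.driver_genes:
        odds = p0 / (1 - p0) * np.where(low_mask, mult, 1.0)
        prob = odds / (1 + odds)
        hit = rng_mut.random(n) < prob
        for i in np.nonzero(hit)[0]:
            if gene == "CDH1" and low_mask[i] and rng_mut.random() < 0.6:
                change = "p.D254Y"
            else:
                change = f"p.A{int(rng_mut.integers(100, 999))}V"
            records.append((samples[i], gene, change))
    for j in range(p.n_passenger_genes):
        gene = f"PSG{j:03d}"
        hit = rng_mut.random(n) < p.passenger_rate
        for i in np.nonzero(hit)[0]:
            records.append((samples[i], gene,
                            f"p.G{int(rng_mut.integers(100, 999))}S"))
    mut = MutationTable(
        pd.DataFrame(records, columns=["sample", "gene", "protein_change"]),
        samples=samples,
    )

    # --- clinical covariates --------------------------------------------
    shift = p.clinical_shift
    gender = np.where(rng_clin.random(n) < 0.6, "Male", "Female")
    age = np.clip(rng_clin.normal(62, 10, n), 25, 90)
    lauren = _draw_categories(
        rng_clin,
        _softmax_probs(np.array([0.35, 0.50, 0.15]),
                       np.column_stack([-shift * latent, np.zeros(n),
                                        np.zeros(n)])),
        ["Diffuse", "Intestinal", "Others"])
    t_stage = _draw_categories(
        rng_clin,
        _softmax_probs(np.array([0.05, 0.20, 0.45, 0.30]),
                       np.outer(-latent * shift, np.array([-1, -0.3, 0.3, 1]))),
        ["t1", "t2", "t3", "t4"])
    n_stage = _draw_categories(
        rng_clin,
        _softmax_probs(np.array([0.30, 0.20, 0.20, 0.30]),
                       np.outer(-latent * shift, np.array([-1, -0.3, 0.3, 1]))),
        ["n0", "n1", "n2", "n3"])
    m1_prob = 1.0 / (1.0 + np.exp(-(-2.8 - 0.4 * shift * latent)))
    m_stage = np.where(rng_clin.random(n) < m1_prob, "m1", "m0")
    stage = _draw_categories(
        rng_clin,
        _softmax_probs(np.array([0.15, 0.30, 0.40, 0.15]),
                       np.outer(-latent * shift, np.array([-1, -0.3, 0.3, 1]))),
        ["I", "II", "III", "IV"])
    tmb = np.exp(1.5 + p.tmb_shift * latent
                 + 0.4 * rng_clin.standard_normal(n))
    msih_prob = 1.0 / (1.0 + np.exp(-(-1.8 + 0.8 * shift * latent)))
    u = rng_clin.random(n)
    msi = np.where(u < msih_prob, "MSI-H",
                   np.where(u < msih_prob + 0.2, "MSI-L", "MSS"))
    ebv = np.where(rng_clin.random(n) < 0.09, "pos", "neg")

    clin = ClinicalTable(pd.DataFrame({
        "os_months": t_obs, "os_event": os_event, "gender": gender,
        "age_years": age, "lauren": lauren, "t_stage": t_stage,
        "n_stage": n_stage, "m_stage": m_stage, "stage": stage,
        "tmb": tmb, "msi": msi, "ebv": ebv,
    }, index=pd.Index(samples, name="sample")))

    # --- gene sets -------------------------------------------------------
    spiked_set = "ONCOGENIC_SPIKE"
    sets = {spiked_set: list(spiked_genes)} if spiked_genes else {}
    noise_genes = [f"BG{i:03d}" for i in range(max(n_noise, 0))]
    rng_sets = np.random.default_rng(streams[4])
    for k in range(3):
        if len(noise_genes) >= 10:
            pick = sorted(rng_sets.choice(noise_genes, size=10, replace=False))
            sets[f"RANDOM_SET_{k}"] = list(pick)
    gsc = GeneSetCollection(sets, {spiked_set: "anti-correlated with m6A latent"})

    truth = pd.DataFrame({
        "latent": latent, "tertile": tertile, "hazard": hazard,
        "event_time": t_event, "censored": censored,
    }, index=pd.Index(samples, name="sample"))

    return SyntheticCohort(expr, clin, mut, gsc, truth,
                           spiked_drivers, spiked_set, p)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write every artifact in the exact dialects the readers consume.

    The truth table is written separately and never read by the pipeline.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "mutations": out / "mutations.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.tsv",
        "params": out / "params.tsv",
    }
    cohort_io.write_expression(cohort.expression, paths["expression"])
    cohort_io.write_clinical(cohort.clinical, paths["clinical"])
    cohort_io.write_mutations(cohort.mutations, paths["mutations"])
    cohort_io.write_gmt(cohort.gene_sets, paths["gene_sets"])
    cohort.truth.to_csv(paths["truth"], sep="\t")
    pd.Series({k: repr(v) for k, v in asdict(cohort.params).items()}) \
        .to_csv(paths["params"], sep="\t", header=False)
    return paths


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass
class RecoveryReport:
    """Pass/fail checks that the pipeline recovers the simulated structure."""

    km_median_ordered: bool       # WR^dH E^L outlives WR^dL E^H
    drivers_called_up: bool       # spiked drivers consensus UP across replicates
    logrank_significant: bool     # extreme-corner two-group P < 0.05
    nes_sign_correct: bool        # spiked set negatively enriched in high m6A
    underpowered: bool = False
    details: dict = field(default_factory=dict)

    def all_pass(self) -> bool:
        return (self.km_median_ordered and self.drivers_called_up
                and self.logrank_significant and self.nes_sign_correct)


MIN_POWERED_N = 100  # below this the report flags insufficient power


def recovery_report(
    cohort: SyntheticCohort,
    replicate: SyntheticCohort | None = None,
    n_perm: int = 200,
    run_gsea: bool = True,
) -> RecoveryReport:
    """Run the pipeline on a synthetic cohort and check ground-truth recovery.

    ``replicate`` (an independent cohort from the same parameters, different
    seed) feeds the cross-cohort UP-call check; it is generated automatically
    when omitted.
    """
    from .signatures import compute_wre
    from .stratification import stratify_all
    from .survival import compare_strata_survival
    from .association import foldchange_low_vs_high, cross_cohort_intersect
    from .enrichment import gsea

    p = cohort.params
    underpowered = p.n_samples < MIN_POWERED_N
    if replicate is None:
        rep_params = SimulationParams(**{**asdict(p), "seed": p.seed + 104729})
        rep_params.driver_genes = p.driver_genes
        replicate = generate_cohort(rep_params)

    details: dict = {}

    def strata(c: SyntheticCohort):
        return stratify_all(compute_wre(c.expression))

    asg = strata(cohort)
    wre = asg["WRE"]

    # (a) KM median ordering between the extreme WRE corners
    res, curves = compare_strata_survival(
        cohort.clinical, wre, pair=("WR^dL E^H", "WR^dH E^L"))
    med_low = curves["WR^dL E^H"].median
    med_high = curves["WR^dH E^L"].median
    km_ok = med_high > med_low
    details["km_median"] = {"WR^dL E^H": med_low, "WR^dH E^L": med_high}

    # (c) log-rank significance, when powered per design
    logrank_ok = res.p_value < 0.05
    details["logrank_p"] = res.p_value

    # (b) spiked drivers UP in the cross-replicate intersection; a null
    # configuration (no spiked drivers) is checked over all driver genes,
    # where UP consensus should occur only at chance rates
    genes = cohort.spiked_drivers or [g for g, _, _ in p.driver_genes]
    fc_a = foldchange_low_vs_high(cohort.mutations, asg, genes=genes)
    fc_b = foldchange_low_vs_high(replicate.mutations, strata(replicate),
                                  genes=genes)
    calls = cross_cohort_intersect(fc_a, fc_b)
    up_ok = bool((calls.loc[genes, "consensus"] == "UP").all())
    details["consensus_calls"] = calls["consensus"].to_dict()

    # (d) spiked-set NES sign in the high- vs low-m6A indication contrast
    nes_ok = True
    if run_gsea:
        ind = wre.indication()
        keep = ind.isin(["low", "high"])
        sub_expr = ExpressionMatrix(cohort.expression.values.loc[:, keep[keep].index])
        labels = (ind[keep] == "high").to_numpy()
        results = gsea(sub_expr, labels, cohort.gene_sets,
                       n_perm=max(n_perm, 100), seed=p.seed)
        spiked = next(r for r in results if r.name == cohort.spiked_set)
        nes_ok = spiked.nes < 0
        details["spiked_nes"] = spiked.nes
        details["spiked_p"] = spiked.nominal_p

    return RecoveryReport(km_ok, up_ok, logrank_ok, nes_ok,
                          underpowered=underpowered, details=details)
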