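"""Synthetic cohort generator with the statistical structure the analysis
assumes: MSS/MSI labels, sparse genomic-alteration records over a
few-hundred-gene universe, right-censored exponential PFS whose hazard is
modified multiplicatively by planted resistance/sensitivity genes,
log-normal TMB straddling the 10.4 mutations/Mb cut-off, and
negative-binomial expression counts with subtype-template mean shifts and
differential-expression effects planted between prognosis groups.

Defaults emulate a single-arm first-line metastatic colorectal cancer
cohort profiled by a targeted panel: 55 patients (6 MSI), a 336-gene
alteration universe with ~18 alterations per patient, median PFS around
10 months with administrative censoring at 24 months, and TMB with median
~6.7 mutations/Mb. All draws flow from named sub-streams of one seed, so
adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AlterationTable, ClinicalTable, CountMatrix, MarkerTable

__all__ = [
    "ExpressionConfig",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_trial_responses",
]

_ALTERATION_CLASSES = ("SNV", "INDEL", "CNV", "LOH")
# class mix roughly matching a targeted-panel alteration spectrum
_CLASS_PROBS = (0.61, 0.10, 0.27, 0.02)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator keyed by (seed, stable hash of stage name)."""
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


@dataclass(frozen=True)
class ExpressionConfig:
    """Negative-binomial expression model.

    ``dispersion`` is the NB alpha (var = mu + alpha * mu^2); marker genes
    of a sample's true subtype shift by ``marker_shift`` log2 units (up
    markers up, down markers down).
    """

    n_genes: int = 500
    library_size_range: tuple[int, int] = (50_000, 150_000)
    dispersion: float = 0.3
    marker_shift: float = 2.0
    n_classes: int = 2
    markers_per_class: int = 40


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 55
    msi_fraction: float = 6 / 55
    gene_universe: int = 336
    background_alteration_rate: float = 17.85 / 336
    planted_resistance_genes: tuple[tuple[str, float], ...] = tuple(
        (f"RESG{i}", 3.0) for i in range(1, 6)
    )
    planted_sensitivity_genes: tuple[tuple[str, float], ...] = tuple(
        (f"SENSG{i}", 1 / 3) for i in range(1, 6)
    )
    planted_prevalence: float = 0.15  # marginal; ~0.3 in the short-PFS tail at HR 3
    alteration_rate_dispersion: float = 1.5  # log-sd of per-gene background rates
    baseline_hazard: float = np.log(2) / 10.0  # events/month; median ~10 months
    msi_hazard_ratio: float = 0.5
    dropout_hazard: float = 0.01  # events/month, independent censoring
    admin_censor_time: float = 24.0  # months
    tmb_log_mean: float = float(np.log(6.71))
    tmb_log_sd: float = 0.7
    tmb_coupling_shift: float = 0.0  # log-TMB shift for sensitivity-gene carriers
    response_probs: tuple[float, float, float, float, float] = (
        7 / 73, 49 / 73, 15 / 73, 0.0, 2 / 73
    )  # CR, PR, SD, PD, NE
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    n_deg_genes: int = 50
    deg_effect: float = 2.0  # log2 fold planted between prognosis groups
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 8:
            raise ValueError("n_patients must be >= 8")
        for name in ("msi_fraction", "background_alteration_rate", "planted_prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for g, hr in self.planted_resistance_genes:
            if hr <= 0:
                raise ValueError(f"hazard ratio for {g} must be positive")
        for g, hr in self.planted_sensitivity_genes:
            if hr <= 0:
                raise ValueError(f"hazard ratio for {g} must be positive")
        res = {g for g, _ in self.planted_resistance_genes}
        sens = {g for g, _ in self.planted_sensitivity_genes}
        if res & sens:
            raise ValueError("resistance and sensitivity gene lists must be disjoint")
        if len(res) + len(sens) > self.gene_universe:
            raise ValueError("more planted genes than the gene universe holds")
        if abs(sum(self.response_probs) - 1) > 1e-9:
            raise ValueError("response_probs must sum to 1")


@dataclass(frozen=True)
class SyntheticCohort:
    clinical: ClinicalTable
    alterations: AlterationTable
    counts: CountMatrix
    ground_truth: dict

    def __post_init__(self) -> None:
        clin = set(self.clinical.patient_ids)
        alt = set(self.alterations.records["patient_id"])
        if alt - clin:
            raise ValueError("alteration table contains unknown patients")


def _gene_names(config: SimulationConfig) -> list[str]:
    planted = [g for g, _ in config.planted_resistance_genes] + [
        g for g, _ in config.planted_sensitivity_genes
    ]
    n_bg = config.gene_universe - len(planted)
    return planted + [f"BG{i:04d}" for i in range(1, n_bg + 1)]


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> SyntheticCohort:
    """Draw one fully reproducible cohort from the configured model.

    Per patient: carried genes are independent Bernoulli draws (background
    rate for background genes, planted prevalence for planted genes); the
    PFS hazard is baseline x MSI modifier x the product of carried
    planted-gene hazard ratios; observation is censored at the minimum of
    an independent exponential dropout and the administrative horizon.
    """
    n = config.n_patients
    expr = config.expression
    if expr.n_classes * expr.markers_per_class + config.n_deg_genes > expr.n_genes:
        raise ValueError("marker and DEG blocks exceed the expression gene count")
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    genes = _gene_names(config)
    hr = {g: r for g, r in config.planted_resistance_genes}
    hr.update({g: r for g, r in config.planted_sensitivity_genes})

    # --- MSI labels: deterministic count, random membership -----------------
    rng = _stage_rng(config.seed, "msi")
    n_msi = int(round(config.msi_fraction * n))
    msi_idx = set(rng.choice(n, size=n_msi, replace=False).tolist())
    msi = np.array(["MSI" if i in msi_idx else "MSS" for i in range(n)])

    # --- alteration matrix --------------------------------------------------
    # per-gene background rates are log-normally heterogeneous (a few
    # recurrently altered genes, a long tail of rare ones), matching the
    # skewed per-gene frequency spectrum of targeted-panel cohorts; the
    # log-normal mean is set so the expected alterations/patient matches
    # background_alteration_rate * gene_universe
    rng = _stage_rng(config.seed, "alterations")
    sigma = config.alteration_rate_dispersion
    mu = np.log(max(config.background_alteration_rate, 1e-12)) - sigma**2 / 2
    gene_rates = np.minimum(rng.lognormal(mu, sigma, size=len(genes)), 0.95)
    carried = np.zeros((n, len(genes)), dtype=bool)
    for j, g in enumerate(genes):
        rate = config.planted_prevalence if g in hr else gene_rates[j]
        carried[:, j] = rng.random(n) < rate
    classes = rng.choice(len(_ALTERATION_CLASSES), size=carried.shape, p=_CLASS_PROBS)
    records = [
        {"patient_id": ids[i], "gene": genes[j],
         "alteration_class": _ALTERATION_CLASSES[classes[i, j]]}
        for i, j in zip(*np.nonzero(carried))
    ]
    rec_df = pd.DataFrame(records, columns=["patient_id", "gene", "alteration_class"])

    # --- TMB ----------------------------------------------------------------
    rng = _stage_rng(config.seed, "tmb")
    log_tmb = rng.normal(config.tmb_log_mean, config.tmb_log_sd, size=n)
    if config.tmb_coupling_shift:
        sens_cols = [genes.index(g) for g, _ in config.planted_sensitivity_genes]
        coupled = carried[:, sens_cols].any(axis=1)
        log_tmb = log_tmb + config.tmb_coupling_shift * coupled
    tmb = pd.Series(np.exp(log_tmb), index=ids, name="tmb")

    # --- PFS ----------------------------------------------------------------
    rng = _stage_rng(config.seed, "survival")
    hazard = np.full(n, config.baseline_hazard)
    hazard[msi == "MSI"] *= config.msi_hazard_ratio
    for g, r in hr.items():
        hazard *= np.where(carried[:, genes.index(g)], r, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    dropout = (
        rng.exponential(1.0 / config.dropout_hazard, size=n)
        if config.dropout_hazard > 0
        else np.full(n, np.inf)
    )
    censor = np.minimum(dropout, config.admin_censor_time)
    pfs = np.minimum(event_time, censor)
    event = event_time <= censor

    # --- best response ------------------------------------------------------
    rng = _stage_rng(config.seed, "response")
    cats = ("CR", "PR", "SD", "PD", "NE")
    response = rng.choice(cats, size=n, p=config.response_probs)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": ids,
                "msi_status": msi,
                "ras_status": ["mut"] * n,  # trial enrols RAS/BRAF-mutated only
                "braf_status": ["wt"] * n,
                "pfs_months": np.round(pfs, 3),
                "pfs_event": event,
                "best_response": response,
            }
        )
    )
    alterations = AlterationTable(rec_df, tmb)

    # --- expression ---------------------------------------------------------
    rng = _stage_rng(config.seed, "expression")
    expr_genes = [f"EXPR{i:04d}" for i in range(1, expr.n_genes + 1)]
    subtype_classes = [f"S{c + 1}" for c in range(expr.n_classes)]
    true_class = rng.choice(subtype_classes, size=n)
    # marker block per class: first half up, second half down
    marker_rows = []
    shift = np.zeros((expr.n_genes, n))
    cursor = 0
    for cls in subtype_classes:
        block = expr_genes[cursor: cursor + expr.markers_per_class]
        cursor += expr.markers_per_class
        half = len(block) // 2
        for k, g in enumerate(block):
            direction = "up" if k < half else "down"
            marker_rows.append({"gene": g, "class": cls, "direction": direction})
            sign = 1.0 if direction == "up" else -1.0
            gi = expr_genes.index(g)
            shift[gi, true_class == cls] += sign * expr.marker_shift
    # planted DEGs: shift in the good-prognosis half (PFS above the median)
    deg_block = expr_genes[cursor: cursor + config.n_deg_genes]
    good = pfs >= np.median(pfs)
    half = len(deg_block) // 2
    deg_truth = []
    for k, g in enumerate(deg_block):
        sign = 1.0 if k < half else -1.0
        deg_truth.append({"gene": g, "direction": "up" if sign > 0 else "down"})
        shift[expr_genes.index(g), good] += sign * config.deg_effect

    base_mean = rng.lognormal(mean=3.0, sigma=1.0, size=expr.n_genes)
    rel = base_mean[:, None] * 2.0**shift
    rel /= rel.sum(axis=0, keepdims=True)
    lib = rng.integers(expr.library_size_range[0], expr.library_size_range[1] + 1, size=n)
    mu = rel * lib[None, :]
    alpha = expr.dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam)
    count_matrix = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=expr_genes, columns=ids)
    )

    ground_truth = {
        "resistance_genes": [g for g, _ in config.planted_resistance_genes],
        "sensitivity_genes": [g for g, _ in config.planted_sensitivity_genes],
        "subtype_labels": pd.Series(true_class, index=ids, name="true_class"),
        "marker_table": MarkerTable(pd.DataFrame(marker_rows)),
        "deg_genes": pd.DataFrame(deg_truth),
        "good_prognosis": pd.Series(good, index=ids, name="good_prognosis"),
    }
    return SyntheticCohort(
        clinical=clinical, alterations=alterations, counts=count_matrix,
        ground_truth=ground_truth,
    )


def simulate_trial_responses(n: int, p_true: float, seed: int) -> list[str]:
    """Bernoulli responder draws mapped to best-response categories.

    Responders become PR, non-responders PD; intended as a harness for
    power checks of the exact single-stage design.
    """
    if not 0 <= p_true <= 1:
        raise ValueError("p_true must be in [0, 1]")
    rng = _stage_rng(seed, "trial_responses")
    return ["PR" if u < p_true else "PD" for u in rng.random(n)]
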