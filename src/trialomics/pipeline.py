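"""Pipeline orchestration: run the full analysis from one YAML config.

Stages run in dependency order — simulate (or load inputs), trial-stats,
survival, signatures, deg, subtype, enrich — each writing deterministic
tabular outputs under the configured output directory; a run manifest
records stage statuses, output files, parameters and the seed, and a text
report summarises the main numbers. A single seed fans out to per-stage
sub-seeds by stable hashing of stage names, so enabling or disabling one
stage never changes another's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as tio
from . import __version__
from .enrichment import ora
from .expression import FilterConfig, filter_genes, log_normalize, pca_coordinates, select_degs, tmm_factors
from .ntp import NTPConfig, build_templates, ntp_classify, subtype_survival
from .signatures import (
    DEFAULT_TMB_CUTOFF,
    assign_quartiles,
    classify_carriers,
    classify_tmb,
    derive_signatures,
    evaluate_signature,
    stratify_by_pathway,
    summarize_alterations,
    SignatureResult,
)
from .simulate import ExpressionConfig, SimulationConfig, simulate_cohort
from .survival import NOT_REACHED, km_fit, sample_from_frame
from .trial import tabulate_responses

logger = logging.getLogger("trialomics")

__all__ = ["RunConfig", "run_pipeline", "report"]

_ALL_STAGES = ("simulate", "trial_stats", "survival", "signatures", "deg", "subtype", "enrich")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    # input paths (unused when the simulate stage is enabled)
    clinical_path: Path | None = None
    alterations_path: Path | None = None
    tmb_path: Path | None = None
    counts_path: Path | None = None
    markers_path: Path | None = None
    gmt_path: Path | None = None
    # thresholds
    tmb_cutoff: float = DEFAULT_TMB_CUTOFF
    fc_threshold: float = 2.5
    p_threshold: float = 0.0128
    fdr_threshold: float = 0.05
    n_permutations: int = 1000
    subcohort: str = "MSS"
    pathway: str | None = None
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if "simulate" not in self.stages:
            needed = {
                "trial_stats": [self.clinical_path],
                "survival": [self.clinical_path],
                "signatures": [self.clinical_path, self.alterations_path, self.tmb_path],
                "deg": [self.counts_path, self.clinical_path],
                "subtype": [self.counts_path, self.markers_path],
            }
            for stage, paths in needed.items():
                if stage in self.stages:
                    for p in paths:
                        if p is None:
                            raise ValueError(f"stage {stage!r} needs an input path")
                        if not Path(p).exists():
                            raise FileNotFoundError(f"stage {stage!r}: missing input {p}")
        if "enrich" in self.stages and self.gmt_path is not None:
            if not Path(self.gmt_path).exists():
                raise FileNotFoundError(f"missing GMT file {self.gmt_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s) {sorted(bad)}")
        for key in list(raw):
            if key.endswith("_path"):
                raw[key] = Path(raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big") % (2**31)
    return (seed ^ h) % (2**31)


def _fmt_median(m: float) -> str:
    return "NR" if math.isinf(m) else f"{m:.2f}"


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order; return the manifest.

    A stage failure is recorded and halts every downstream stage; the
    manifest (also written to ``manifest.json``) carries enough parameter
    echo to re-run the pipeline identically.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "tmb_cutoff": config.tmb_cutoff,
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "fdr_threshold": config.fdr_threshold,
            "n_permutations": config.n_permutations,
            "subcohort": config.subcohort,
        },
        "stages": {},
    }
    halted = False
    state: dict[str, Any] = {}

    def run_stage(name, fn):
        nonlocal halted
        if name not in config.stages:
            return
        if halted:
            manifest["stages"][name] = {"status": "skipped (upstream failure)"}
            return
        logger.info("stage %s: seed=%d", name, _stage_seed(config.seed, name))
        try:
            outputs = fn()
            manifest["stages"][name] = {"status": "ok", "outputs": outputs}
        except Exception as exc:  # halt downstream, keep the record
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": f"failed: {exc}"}
            halted = True

    # ----- simulate / load -------------------------------------------------
    def stage_simulate():
        sim_kwargs = dict(config.simulation)
        if "expression" in sim_kwargs:
            sim_kwargs["expression"] = ExpressionConfig(**sim_kwargs["expression"])
        sim_cfg = SimulationConfig(seed=_stage_seed(config.seed, "simulate"), **sim_kwargs)
        cohort = simulate_cohort(sim_cfg)
        state["clinical"] = cohort.clinical
        state["alterations"] = cohort.alterations
        state["counts"] = cohort.counts
        state["markers"] = cohort.ground_truth["marker_table"]
        tio.write_clinical(cohort.clinical, outdir / "clinical.tsv")
        tio.write_alterations(
            cohort.alterations, outdir / "alterations.tsv", outdir / "tmb.tsv"
        )
        tio.write_counts(cohort.counts, outdir / "counts.tsv")
        truth = {
            "resistance_genes": cohort.ground_truth["resistance_genes"],
            "sensitivity_genes": cohort.ground_truth["sensitivity_genes"],
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return ["clinical.tsv", "alterations.tsv", "tmb.tsv", "counts.tsv",
                "ground_truth.json"]

    run_stage("simulate", stage_simulate)

    def ensure(name, loader):
        if name not in state:
            state[name] = loader()
        return state[name]

    def load_clinical():
        return tio.read_clinical(config.clinical_path)

    def load_alterations():
        return tio.read_alterations(config.alterations_path, config.tmb_path)

    def load_counts():
        return tio.read_counts(config.counts_path)

    # ----- trial stats ------------------------------------------------------
    def stage_trial():
        clinical = ensure("clinical", load_clinical)
        summary = tabulate_responses(clinical)
        orr = summary.orr_interval()
        dcr = summary.dcr_interval()
        df = pd.DataFrame(
            [
                {"measure": "ORR", "count": summary.orr_count, "n": summary.n_total,
                 "percent": 100 * orr.estimate,
                 "ci_low": 100 * orr.lower, "ci_high": 100 * orr.upper},
                {"measure": "DCR", "count": summary.dcr_count, "n": summary.n_total,
                 "percent": 100 * dcr.estimate,
                 "ci_low": 100 * dcr.lower, "ci_high": 100 * dcr.upper},
            ]
        )
        state["trial_summary"] = summary
        tio.write_results(df, outdir, prefix="trial_stats")
        return ["trial_stats.tsv"]

    run_stage("trial_stats", stage_trial)

    # ----- survival by MSI status -------------------------------------------
    def stage_survival():
        clinical = ensure("clinical", load_clinical)
        out = []
        for status, grp in clinical.data.groupby("msi_status"):
            curve = km_fit(sample_from_frame(grp))
            df = pd.DataFrame(
                {"time": curve.times, "at_risk": curve.at_risk,
                 "events": curve.events, "survival": curve.survival}
            )
            fname = f"km_{status}.tsv"
            tio.write_results(df, outdir, prefix=f"km_{status}")
            out.append(fname)
        return out

    run_stage("survival", stage_survival)

    # ----- signatures -------------------------------------------------------
    def stage_signatures():
        clinical = ensure("clinical", load_clinical)
        alterations = ensure("alterations", load_alterations)
        profiled = set(alterations.tmb.index)
        sub = clinical.data[
            (clinical.data["msi_status"] == config.subcohort)
            & clinical.data["patient_id"].isin(profiled)
        ] if config.subcohort else clinical.data
        sub_ids = list(sub["patient_id"])
        quartiles = assign_quartiles(clinical, sub_ids)
        res, sens = derive_signatures(alterations, quartiles)
        res_flags = classify_carriers(alterations, res, sub_ids)
        sens_flags = classify_carriers(alterations, sens, sub_ids)
        sub_table = clinical.subset(sub_ids)
        comparisons = {
            "RES_full": evaluate_signature(sub_table, res_flags),
            "RES_wo_Q1": evaluate_signature(
                sub_table, res_flags, "drop_Q1_positives", quartiles
            ),
            "SENS_full": evaluate_signature(sub_table, sens_flags),
            "SENS_wo_Q4": evaluate_signature(
                sub_table, sens_flags, "drop_Q4_positives", quartiles
            ),
        }
        result = SignatureResult(
            res_genes=res, sens_genes=sens,
            res_flags=res_flags, sens_flags=sens_flags, comparisons=comparisons,
        )
        state["signature_result"] = result
        state["quartiles"] = quartiles
        files = tio.write_results(result, outdir, prefix="signatures")
        # TMB stratification within the subcohort
        tmb_cls = classify_tmb(alterations.tmb.reindex(sub_ids), config.tmb_cutoff)
        tmb_flags = tmb_cls.labels == "high"
        comp = evaluate_signature(sub_table, tmb_flags)
        tmb_df = pd.DataFrame(
            [{"n_high": comp.n_positive, "n_low": comp.n_negative,
              "median_high": comp.median_positive, "median_low": comp.median_negative,
              "p_value": comp.logrank.p_value if comp.logrank else float("nan")}]
        )
        tio.write_results(tmb_df, outdir, prefix="tmb_stratification")
        out = [f"signatures_{k}.tsv" for k in files] + ["tmb_stratification.tsv"]
        if config.pathway and config.gmt_path:
            gmt = tio.read_gmt(config.gmt_path)
            strat = stratify_by_pathway(
                alterations, gmt[config.pathway], sub_table,
                pathway_name=config.pathway, tmb_cutoff=config.tmb_cutoff,
            )
            pdf = pd.DataFrame(
                [{"pathway": strat.pathway,
                  "n_mut": int((strat.labels == "MUT").sum()),
                  "n_wt": int((strat.labels == "WT").sum()),
                  "median_mut": strat.median_mut, "median_wt": strat.median_wt,
                  "logrank_p": strat.logrank.p_value, "fisher_p": strat.fisher_p}]
            )
            tio.write_results(pdf, outdir, prefix="pathway_stratification")
            out.append("pathway_stratification.tsv")
        summary = summarize_alterations(alterations)
        tio.write_results(summary, outdir, prefix="alteration_summary")
        out.append("alteration_summary.json")
        return out

    run_stage("signatures", stage_signatures)

    # ----- differential expression ------------------------------------------
    def stage_deg():
        clinical = ensure("clinical", load_clinical)
        counts = ensure("counts", load_counts)
        filtered = filter_genes(counts, FilterConfig())
        factors = tmm_factors(filtered)
        norm = log_normalize(filtered, factors)
        state["normalized"] = norm
        quartiles = state.get("quartiles")
        if quartiles is None:
            profiled = [p for p in clinical.patient_ids if p in set(norm.samples)]
            quartiles = assign_quartiles(clinical, profiled)
        group_good = [p for p in quartiles.patients("Q4") if p in norm.samples]
        group_poor = [p for p in quartiles.patients("Q1") if p in norm.samples]
        result = select_degs(
            norm, group_good, group_poor,
            fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
        )
        state["deg_result"] = result
        tio.write_results(result, outdir, prefix="deg")
        scores, fractions = pca_coordinates(norm)
        tio.write_results(scores.rename_axis("sample").reset_index(), outdir, prefix="pca")
        return ["deg_deg.tsv", "pca.tsv"]

    run_stage("deg", stage_deg)

    # ----- subtype ----------------------------------------------------------
    def stage_subtype():
        counts = ensure("counts", load_counts)
        if "normalized" not in state:
            filtered = filter_genes(counts, FilterConfig())
            state["normalized"] = log_normalize(filtered, tmm_factors(filtered))
        norm = state["normalized"]
        if "markers" not in state:
            state["markers"] = tio.read_markers(config.markers_path)
        markers = state["markers"]
        templates = build_templates(markers, mode="one_vs_rest")
        calls = ntp_classify(
            norm, templates,
            NTPConfig(
                n_permutations=config.n_permutations,
                fdr_threshold=config.fdr_threshold,
                seed=_stage_seed(config.seed, "subtype"),
            ),
        )
        state["subtype_calls"] = calls
        tio.write_results(calls, outdir, prefix="subtype")
        out = ["subtype_subtype_calls.tsv"]
        if "clinical" in state and "signature_result" in state:
            per_class = subtype_survival(
                calls, state["clinical"], state["signature_result"].res_flags
            )
            rows = [
                {"class": cls, "n_positive": c.n_positive, "n_negative": c.n_negative,
                 "median_positive": c.median_positive,
                 "median_negative": c.median_negative,
                 "p_value": c.logrank.p_value if c.logrank else float("nan")}
                for cls, c in per_class.items()
            ]
            tio.write_results(pd.DataFrame(rows), outdir, prefix="subtype_survival")
            out.append("subtype_survival.tsv")
        return out

    run_stage("subtype", stage_subtype)

    # ----- enrichment -------------------------------------------------------
    def stage_enrich():
        if config.gmt_path is None:
            manifest["stages"]["enrich"] = {"status": "skipped (no GMT supplied)"}
            return []
        gmt = tio.read_gmt(config.gmt_path)
        if "deg_result" in state:
            norm = state["normalized"]
            query = state["deg_result"].selected_genes
            universe = norm.genes
        elif "signature_result" in state:
            query = sorted(state["signature_result"].res_genes)
            alterations = state["alterations"]
            universe = sorted(set(alterations.records["gene"]))
        else:
            raise ValueError("enrich stage needs a DEG or signature result upstream")
        if not query:
            manifest["stages"]["enrich"] = {"status": "skipped (empty query)"}
            return []
        table = ora(query, gmt, universe)
        tio.write_results(table, outdir, prefix="enrichment")
        return ["enrichment.tsv"]

    run_stage("enrich", stage_enrich)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def report(manifest: dict[str, Any], outdir: str | Path) -> str:
    """Render a deterministic text summary from a completed manifest.

    Every number is read back from the stage output files, so the report
    is traceable to (and never diverges from) what the stages wrote.
    """
    outdir = Path(outdir)
    lines = ["# Analysis report", f"seed: {manifest.get('seed')}", ""]
    stages = manifest.get("stages", {})
    if not stages:
        lines.append("No stages were run.")
        return "\n".join(lines) + "\n"
    for name in _ALL_STAGES:
        if name not in stages:
            continue
        status = stages[name].get("status", "unknown")
        lines.append(f"## {name} [{status}]")
        if status != "ok":
            lines.append("(no outputs)")
            lines.append("")
            continue
        if name == "trial_stats":
            df = pd.read_csv(outdir / "trial_stats.tsv", sep="\t")
            for _, row in df.iterrows():
                lines.append(
                    f"{row['measure']}: {row['count']}/{row['n']} = "
                    f"{row['percent']:.1f}% (95% CI {row['ci_low']:.1f} to "
                    f"{row['ci_high']:.1f})"
                )
        elif name == "signatures":
            genes = pd.read_csv(outdir / "signatures_genes.tsv", sep="\t")
            n_res = int((genes["signature"] == "RES").sum())
            n_sens = int((genes["signature"] == "SENS").sum())
            lines.append(f"RES signature: {n_res} genes; SENS signature: {n_sens} genes")
            comps = pd.read_csv(outdir / "signatures_comparisons.tsv", sep="\t")
            for _, row in comps.iterrows():
                mp = row["median_positive"]
                mn = row["median_negative"]
                mp = "NR" if math.isinf(float(mp)) else f"{float(mp):.2f}"
                mn = "NR" if math.isinf(float(mn)) else f"{float(mn):.2f}"
                lines.append(
                    f"{row['comparison']}: n+={row['n_positive']} n-={row['n_negative']} "
                    f"median+ {mp} vs median- {mn} (log-rank p={row['p_value']:.4g})"
                )
        elif name == "deg":
            df = pd.read_csv(outdir / "deg_deg.tsv", sep="\t")
            sel = df[df["selected"]]
            lines.append(
                f"DEGs: {len(sel)} selected ({int((sel['fold_change'] > 0).sum())} up, "
                f"{int((sel['fold_change'] < 0).sum())} down)"
            )
        elif name == "subtype":
            df = pd.read_csv(outdir / "subtype_subtype_calls.tsv", sep="\t")
            counts = df["final_label"].value_counts()
            parts = ", ".join(f"{k}: {v}" for k, v in sorted(counts.items()))
            lines.append(f"subtype calls: {parts}")
        elif name == "enrich" and (outdir / "enrichment.tsv").exists():
            df = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
            sig = df[df["adjusted_p"] < 0.05]
            lines.append(f"enriched sets at BH < 0.05: {len(sig)} of {len(df)}")
        lines.append("")
    return "\n".join(lines) + "\n"
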