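"""PFS-quartile genomic resistance/sensitivity signature derivation.

The central correlative procedure: rank MSS patients by observed
progression-free survival, split off the worst quartile (Q1) and the best
quartile (Q4), and call a gene part of the resistance (RES) signature if it
is altered in at least one Q1 patient and in no Q4 patient — and part of
the sensitivity (SENS) signature under the mirrored rule. Patients are then
labelled carriers (+) if they harbour any alteration in any signature gene,
and the +/- groups are compared by Kaplan-Meier curves and the log-rank
test, optionally holding out the derivation quartile from the carrier group
(the "without 25th/75th percentile" evaluation) to blunt the circularity of
testing a signature on the patients that defined it.

Also here: TMB high/low dichotomisation (default cut-off 10.4 mutations/Mb)
and pathway MUT/WT stratification with a Fisher exact test against TMB
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io import AlterationTable, ClinicalTable
from .survival import NOT_REACHED, LogRankResult, km_fit, km_median, logrank_test

__all__ = [
    "QuartileAssignment",
    "SignatureResult",
    "TMBClassification",
    "PathwayStratification",
    "assign_quartiles",
    "derive_signatures",
    "classify_carriers",
    "evaluate_signature",
    "classify_tmb",
    "stratify_by_pathway",
    "summarize_alterations",
    "DEFAULT_TMB_CUTOFF",
]

DEFAULT_TMB_CUTOFF = 10.4  # mutations/Mb

Holdout = Literal["none", "drop_Q1_positives", "drop_Q4_positives"]


@dataclass(frozen=True)
class QuartileAssignment:
    """Quartile labels Q1..Q4 over a survival-ranked subcohort.

    Q1 holds the floor(n/4) patients with the lowest PFS rank, Q4 the
    floor(n/4) with the highest; the middle splits into Q2/Q3 with any
    remainder patient going to Q2 (so n=49 gives 12/13/12/12). Ties in PFS
    break by (event before censored, then patient id) for determinism.
    """

    labels: pd.Series  # index patient_id, values in {"Q1","Q2","Q3","Q4"}

    @property
    def sizes(self) -> dict[str, int]:
        counts = self.labels.value_counts()
        return {q: int(counts.get(q, 0)) for q in ("Q1", "Q2", "Q3", "Q4")}

    def patients(self, quartile: str) -> list[str]:
        return list(self.labels.index[self.labels == quartile])


@dataclass(frozen=True)
class SignatureResult:
    """Derived gene sets, per-patient carrier flags, and survival comparisons."""

    res_genes: frozenset[str]
    sens_genes: frozenset[str]
    res_flags: pd.Series  # index patient_id, bool (True = RES+)
    sens_flags: pd.Series
    comparisons: dict[str, "StratifiedComparison"] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        genes = pd.DataFrame(
            [("RES", g) for g in sorted(self.res_genes)]
            + [("SENS", g) for g in sorted(self.sens_genes)],
            columns=["signature", "gene"],
        )
        flags = pd.DataFrame(
            {
                "patient_id": self.res_flags.index,
                "res_carrier": ["+" if v else "-" for v in self.res_flags],
                "sens_carrier": ["+" if v else "-" for v in self.sens_flags],
            }
        )
        rows = []
        for name, comp in sorted(self.comparisons.items()):
            rows.append(
                {
                    "comparison": name,
                    "n_positive": comp.n_positive,
                    "n_negative": comp.n_negative,
                    "median_positive": comp.median_positive,
                    "median_negative": comp.median_negative,
                    "chi_square": comp.logrank.chi_square if comp.logrank else np.nan,
                    "p_value": comp.logrank.p_value if comp.logrank else np.nan,
                    "degenerate": comp.degenerate,
                }
            )
        stats = pd.DataFrame(
            rows,
            columns=[
                "comparison", "n_positive", "n_negative", "median_positive",
                "median_negative", "chi_square", "p_value", "degenerate",
            ],
        )
        return {"genes": genes, "carriers": flags, "comparisons": stats}


@dataclass(frozen=True)
class StratifiedComparison:
    """Two-group survival comparison between carrier (+) and non-carrier (-)."""

    n_positive: int
    n_negative: int
    median_positive: float
    median_negative: float
    logrank: LogRankResult | None
    degenerate: bool = False


@dataclass(frozen=True)
class TMBClassification:
    """Per-patient TMB high/low labels; high iff tmb >= cutoff."""

    labels: pd.Series  # index patient_id, values "high"/"low"
    cutoff: float


@dataclass(frozen=True)
class PathwayStratification:
    """MUT/WT labels for a pathway plus survival and TMB-association tests."""

    pathway: str
    labels: pd.Series  # index patient_id, values "MUT"/"WT"
    logrank: LogRankResult
    median_mut: float
    median_wt: float
    contingency: np.ndarray  # 2x2: rows MUT/WT, cols TMB high/low
    fisher_p: float
    fisher_degenerate: bool = False


def assign_quartiles(
    clinical: ClinicalTable,
    subcohort: Callable[[pd.Series], bool] | Iterable[str] | None = None,
) -> QuartileAssignment:
    """Partition a subcohort into PFS quartiles by rank.

    ``subcohort`` may be a predicate over clinical rows, an iterable of
    patient ids, or None for the full table. Refuses subcohorts of fewer
    than 8 patients, where quartiles are meaningless.
    """
    df = clinical.data
    if subcohort is None:
        sub = df
    elif callable(subcohort):
        sub = df[df.apply(subcohort, axis=1)]
    else:
        wanted = set(subcohort)
        sub = df[df["patient_id"].isin(wanted)]
    n = len(sub)
    if n < 8:
        raise ValueError(f"subcohort has {n} patients; need >= 8 for quartiles")
    # rank by PFS; ties: observed events before censored, then id lexicographic
    order = sub.sort_values(
        by=["pfs_months", "pfs_event", "patient_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    q = n // 4
    middle = n - 2 * q
    n_q2 = middle - middle // 2  # remainder patient lands in Q2
    labels = (
        ["Q1"] * q + ["Q2"] * n_q2 + ["Q3"] * (middle - n_q2) + ["Q4"] * q
    )
    return QuartileAssignment(
        labels=pd.Series(labels, index=list(order["patient_id"]), name="quartile")
    )


def derive_signatures(
    alterations: AlterationTable, quartiles: QuartileAssignment
) -> tuple[frozenset[str], frozenset[str]]:
    """Derive (res_genes, sens_genes) by quartile set difference.

    RES = genes altered in >= 1 Q1 patient and in 0 Q4 patients;
    SENS = genes altered in >= 1 Q4 patient and in 0 Q1 patients.
    A gene altered in both quartiles joins neither, so the sets are
    disjoint by construction.
    """
    q1_genes = alterations.altered_genes(quartiles.patients("Q1"))
    q4_genes = alterations.altered_genes(quartiles.patients("Q4"))
    return frozenset(q1_genes - q4_genes), frozenset(q4_genes - q1_genes)


def classify_carriers(
    alterations: AlterationTable, genes: Iterable[str], patients: Iterable[str]
) -> pd.Series:
    """Boolean carrier flag per patient: True iff any alteration in any gene."""
    carriers = alterations.patients_with_any(genes)
    ids = list(patients)
    return pd.Series([p in carriers for p in ids], index=ids, name="carrier")


def _median_of(sample) -> float:
    return km_median(km_fit(sample)) if len(sample) else NOT_REACHED


def evaluate_signature(
    clinical: ClinicalTable,
    flags: pd.Series,
    holdout: Holdout = "none",
    quartiles: QuartileAssignment | None = None,
) -> StratifiedComparison:
    """Compare carrier (+) vs non-carrier (-) PFS, optionally with holdout.

    ``drop_Q1_positives`` removes Q1 patients from the carrier group only
    (the non-carrier group is untouched), removing the patients whose short
    PFS defined the resistance signature; ``drop_Q4_positives`` is the
    mirrored rule for the sensitivity signature. Returns a degenerate
    result when either group is empty after the holdout.
    """
    if holdout != "none" and quartiles is None:
        raise ValueError("holdout evaluation requires a quartile assignment")
    df = clinical.data.set_index("patient_id").loc[flags.index]
    pos_ids = list(flags.index[flags])
    neg_ids = list(flags.index[~flags])
    if holdout == "drop_Q1_positives":
        drop = set(quartiles.patients("Q1"))
        pos_ids = [p for p in pos_ids if p not in drop]
    elif holdout == "drop_Q4_positives":
        drop = set(quartiles.patients("Q4"))
        pos_ids = [p for p in pos_ids if p not in drop]

    def sample(ids):
        rows = df.loc[ids]
        return list(zip(rows["pfs_months"].astype(float), rows["pfs_event"].astype(bool)))

    if not pos_ids or not neg_ids:
        return StratifiedComparison(
            n_positive=len(pos_ids), n_negative=len(neg_ids),
            median_positive=_median_of(sample(pos_ids)) if pos_ids else NOT_REACHED,
            median_negative=_median_of(sample(neg_ids)) if neg_ids else NOT_REACHED,
            logrank=None, degenerate=True,
        )
    pos, neg = sample(pos_ids), sample(neg_ids)
    result = logrank_test(pos, neg)
    return StratifiedComparison(
        n_positive=len(pos_ids), n_negative=len(neg_ids),
        median_positive=_median_of(pos), median_negative=_median_of(neg),
        logrank=result, degenerate=result.degenerate,
    )


def classify_tmb(tmb: pd.Series, cutoff: float = DEFAULT_TMB_CUTOFF) -> TMBClassification:
    """Dichotomise TMB at the cutoff (high iff tmb >= cutoff, boundary high)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if tmb.isna().any():
        missing = list(tmb.index[tmb.isna()])
        raise ValueError(f"TMB missing for patient(s) {missing[:3]}")
    labels = pd.Series(
        np.where(tmb >= cutoff, "high", "low"), index=tmb.index, name="tmb_class"
    )
    return TMBClassification(labels=labels, cutoff=cutoff)


def stratify_by_pathway(
    alterations: AlterationTable,
    pathway_genes: Iterable[str],
    clinical: ClinicalTable,
    pathway_name: str = "pathway",
    tmb_cutoff: float = DEFAULT_TMB_CUTOFF,
) -> PathwayStratification:
    """MUT/WT stratification by pathway membership.

    A patient is MUT iff they carry >= 1 alteration in >= 1 pathway gene.
    Returns the MUT-vs-WT log-rank comparison of PFS and the 2x2
    pathway-status x TMB-class table with a two-sided Fisher exact p.
    Degenerate 2x2 margins (a row or column of zeros) yield p = 1, flagged.
    """
    genes = set(pathway_genes)
    if not genes:
        raise ValueError("pathway gene set must be non-empty")
    ids = clinical.patient_ids
    flags = classify_carriers(alterations, genes, ids)
    labels = pd.Series(
        np.where(flags, "MUT", "WT"), index=flags.index, name="pathway_status"
    )
    df = clinical.data.set_index("patient_id")
    mut = df.loc[labels.index[labels == "MUT"]]
    wt = df.loc[labels.index[labels == "WT"]]

    def sample(rows):
        return list(zip(rows["pfs_months"].astype(float), rows["pfs_event"].astype(bool)))

    if len(mut) and len(wt):
        lr = logrank_test(sample(mut), sample(wt))
    else:
        lr = LogRankResult(0.0, 1, 1.0, (0.0, 0.0), (0.0, 0.0), degenerate=True)

    tmb = alterations.tmb.reindex(ids)
    tmb_cls = classify_tmb(tmb, tmb_cutoff)
    table = np.zeros((2, 2), dtype=np.int64)
    for i, status in enumerate(("MUT", "WT")):
        for j, level in enumerate(("high", "low")):
            table[i, j] = int(
                ((labels == status) & (tmb_cls.labels == level)).sum()
            )
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        fisher_p = 1.0
    else:
        _, fisher_p = fisher_exact(table, alternative="two-sided")
    return PathwayStratification(
        pathway=pathway_name,
        labels=labels,
        logrank=lr,
        median_mut=_median_of(sample(mut)) if len(mut) else NOT_REACHED,
        median_wt=_median_of(sample(wt)) if len(wt) else NOT_REACHED,
        contingency=table,
        fisher_p=float(fisher_p),
        fisher_degenerate=degenerate,
    )


def summarize_alterations(alterations: AlterationTable) -> dict[str, float]:
    """Totals by alteration class, distinct genes, and mean alterations/patient."""
    rec = alterations.records  # already deduplicated on load
    by_class = rec["alteration_class"].value_counts()
    n_patients = rec["patient_id"].nunique()
    return {
        "n_alterations": int(len(rec)),
        "n_genes": int(rec["gene"].nunique()),
        "n_patients": int(n_patients),
        "n_SNV": int(by_class.get("SNV", 0)),
        "n_INDEL": int(by_class.get("INDEL", 0)),
        "n_CNV": int(by_class.get("CNV", 0)),
        "n_LOH": int(by_class.get("LOH", 0)),
        "mean_per_patient": float(len(rec) / n_patients) if n_patients else 0.0,
    }
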