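"""Nearest-template-prediction (NTP) molecular subtyping with a
permutation null and a per-sample FDR unclassified rule.

Each subtype is a signed template: +1 for marker genes up-regulated in the
class, -1 for down-regulated ones. A sample's similarity to a template is
the Pearson correlation between its expression over the template genes and
the signed template vector (affine-invariant in the sample, so absolute
expression scale never matters). The best class is the one with the
highest similarity; significance comes from a permutation null in which
random gene subsets of the same size are drawn from the measured gene
universe, and the p-value is the fraction of draws achieving at least the
observed similarity (with the 1/(n_permutations+1) floor convention).
Benjamini-Hochberg adjustment across samples yields an FDR; samples with
FDR >= the threshold (default 0.05) stay UNCLASSIFIED.

Templates can be built from a signed marker table either one-vs-rest (each
class uses its own up/down rows, e.g. a four-class CMS panel) or pairwise
(two intrinsic classes, where an up-marker of class A must also be a
down-marker of class B — the construction used for iCMS2/iCMS3 epithelial
templates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .enrichment import bh_adjust
from .io import ClinicalTable, MarkerTable
from .signatures import StratifiedComparison, evaluate_signature
from .expression import NormalizedMatrix

__all__ = [
    "UNCLASSIFIED",
    "SubtypeTemplate",
    "SubtypeCall",
    "NTPConfig",
    "build_templates",
    "ntp_classify",
    "subtype_survival",
]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class SubtypeTemplate:
    """Signed marker vector for one subtype class (+1 up, -1 down)."""

    label: str
    genes: tuple[str, ...]
    signs: np.ndarray  # +1/-1 aligned with genes

    def __post_init__(self) -> None:
        if len(self.genes) < 5:
            raise ValueError(f"template {self.label!r} has < 5 markers")
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"template {self.label!r} has duplicate genes")


@dataclass(frozen=True)
class NTPConfig:
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    similarity: Literal["pearson", "cosine"] = "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("need >= 100 permutations")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SubtypeCall:
    """Per-sample classification table.

    ``table`` columns: best_class, similarity_<class>..., p_value, fdr,
    final_label (the best class, or UNCLASSIFIED when fdr >= threshold).
    """

    table: pd.DataFrame
    config: NTPConfig

    def labels(self) -> pd.Series:
        return self.table["final_label"]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"subtype_calls": self.table.rename_axis("sample").reset_index()}


def build_templates(
    markers: MarkerTable, mode: Literal["one_vs_rest", "pairwise_icms"] = "one_vs_rest"
) -> list[SubtypeTemplate]:
    """Build signed templates from a marker table.

    one_vs_rest: each class contributes its own up/down rows.
    pairwise_icms: exactly two classes; a gene is a +1 marker of class A
    iff it is up in A and down in B (and symmetrically); genes up or down
    in both classes are excluded. A gene listed with both directions in
    one class is an error.
    """
    df = markers.data
    for (gene, cls), grp in df.groupby(["gene", "class"]):
        if grp["direction"].nunique() > 1:
            raise ValueError(f"gene {gene!r} has contradictory directions in class {cls!r}")
    classes = markers.classes
    if len(classes) < 2:
        raise ValueError("marker table must cover >= 2 classes")
    templates = []
    if mode == "one_vs_rest":
        for cls in classes:
            sub = df[df["class"] == cls]
            genes = tuple(sub["gene"])
            signs = np.where(sub["direction"].to_numpy() == "up", 1.0, -1.0)
            templates.append(SubtypeTemplate(label=cls, genes=genes, signs=signs))
    elif mode == "pairwise_icms":
        if len(classes) != 2:
            raise ValueError("pairwise_icms mode needs exactly 2 classes")
        a, b = classes
        direction = {
            cls: df[df["class"] == cls].set_index("gene")["direction"] for cls in classes
        }
        for this, other in ((a, b), (b, a)):
            genes, signs = [], []
            for gene, d in direction[this].items():
                d_other = direction[other].get(gene)
                opposite = "down" if d == "up" else "up"
                # marker counts only when the other class disagrees (or is silent
                # in the other direction); same-direction genes are uninformative
                if d_other == d:
                    continue
                if d_other == opposite or d_other is None:
                    genes.append(gene)
                    signs.append(1.0 if d == "up" else -1.0)
            templates.append(
                SubtypeTemplate(label=this, genes=tuple(genes), signs=np.asarray(signs))
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return templates


def _similarity(x: np.ndarray, signs: np.ndarray, kind: str) -> float:
    """Similarity between a sample's expression slice and a signed template."""
    if kind == "pearson":
        if np.std(x) == 0 or np.std(signs) == 0:
            return np.nan
        return float(np.corrcoef(x, signs)[0, 1])
    # cosine on raw values (scale- but not shift-invariant)
    nx, ns = np.linalg.norm(x), np.linalg.norm(signs)
    if nx == 0 or ns == 0:
        return np.nan
    return float(np.dot(x, signs) / (nx * ns))


def ntp_classify(
    norm: NormalizedMatrix,
    templates: Sequence[SubtypeTemplate],
    config: NTPConfig = NTPConfig(),
) -> SubtypeCall:
    """Classify every sample by nearest template with a permutation FDR.

    Requires >= 50% of each template's genes to be present in the matrix.
    The permutation stream is seeded per sample index so results are
    deterministic and permuting sample order permutes outputs identically.
    """
    values = norm.values
    universe = values.index.to_numpy()
    restricted = []
    for tpl in templates:
        present = [g for g in tpl.genes if g in values.index]
        if len(present) < 0.5 * len(tpl.genes):
            raise ValueError(
                f"template {tpl.label!r}: only {len(present)}/{len(tpl.genes)} "
                "marker genes measured"
            )
        keep = [i for i, g in enumerate(tpl.genes) if g in values.index]
        restricted.append(
            SubtypeTemplate(
                label=tpl.label,
                genes=tuple(tpl.genes[i] for i in keep),
                signs=tpl.signs[keep],
            )
        )

    rows = []
    labels = [t.label for t in restricted]
    root = np.random.SeedSequence(config.seed)
    for sample in values.columns:
        col = values[sample]
        sims = {
            t.label: _similarity(col.loc[list(t.genes)].to_numpy(), t.signs,
                                 config.similarity)
            for t in restricted
        }
        if all(np.isnan(s) for s in sims.values()):
            warnings.warn(f"sample {sample!r}: similarity undefined (constant expression)")
            rows.append({"sample": sample, "best_class": UNCLASSIFIED,
                         **{f"similarity_{k}": np.nan for k in labels},
                         "p_value": 1.0})
            continue
        best = max(labels, key=lambda k: (-np.inf if np.isnan(sims[k]) else sims[k]))
        best_sim = sims[best]
        tpl = restricted[labels.index(best)]
        m = len(tpl.genes)
        # per-sample stream keyed by a stable hash of the sample id, so the
        # draw for one sample never depends on the others
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _stable_hash(sample)])
        )
        count = 0
        expr_all = values[sample].to_numpy()
        for _ in range(config.n_permutations):
            idx = rng.choice(len(universe), size=m, replace=False)
            s = _similarity(expr_all[idx], tpl.signs, config.similarity)
            if not np.isnan(s) and s >= best_sim - 1e-12:
                count += 1
        p = max(count, 1) / (config.n_permutations + 1)
        rows.append({"sample": sample, "best_class": best,
                     **{f"similarity_{k}": sims[k] for k in labels},
                     "p_value": p})

    table = pd.DataFrame(rows).set_index("sample")
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["final_label"] = np.where(
        (table["fdr"] < config.fdr_threshold) & (table["best_class"] != UNCLASSIFIED),
        table["best_class"],
        UNCLASSIFIED,
    )
    return SubtypeCall(table=table, config=config)


def _stable_hash(text: str) -> int:
    """Platform-stable 31-bit hash of a string (builtin hash is salted)."""
    import hashlib

    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % (2**31)


def subtype_survival(
    calls: SubtypeCall,
    clinical: ClinicalTable,
    carrier_flags: pd.Series | None = None,
) -> dict[str, StratifiedComparison]:
    """Within-class carrier (+/-) survival comparisons.

    For each non-UNCLASSIFIED class, compares carriers vs non-carriers of
    ``carrier_flags`` (e.g. RES+ vs RES-) by Kaplan-Meier medians and
    log-rank. Classes with < 2 patients in either arm yield a degenerate
    result. With no flags, returns each class's own median under the key
    ``<class>`` with the full class as the positive group.
    """
    labels = calls.labels()
    shared = [p for p in labels.index if p in set(clinical.patient_ids)]
    out: dict[str, StratifiedComparison] = {}
    for cls in sorted(set(labels) - {UNCLASSIFIED}):
        members = [p for p in shared if labels[p] == cls]
        if not members:
            continue
        sub = clinical.subset(members)
        if carrier_flags is None:
            flags = pd.Series(True, index=members)
        else:
            flags = carrier_flags.reindex(members, fill_value=False).astype(bool)
        comp = evaluate_signature(sub, flags, holdout="none")
        if min(comp.n_positive, comp.n_negative) < 2 and carrier_flags is not None:
            comp = StratifiedComparison(
                n_positive=comp.n_positive, n_negative=comp.n_negative,
                median_positive=comp.median_positive,
                median_negative=comp.median_negative,
                logrank=None, degenerate=True,
            )
        out[cls] = comp
    return out
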