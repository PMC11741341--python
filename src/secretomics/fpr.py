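"""Control-calibrated hit calling for proximity-labeling secretome screens.

A proximity-labeling enrichment experiment has no universal log2-ratio
cutoff: the spread of non-specific background differs between runs.  The
calibration implemented here uses two annotation-derived control sets —
positive controls (PC, annotated secreted genes, expected enriched) and
negative controls (NC, annotated transcription factors, expected absent
from the secretome) — and sweeps candidate log2-ratio thresholds.  At each
threshold t the empirical false-positive rate is

    FPR(t) = n_NC(logFC >= t) / (n_NC(logFC >= t) + n_PC(logFC >= t))

and the calibrated threshold is the smallest t from which the FPR never
again exceeds the target (10% by default).  Hits must clear both this
ratio threshold and an adjusted-p cutoff.  Summaries of hit-list overlap
and top-k category composition are included for cross-contrast comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError
from .modstats import DiffTestTable

__all__ = [
    "ControlAnnotation",
    "FPRCurve",
    "HitTable",
    "OverlapSummary",
    "annotate_controls",
    "fpr_curve",
    "call_hits",
    "overlap_summary",
    "top_k_composition",
]


@dataclass
class ControlAnnotation:
    """Per-protein control labels: ``"PC"``, ``"NC"`` or ``"none"``.

    Proteins appearing in both source lists are ambiguous: they are labeled
    ``"none"`` and counted in ``n_ambiguous``.
    """

    labels: pd.Series
    n_ambiguous: int = 0
    pc_source: str = ""
    nc_source: str = ""

    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {k: int(c.get(k, 0)) for k in ("PC", "NC", "none")}


@dataclass
class FPRCurve:
    """Threshold sweep over the distinct control log2 ratios.

    ``curve`` columns: threshold (first row is -inf), n_pc_above,
    n_nc_above, fpr.  ``calibrated_threshold`` is None when no threshold
    meets the target.
    """

    curve: pd.DataFrame
    target_fpr: float
    calibrated_threshold: float | None


@dataclass
class HitTable:
    """All tested proteins with per-criterion flags; hits sorted first.

    ``table`` columns: logFC, p_adj, pass_p, pass_ratio, is_hit — ordered
    by (logFC descending, protein_id ascending).  ``hits`` is the ordered
    hit subset.
    """

    table: pd.DataFrame
    threshold: float
    alpha: float

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["is_hit"]]

    @property
    def hit_ids(self) -> list[str]:
        return list(self.hits.index)


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_shared: int
    jaccard: float
    pct_of_smaller: float


def annotate_controls(
    proteins,
    pc_list,
    nc_list,
    pc_source: str = "",
    nc_source: str = "",
) -> ControlAnnotation:
    """Label proteins by exact identifier match (case-insensitive) to the control lists."""
    pc = {str(g).casefold() for g in pc_list}
    nc = {str(g).casefold() for g in nc_list}
    both = pc & nc
    pc -= both
    nc -= both

    index = pd.Index(proteins)
    keys = [str(g).casefold() for g in index]
    labels = pd.Series(
        ["PC" if k in pc else "NC" if k in nc else "none" for k in keys],
        index=index, dtype=object,
    )
    n_ambiguous = sum(k in both for k in keys)
    return ControlAnnotation(labels, n_ambiguous, pc_source, nc_source)


def fpr_curve(
    test: DiffTestTable,
    ann: ControlAnnotation,
    target_fpr: float = 0.10,
) -> FPRCurve:
    """Empirical FPR sweep and threshold calibration from the control ratios.

    Candidate thresholds are the distinct control logFC values (the
    empirical FPR only changes there, so the sweep is exact) preceded by
    -inf.  ``FPR(t) = n_NC>=t / (n_NC>=t + n_PC>=t)``, defined as 0 when no
    control lies at or above t.  The calibrated threshold is the smallest
    candidate from which FPR(t') <= target for every candidate t' >= t —
    robust to non-monotone empirical curves.
    """
    if not 0.0 <= target_fpr <= 1.0:
        raise ConfigurationError("target_fpr must lie in [0, 1]")
    labels = ann.labels.reindex(test.table.index)
    lfc = test.logfc
    tested = lfc.notna()
    pc_lfc = lfc[tested & (labels == "PC")].to_numpy(dtype=float)
    nc_lfc = lfc[tested & (labels == "NC")].to_numpy(dtype=float)
    if pc_lfc.size == 0 or nc_lfc.size == 0:
        raise CalibrationError(
            "FPR calibration needs at least one PC and one NC among tested proteins"
        )

    thresholds = np.concatenate(
        [[-np.inf], np.unique(np.concatenate([pc_lfc, nc_lfc]))]
    )
    pc_sorted = np.sort(pc_lfc)
    nc_sorted = np.sort(nc_lfc)
    n_pc_above = pc_sorted.size - np.searchsorted(pc_sorted, thresholds, side="left")
    n_nc_above = nc_sorted.size - np.searchsorted(nc_sorted, thresholds, side="left")
    denom = n_pc_above + n_nc_above
    with np.errstate(invalid="ignore"):
        fpr = np.where(denom > 0, n_nc_above / np.maximum(denom, 1), 0.0)

    # smallest threshold from which the FPR never again exceeds the target
    suffix_max = np.maximum.accumulate(fpr[::-1])[::-1]
    ok = suffix_max <= target_fpr
    calibrated = float(thresholds[np.argmax(ok)]) if ok.any() else None

    curve = pd.DataFrame(
        {
            "threshold": thresholds,
            "n_pc_above": n_pc_above,
            "n_nc_above": n_nc_above,
            "fpr": fpr,
        }
    )
    return FPRCurve(curve, target_fpr, calibrated)


def call_hits(test: DiffTestTable, threshold: float, alpha: float = 0.05) -> HitTable:
    """Select enriched hits: adjusted p < alpha and logFC >= threshold.

    Only the enrichment direction counts — depleted proteins are never
    hits.  The output is ordered by logFC descending with ties broken by
    protein identifier ascending; per-criterion pass flags are retained for
    every tested protein.
    """
    t = test.table
    pass_p = t["p_adj"] < alpha
    pass_ratio = t["logFC"] >= threshold
    out = pd.DataFrame(
        {
            "logFC": t["logFC"],
            "p_adj": t["p_adj"],
            "pass_p": pass_p.fillna(False),
            "pass_ratio": pass_ratio.fillna(False),
        },
        index=t.index,
    )
    out["is_hit"] = out["pass_p"] & out["pass_ratio"]
    out = (
        out.assign(_pid=out.index.astype(str))
        .sort_values(["logFC", "_pid"], ascending=[False, True])
        .drop(columns="_pid")
    )
    return HitTable(out, threshold=float(threshold), alpha=float(alpha))


def overlap_summary(hits_a: HitTable, hits_b: HitTable) -> OverlapSummary:
    """Set overlap between two hit lists: shared count, Jaccard, fraction of the smaller."""
    a, b = set(hits_a.hit_ids), set(hits_b.hit_ids)
    shared = len(a & b)
    union = len(a | b)
    smaller = min(len(a), len(b))
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_shared=shared,
        jaccard=shared / union if union else 0.0,
        pct_of_smaller=shared / smaller if smaller else 0.0,
    )


def top_k_composition(
    hits: HitTable,
    categories: dict[str, str],
    k: int = 100,
) -> dict[str, float]:
    """Category fractions among the top-k hits (by the hit ordering).

    Uncategorized proteins count under ``"other"``; fractions sum to 1.
    ``k`` larger than the hit count uses all hits.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    top = hits.hit_ids[: min(k, len(hits.hit_ids))]
    if not top:
        return {}
    counts: dict[str, int] = {}
    for g in top:
        cat = categories.get(g, "other")
        counts[cat] = counts.get(cat, 0) + 1
    return {cat: n / len(top) for cat, n in counts.items()}
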