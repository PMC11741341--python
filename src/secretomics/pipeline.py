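"""End-to-end orchestration: reporter intensities to calibrated hit lists.

``run_pipeline`` chains the standard stages — impurity correction, quality
filtering, log2 transformation and normalization, moderated differential
tests per contrast, control-based FPR threshold calibration, and hit
calling — and returns every intermediate for inspection.

Normalization note: the differential tests run two-sample on
channel-centered log2 intensities (each channel's log2 values shifted so
the median of its protein-level log2 ratios to the plex average is zero).
The :class:`~secretomics.quant.RatioTable` versus the reference condition
is computed and median-normalized as well; its sample-mean ratios equal
the tested logFC up to the normalization offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fpr import ControlAnnotation, FPRCurve, HitTable, annotate_controls, call_hits, fpr_curve
from .modstats import Contrast, DiffTestTable, moderated_t
from .quant import (
    FilterReport,
    ImpurityMatrix,
    RatioTable,
    ReporterMatrix,
    StudyDesign,
    compute_log_ratios,
    correct_impurities,
    filter_proteins,
    median_normalize,
)

__all__ = ["PipelineResult", "normalized_log2_matrix", "run_pipeline"]


@dataclass
class PipelineResult:
    filtered: ReporterMatrix
    filter_report: FilterReport
    log2_normalized: pd.DataFrame
    ratios: RatioTable
    tests: dict[str, DiffTestTable]
    annotation: ControlAnnotation | None = None
    fpr_curves: dict[str, FPRCurve] = field(default_factory=dict)
    hit_tables: dict[str, HitTable] = field(default_factory=dict)


def normalized_log2_matrix(m: ReporterMatrix) -> pd.DataFrame:
    """Channel-centered log2 intensities.

    Each protein's log2 intensities are expressed relative to its own plex
    average; the per-channel median of those relative values is the
    channel's loading offset, which is subtracted from the raw log2 values.
    Centering is performed on ratios (not raw log2 intensities) so protein
    abundance differences do not leak into the channel offsets.
    """
    with np.errstate(divide="ignore"):
        log2i = np.log2(m.intensities)
    log2i = log2i.where(m.intensities > 0)
    relative = log2i.sub(log2i.mean(axis=1), axis=0)
    offsets = relative.median(axis=0)
    return log2i.sub(offsets, axis=1)


def run_pipeline(
    raw: ReporterMatrix,
    design: StudyDesign,
    contrasts: list[Contrast],
    impurity: ImpurityMatrix | None = None,
    pc_genes: list[str] | None = None,
    nc_genes: list[str] | None = None,
    min_unique_peptides: int = 2,
    target_fpr: float = 0.10,
    alpha: float = 0.05,
) -> PipelineResult:
    """Run the full quantitative analysis on one multiplexed experiment.

    When control gene lists are supplied, each contrast's ratio threshold is
    calibrated at ``target_fpr`` from the PC/NC logFC distributions and hits
    are called at (adjusted p < alpha, logFC >= threshold); contrasts whose
    calibration finds no admissible threshold get no hit table.
    """
    m = correct_impurities(raw, impurity) if impurity is not None else raw
    filtered, report = filter_proteins(m, min_unique_peptides=min_unique_peptides)
    log2n = normalized_log2_matrix(filtered)
    ratios = median_normalize(compute_log_ratios(filtered, design))

    tests = {
        c.name: moderated_t(log2n, design, c)
        for c in contrasts
    }

    annotation = None
    curves: dict[str, FPRCurve] = {}
    hit_tables: dict[str, HitTable] = {}
    if pc_genes is not None and nc_genes is not None:
        annotation = annotate_controls(filtered.protein_ids, pc_genes, nc_genes)
        for name, test in tests.items():
            curve = fpr_curve(test, annotation, target_fpr=target_fpr)
            curves[name] = curve
            if curve.calibrated_threshold is not None:
                hit_tables[name] = call_hits(test, curve.calibrated_threshold, alpha=alpha)

    return PipelineResult(
        filtered=filtered,
        filter_report=report,
        log2_normalized=log2n,
        ratios=ratios,
        tests=tests,
        annotation=annotation,
        fpr_curves=curves,
        hit_tables=hit_tables,
    )
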