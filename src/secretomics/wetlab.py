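"""Quantification formulas for qPCR validation assays.

Two exactly specified calculations used to validate proteomic findings:

* relative mRNA expression by the ΔΔCt method — the difference of
  (target − reference-gene) threshold cycles between an experimental and a
  control sample, expressed as a fold change ``2**(-ΔΔCt)`` assuming an
  amplification efficiency of 2 per cycle;
* ChIP-qPCR fold enrichment versus a non-tagged control IP:
  ``2**(-(Ct_IP - Ct_control))``.

Technical replicates are averaged on the Ct (cycle) scale before
exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import math

from .errors import ConfigurationError, DomainError

__all__ = ["CtRecord", "ChipCtRecord", "ddct", "chip_fold_enrichment", "mean_ct_record"]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference-gene threshold cycles."""

    sample: str
    target_gene: str
    reference_gene: str
    ct_target: float
    ct_reference: float
    condition: str = ""

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise DomainError("Ct values must be finite and positive")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class ChipCtRecord:
    """One ChIP-qPCR measurement: tagged IP vs non-tagged control IP cycles."""

    region: str
    ct_ip: float
    ct_control: float

    def __post_init__(self) -> None:
        for v in (self.ct_ip, self.ct_control):
            if not math.isfinite(v):
                raise DomainError("Ct values must be finite")


def ddct(exp: CtRecord, ctrl: CtRecord) -> float:
    """Relative expression of the experimental vs control sample, ``2**(-ΔΔCt)``.

    ΔCt = Ct_target − Ct_reference per record; ΔΔCt = ΔCt_exp − ΔCt_ctrl.
    Both records must measure the same target and reference genes.
    """
    if exp.target_gene != ctrl.target_gene or exp.reference_gene != ctrl.reference_gene:
        raise ConfigurationError(
            "experimental and control records must share target and reference genes"
        )
    return 2.0 ** (-(exp.dct - ctrl.dct))


def chip_fold_enrichment(r: ChipCtRecord) -> float:
    """ChIP signal as fold increase over the non-tagged control: ``2**(-(Ct_IP - Ct_ctrl))``."""
    return 2.0 ** (-(r.ct_ip - r.ct_control))


def mean_ct_record(records: list[CtRecord]) -> CtRecord:
    """Average technical replicates on the Ct scale (standard ΔΔCt practice)."""
    if not records:
        raise ConfigurationError("no replicate records to average")
    first = records[0]
    for r in records[1:]:
        if (r.target_gene, r.reference_gene) != (first.target_gene, first.reference_gene):
            raise ConfigurationError("replicates must share target and reference genes")
    return CtRecord(
        sample=first.sample,
        target_gene=first.target_gene,
        reference_gene=first.reference_gene,
        ct_target=fmean(r.ct_target for r in records),
        ct_reference=fmean(r.ct_reference for r in records),
        condition=first.condition,
    )
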