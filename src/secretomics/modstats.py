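"""Empirical-Bayes moderated t-tests for differential protein abundance.

Small-replicate TMT designs (here 3 replicates per condition) make the
per-protein sample variance a noisy quantity; the moderated t-test (Smyth
2004, the limma formulation) shrinks each protein's variance toward a
common prior estimated from the whole dataset, gaining ``d0`` extra degrees
of freedom:

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_mod       = logFC_g / (s_tilde_g * sqrt(1/n_a + 1/n_b))
    p           = 2 * P(T_{d0 + d_g} >= |t_mod|)

The prior (d0, s0^2) is estimated by the moment method: the log sample
variances follow a scaled F distribution under the hierarchical model, so
matching the mean and variance of log s_g^2 via digamma/trigamma functions
identifies both hyperparameters.  d0 = +inf collapses to a fully pooled
common variance; d0 = 0 recovers the ordinary two-sample t-test.

Benjamini-Hochberg adjustment of the resulting p-values controls the FDR
across proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, DomainError, NumericalError
from .quant import RatioTable, StudyDesign

__all__ = [
    "Contrast",
    "DiffTestTable",
    "VariancePrior",
    "estimate_variance_prior",
    "moderated_t",
    "bh_adjust",
]

# d0 estimates beyond this are numerically indistinguishable from infinity.
_D0_CAP = 1e6


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: ``group_a`` (experimental) vs ``group_b`` (reference)."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise DesignError("contrast groups must differ")


@dataclass
class DiffTestTable:
    """Per-protein moderated test results for one contrast.

    ``table`` columns: logFC, s2, t_mod, df_total, p, p_adj.  Proteins with
    too few observations in either group appear with NaN statistics
    (untested) and are excluded from multiplicity correction.
    """

    table: pd.DataFrame
    contrast: Contrast
    d0: float
    s0_sq: float

    @property
    def logfc(self) -> pd.Series:
        return self.table["logFC"]

    @property
    def p_adj(self) -> pd.Series:
        return self.table["p_adj"]


@dataclass(frozen=True)
class VariancePrior:
    d0: float
    s0_sq: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise DomainError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-8 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Moment estimator of the variance prior from per-protein sample variances.

    Works on z = log(s2): under the hierarchical model z - digamma(df/2) +
    log(df/2) has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) beyond trigamma(df/2); inverting the trigamma
    function yields d0, then the mean equation yields s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise NumericalError("all sample variances are zero: degenerate fit")
    if positive.size < 2:
        return VariancePrior(d0=np.inf, s0_sq=float(positive.mean()))

    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if d0 > _D0_CAP:
            d0 = np.inf
            s0_sq = float(np.exp(e_mean))
        else:
            s0_sq = float(np.exp(
                e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
            ))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def _group_columns(
    data: pd.DataFrame | RatioTable,
    design: StudyDesign | None,
    condition: str,
) -> list[str]:
    if isinstance(data, RatioTable):
        cols = [s for s, c in data.sample_to_condition.items() if c == condition]
    elif design is not None:
        cols = [
            c for c in data.columns
            if design.channel_to_condition.get(c) == condition
        ]
        if not cols:
            # columns may be sample names rather than channel names
            cols = [
                design.sample_name(ch)
                for ch, c in design.channel_to_condition.items()
                if c == condition and design.sample_name(ch) in data.columns
            ]
    else:
        raise DesignError("a StudyDesign is required when data is a plain matrix")
    return cols


def moderated_t(
    data: pd.DataFrame | RatioTable,
    design: StudyDesign | None,
    contrast: Contrast,
    d0: float | None = None,
    s0_sq: float | None = None,
    mode: str = "two-sample",
) -> DiffTestTable:
    """Moderated two-group t-test of ``contrast`` on log2-scale data.

    Parameters
    ----------
    data
        Either a protein x sample DataFrame of log2 values with a
        ``design`` mapping columns to conditions, or a :class:`RatioTable`
        (whose sample-to-condition mapping is used directly).
    d0, s0_sq
        Optional fixed prior, overriding the moment estimate.  ``d0=0``
        gives the ordinary pooled two-sample t; ``d0=inf`` fully pools the
        variance at ``s0_sq`` (estimated from the data if not given).
    mode
        ``"two-sample"`` (default) compares the two groups' columns;
        ``"one-sample"`` tests the mean of ``group_a``'s ratio columns
        against zero (only meaningful on a RatioTable whose reference is
        ``group_b``; note the pooled-reference correlation caveat).

    Proteins with fewer than 2 observed replicates in a required group are
    reported untested (NaN statistics).
    """
    if mode not in ("two-sample", "one-sample"):
        raise DesignError("mode must be 'two-sample' or 'one-sample'")

    frame = data.ratios if isinstance(data, RatioTable) else data
    cols_a = _group_columns(data, design, contrast.group_a)
    if mode == "two-sample":
        cols_b = _group_columns(data, design, contrast.group_b)
    else:
        if isinstance(data, RatioTable) and contrast.group_b != data.reference_condition:
            raise DesignError(
                "one-sample mode tests ratios against the table's reference condition"
            )
        cols_b = []
    if len(cols_a) < 2 or (mode == "two-sample" and len(cols_b) < 2):
        raise DesignError("each tested group needs at least 2 replicates")

    a = frame[cols_a].to_numpy(dtype=float)
    n_a = np.isfinite(a).sum(axis=1)
    mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
    var_a = _nanvar(a, n_a)

    if mode == "two-sample":
        b = frame[cols_b].to_numpy(dtype=float)
        n_b = np.isfinite(b).sum(axis=1)
        mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
        var_b = _nanvar(b, n_b)
        tested = (n_a >= 2) & (n_b >= 2)
        df_resid = np.where(tested, n_a + n_b - 2, np.nan)
        logfc = mean_a - mean_b
        s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / np.where(tested, n_a + n_b - 2, np.nan)
        stderr_unit = np.sqrt(1.0 / n_a + 1.0 / n_b)
    else:
        tested = n_a >= 2
        df_resid = np.where(tested, n_a - 1, np.nan)
        logfc = mean_a
        s2 = var_a
        stderr_unit = np.sqrt(1.0 / n_a)

    tested_s2 = s2[tested & np.isfinite(s2)]
    if tested_s2.size and np.all(tested_s2 == 0):
        raise NumericalError("zero variance for every tested protein: degenerate fit")

    if d0 is None:
        # residual df is constant across fully observed proteins; use the modal df
        df_for_prior = float(np.nanmedian(df_resid))
        prior = estimate_variance_prior(tested_s2, df_for_prior)
        d0_use, s0_use = prior.d0, prior.s0_sq
    else:
        d0_use = float(d0)
        if s0_sq is not None:
            s0_use = float(s0_sq)
        elif d0_use == 0:
            s0_use = 0.0
        else:
            df_for_prior = float(np.nanmedian(df_resid))
            s0_use = estimate_variance_prior(tested_s2, df_for_prior).s0_sq
    if d0_use > _D0_CAP:
        d0_use = np.inf

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0_use):
            s2_post = np.full_like(s2, s0_use)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_post = (d0_use * s0_use + df_resid * s2) / (d0_use + df_resid)
            df_total = df_resid + d0_use
        t_mod = logfc / (np.sqrt(s2_post) * stderr_unit)
        p = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(t_mod)),
            2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0, df_total)),
        )

    untested = ~tested
    for arr in (logfc, s2, t_mod, df_total, p):
        arr[untested] = np.nan

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=frame.index,
    )
    return DiffTestTable(table, contrast, d0=float(d0_use), s0_sq=float(s0_use))


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-row variance over observed entries (NaN where n < 2)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = np.where(np.isfinite(x), x, np.nan)
        mean = np.nanmean(xm, axis=1)
        ss = np.nansum((xm - mean[:, None]) ** 2, axis=1)
        return np.where(n >= 2, ss / np.maximum(n - 1, 1), np.nan)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    Missing values propagate as missing and do not count toward the number
    of tests m.  Values outside [0, 1] raise :class:`DomainError`.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out
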