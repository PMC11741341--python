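"""Reporter-ion quantitation for isobaric (TMT) multiplexed proteomics.

The processing chain implemented here takes a protein-level reporter-ion
intensity matrix through the standard pre-statistics steps:

1. isotopic-impurity correction — each TMT tag bleeds a known fraction of its
   reporter signal into neighbouring channels; the observed channel vector is
   the true vector multiplied by a mixing matrix, so correction is a linear
   solve per protein;
2. quality filtering — proteins supported by at least two unique peptide
   sequences and quantified in every channel are retained;
3. log2 ratios versus a designated reference condition;
4. per-sample median normalization so every sample's log2-ratio distribution
   is centered at zero.

Containers are thin dataclasses around :class:`pandas.DataFrame` objects so
every intermediate can be inspected, written to TSV, or fed to the statistics
layer directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, DomainError, NumericalError

__all__ = [
    "ReporterMatrix",
    "ImpurityMatrix",
    "StudyDesign",
    "RatioTable",
    "FilterReport",
    "apply_mixing",
    "correct_impurities",
    "filter_proteins",
    "compute_log_ratios",
    "median_normalize",
]

# Maximum condition number accepted for an impurity matrix before the linear
# solve is considered untrustworthy.
_MAX_CONDITION_NUMBER = 1e8


@dataclass
class ReporterMatrix:
    """Protein x channel reporter-ion intensities with peptide support counts.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein identifier with one column per TMT
        channel.  Missing measurements are ``NaN``; observed values must be
        non-negative.
    n_unique_peptides
        Series aligned to ``intensities.index`` giving the number of distinct
        peptide sequences supporting each protein.
    corrected_flags
        Per-protein bookkeeping set by :func:`correct_impurities`:
        ``"corrected"``, ``"clamped"`` (negative solution truncated at zero)
        or ``"uncorrected_missing"`` (row passed through because a channel
        was missing).  Empty before correction.
    """

    intensities: pd.DataFrame
    n_unique_peptides: pd.Series
    corrected_flags: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ConfigurationError("duplicate protein_ids in ReporterMatrix")
        if self.intensities.columns.has_duplicates:
            raise ConfigurationError("duplicate channel names in ReporterMatrix")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ConfigurationError("observed intensities must be non-negative")
        self.n_unique_peptides = self.n_unique_peptides.reindex(self.intensities.index)

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def channel_names(self) -> list[str]:
        return list(self.intensities.columns)

    def is_complete(self) -> pd.Series:
        """Boolean per protein: quantified in every channel."""
        return self.intensities.notna().all(axis=1)


@dataclass(frozen=True)
class ImpurityMatrix:
    """Channel-mixing matrix for reporter-ion isotopic impurities.

    Column convention: column *j* gives the fraction of channel *j*'s true
    signal observed in each channel, so ``observed = M @ true`` for one
    protein's channel vector.  Entries are fractions in [0, 1] and each
    column sums to at most 1 (signal may be lost outside the measured
    channels, never created).
    """

    values: np.ndarray
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConfigurationError("impurity matrix must be square")
        if (m < 0).any() or (m > 1).any():
            raise ConfigurationError("impurity fractions must lie in [0, 1]")
        if (m.sum(axis=0) > 1 + 1e-6).any():
            raise ConfigurationError("impurity matrix columns must sum to <= 1")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))


@dataclass(frozen=True)
class StudyDesign:
    """Assignment of TMT channels to experimental conditions and replicates."""

    channel_to_condition: dict[str, str]
    channel_to_replicate: dict[str, int]
    reference_condition: str

    def __post_init__(self) -> None:
        if set(self.channel_to_condition) != set(self.channel_to_replicate):
            raise DesignError("condition and replicate maps must cover the same channels")
        if self.reference_condition not in self.channel_to_condition.values():
            raise DesignError(
                f"reference condition {self.reference_condition!r} has no channels"
            )

    @property
    def channels(self) -> list[str]:
        return list(self.channel_to_condition)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.channel_to_condition.values():
            if c not in seen:
                seen.append(c)
        return seen

    def channels_for(self, condition: str) -> list[str]:
        chans = [ch for ch, c in self.channel_to_condition.items() if c == condition]
        if not chans:
            raise DesignError(f"condition {condition!r} not present in design")
        return chans

    def sample_name(self, channel: str) -> str:
        cond = self.channel_to_condition[channel]
        rep = self.channel_to_replicate[channel]
        return f"{cond}.{rep}"


@dataclass
class RatioTable:
    """Protein x sample log2 ratios relative to the reference condition."""

    ratios: pd.DataFrame
    sample_to_condition: dict[str, str]
    reference_condition: str
    normalized: bool = False
    sample_medians: pd.Series | None = field(default=None, repr=False)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    n_removed_peptides: int
    n_removed_incomplete: int


def apply_mixing(true_matrix: ReporterMatrix, impurity: ImpurityMatrix) -> ReporterMatrix:
    """Forward model of reporter-ion cross-contamination: ``observed = M @ true``.

    The inverse of :func:`correct_impurities`; used by the simulator and by
    round-trip tests.
    """
    _check_dims(true_matrix, impurity)
    x = true_matrix.intensities.to_numpy(dtype=float)
    mixed = x @ impurity.values.T
    out = pd.DataFrame(mixed, index=true_matrix.intensities.index,
                       columns=true_matrix.intensities.columns)
    out[true_matrix.intensities.isna()] = np.nan
    return ReporterMatrix(out, true_matrix.n_unique_peptides.copy())


def correct_impurities(raw: ReporterMatrix, impurity: ImpurityMatrix) -> ReporterMatrix:
    """Invert channel cross-contamination by solving ``M x = y`` per protein.

    Proteins with any missing channel cannot be corrected (the linear system
    is incomplete) and pass through unchanged, flagged
    ``"uncorrected_missing"``.  Small negative solutions, which arise from
    measurement noise, are clamped to zero and flagged ``"clamped"``.

    Raises
    ------
    NumericalError
        If the impurity matrix is singular or has condition number >= 1e8.
    ConfigurationError
        If the matrix dimension does not match the channel count.
    """
    _check_dims(raw, impurity)
    m = impurity.values
    if not np.isfinite(cond := np.linalg.cond(m)) or cond >= _MAX_CONDITION_NUMBER:
        raise NumericalError(
            f"impurity matrix is singular or ill-conditioned (cond={cond:.3g})"
        )

    y = raw.intensities.to_numpy(dtype=float)
    complete = ~np.isnan(y).any(axis=1)
    corrected = y.copy()
    flags = pd.Series("uncorrected_missing", index=raw.intensities.index, dtype=object)

    if complete.any():
        # solve M x = y for all complete rows at once
        sol = np.linalg.solve(m, y[complete].T).T
        negative = (sol < 0).any(axis=1)
        sol = np.clip(sol, 0.0, None)
        corrected[complete] = sol
        sub = np.where(negative, "clamped", "corrected")
        flags.iloc[np.flatnonzero(complete)] = sub

    out = pd.DataFrame(corrected, index=raw.intensities.index,
                       columns=raw.intensities.columns)
    return ReporterMatrix(out, raw.n_unique_peptides.copy(), corrected_flags=flags)


def filter_proteins(
    m: ReporterMatrix,
    min_unique_peptides: int = 2,
    require_complete: bool = True,
) -> tuple[ReporterMatrix, FilterReport]:
    """Retain proteins with enough unique peptides and, optionally, no missing channel.

    Row order is preserved.  Returns the filtered matrix together with a
    :class:`FilterReport` of how many proteins each rule removed (a protein
    failing both rules is counted under the peptide rule).
    """
    enough_peptides = m.n_unique_peptides >= min_unique_peptides
    complete = m.is_complete() if require_complete else pd.Series(True, index=m.protein_ids)
    keep = enough_peptides & complete
    report = FilterReport(
        n_input=len(m.protein_ids),
        n_retained=int(keep.sum()),
        n_removed_peptides=int((~enough_peptides).sum()),
        n_removed_incomplete=int((enough_peptides & ~complete).sum()),
    )
    filtered = ReporterMatrix(
        m.intensities.loc[keep].copy(),
        m.n_unique_peptides.loc[keep].copy(),
        corrected_flags=None if m.corrected_flags is None else m.corrected_flags.loc[keep].copy(),
    )
    return filtered, report


def compute_log_ratios(
    m: ReporterMatrix,
    design: StudyDesign,
    reference_stat: str = "mean",
) -> RatioTable:
    """Log2 ratios of each non-reference sample versus the reference condition.

    For protein *g* and non-reference channel *s*::

        r[g, s] = log2(I[g, s]) - stat over reference channels c of log2(I[g, c])

    where ``stat`` is the mean (default; a geometric mean on the intensity
    scale) or the median of the reference channels' log2 intensities.
    Reference channels do not appear as samples in the output.

    Raises
    ------
    DomainError
        If any used cell is zero or missing (the log is undefined); the
        message names the first offending protein and channel.
    """
    if reference_stat not in ("mean", "median"):
        raise ConfigurationError("reference_stat must be 'mean' or 'median'")
    missing_design = set(m.channel_names) - set(design.channels)
    if missing_design:
        raise DesignError(f"design does not cover channels: {sorted(missing_design)}")

    ref_channels = design.channels_for(design.reference_condition)
    sample_channels = [ch for ch in m.channel_names if ch not in ref_channels]

    used = m.intensities[ref_channels + sample_channels]
    bad = (used.isna()) | (used <= 0)
    if bad.to_numpy().any():
        gi, ci = np.argwhere(bad.to_numpy())[0]
        raise DomainError(
            f"non-positive or missing intensity for protein "
            f"{used.index[gi]!r}, channel {used.columns[ci]!r}"
        )

    log2i = np.log2(m.intensities)
    ref_log = log2i[ref_channels]
    ref_center = ref_log.mean(axis=1) if reference_stat == "mean" else ref_log.median(axis=1)

    ratios = log2i[sample_channels].sub(ref_center, axis=0)
    ratios.columns = [design.sample_name(ch) for ch in sample_channels]
    sample_to_condition = {
        design.sample_name(ch): design.channel_to_condition[ch] for ch in sample_channels
    }
    return RatioTable(ratios, sample_to_condition, design.reference_condition)


def median_normalize(r: RatioTable) -> RatioTable:
    """Center every sample column at zero by subtracting its median.

    Centers the aggregate distribution of protein-level log2 ratios so that
    sample-loading differences do not masquerade as enrichment.  Idempotent:
    normalizing an already-normalized table changes nothing.

    Raises
    ------
    DomainError
        If a sample column has no observed entries (its median is undefined).
    """
    n_obs = r.ratios.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = list(n_obs.index[n_obs == 0])
        raise DomainError(f"sample columns with no observed ratios: {empty}")
    medians = r.ratios.median(axis=0, skipna=True)
    return RatioTable(
        r.ratios.sub(medians, axis=1),
        dict(r.sample_to_condition),
        r.reference_condition,
        normalized=True,
        sample_medians=medians,
    )


def _check_dims(m: ReporterMatrix, impurity: ImpurityMatrix) -> None:
    if impurity.n_channels != len(m.channel_names):
        raise ConfigurationError(
            f"impurity matrix is {impurity.n_channels}x{impurity.n_channels} "
            f"but the reporter matrix has {len(m.channel_names)} channels"
        )
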