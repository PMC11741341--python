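"""Simulation of TMT multiplex proximity-labeling secretome experiments.

Generates protein-level reporter-ion matrices with a fully known ground
truth so every downstream stage — impurity correction, filtering, moderated
statistics, FPR threshold calibration, hit calling — can be validated
without access to a deposited dataset.

The generative model, per protein g and channel c(condition, replicate)::

    log2 I_true[g, c] = baseline_g + effect[g, condition] + eps,   eps ~ N(0, noise_sd_log2)
    baseline_g ~ N(20, 2)                                  (log2 intensity units)
    observed   = impurity_matrix @ I_true                  (per-protein channel vector)

A configurable fraction of proteins is truly enriched (positive
``effect_size_log2``) in each non-reference condition.  Positive-control
(PC) proteins emulate annotated secreted genes and are preferentially
enriched (80% of them carry the effect); negative-control (NC) proteins
emulate annotated transcription factors and are never enriched.  Missing
values are introduced per cell, uniformly at random, after mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quant import ImpurityMatrix, ReporterMatrix, StudyDesign

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TMTPRO_TAGS",
    "default_condition_names",
    "default_impurity_matrix",
    "simulate_experiment",
    "simulate_control_lists",
]

# TMTpro reporter tags in mass order; a 12-plex uses the first 12.
TMTPRO_TAGS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C",
    "131N", "131C", "132N", "132C", "133N", "133C", "134N", "134C", "135N",
)

# Fraction of PC proteins that carry a true enrichment effect: secreted
# annotations are assumed enriched among true positives, but not perfectly.
PC_ENRICHED_FRACTION = 0.8

_BASELINE_MEAN_LOG2 = 20.0
_BASELINE_SD_LOG2 = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated TMT multiplex experiment.

    Defaults emulate the 12-plex design with four conditions (one reference)
    and three replicates each; channels = n_conditions * n_replicates and
    may not exceed 18 (the largest TMTpro plex).
    """

    n_proteins: int = 2000
    n_conditions: int = 4
    n_replicates: int = 3
    frac_enriched: float = 0.10
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.3
    n_pc_controls: int = 200
    n_nc_controls: int = 200
    impurity_offdiag: float = 0.02
    missing_rate: float = 0.02
    min_peptides_range: tuple[int, int] = (1, 8)
    seed: int = 0
    condition_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_conditions < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_proteins, n_conditions, n_replicates must be >= 1")
        if not 0.0 <= self.frac_enriched <= 1.0:
            raise ConfigurationError("frac_enriched must lie in [0, 1]")
        if self.effect_size_log2 < 0 or self.noise_sd_log2 <= 0:
            raise ConfigurationError("effect size must be >= 0 and noise sd > 0")
        if self.n_pc_controls < 0 or self.n_nc_controls < 0:
            raise ConfigurationError("control counts must be non-negative")
        if self.n_pc_controls + self.n_nc_controls > self.n_proteins:
            raise ConfigurationError("more control labels than proteins")
        if not 0.0 <= self.impurity_offdiag < 0.5:
            raise ConfigurationError("impurity_offdiag must lie in [0, 0.5)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        lo, hi = self.min_peptides_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("min_peptides_range must be a non-decreasing pair")
        if self.n_channels > 18:
            raise ConfigurationError(
                f"{self.n_channels} channels requested but TMTpro supports at most 18"
            )
        if self.condition_names is not None and len(self.condition_names) != self.n_conditions:
            raise ConfigurationError("condition_names length must equal n_conditions")

    @property
    def n_channels(self) -> int:
        return self.n_conditions * self.n_replicates

    @property
    def conditions(self) -> tuple[str, ...]:
        if self.condition_names is not None:
            return self.condition_names
        return default_condition_names(self.n_conditions)

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]


@dataclass
class GroundTruth:
    """Truth tables for one simulated experiment.

    ``enriched`` and ``true_log2fc`` are protein x condition tables over the
    non-reference conditions; ``control_label`` maps each protein to
    ``"PC"``, ``"NC"`` or ``"none"``.
    """

    enriched: pd.DataFrame
    true_log2fc: pd.DataFrame
    control_label: pd.Series

    def __post_init__(self) -> None:
        if ((self.true_log2fc[self.enriched] <= 0).any()).any():
            raise ConfigurationError("enriched proteins must have true_log2fc > 0")

    def pc_proteins(self) -> list[str]:
        return list(self.control_label.index[self.control_label == "PC"])

    def nc_proteins(self) -> list[str]:
        return list(self.control_label.index[self.control_label == "NC"])


def default_condition_names(n: int) -> tuple[str, ...]:
    """Condition labels mirroring the gut-tumor secretome design.

    The first condition is the non-labeled reference; conditions 2-4 are the
    biotin-ligase (BirA*) control and the two tumor genotypes.  Designs with
    more conditions get generic extra labels.
    """
    base = ("Ctrl", "BirA", "RasBirA", "YkiBirA")
    if n <= len(base):
        return base[:n]
    return base + tuple(f"cond{i}" for i in range(len(base) + 1, n + 1))


def default_impurity_matrix(config: SimulationConfig) -> ImpurityMatrix:
    """Tridiagonal channel-mixing matrix from the configured off-diagonal bleed.

    Each channel leaks ``impurity_offdiag`` of its signal into each adjacent
    channel (one neighbour at the plex edges), keeping every column sum at 1.
    """
    n = config.n_channels
    off = config.impurity_offdiag
    m = np.zeros((n, n))
    for j in range(n):
        neighbours = [i for i in (j - 1, j + 1) if 0 <= i < n]
        for i in neighbours:
            m[i, j] = off
        m[j, j] = 1.0 - off * len(neighbours)
    return ImpurityMatrix(m, channel_names=TMTPRO_TAGS[:n])


def _make_design(config: SimulationConfig) -> StudyDesign:
    tags = TMTPRO_TAGS[: config.n_channels]
    chan_cond: dict[str, str] = {}
    chan_rep: dict[str, int] = {}
    k = 0
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            chan_cond[tags[k]] = cond
            chan_rep[tags[k]] = rep
            k += 1
    return StudyDesign(chan_cond, chan_rep, config.reference_condition)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ReporterMatrix, StudyDesign, GroundTruth]:
    """Draw one multiplexed experiment from the generative model.

    Returns the observed (impurity-mixed, possibly missing-masked) reporter
    matrix, the channel-to-condition design, and the ground truth.  The same
    config (including seed) always yields bitwise-identical output.  The
    impurity matrix actually applied is :func:`default_impurity_matrix` of
    the same config.
    """
    rng = np.random.default_rng(config.seed)
    n, n_ch = config.n_proteins, config.n_channels
    proteins = pd.Index([f"prot{i:05d}" for i in range(n)], name="protein_id")
    design = _make_design(config)
    conditions = config.conditions
    nonref = [c for c in conditions if c != config.reference_condition]

    # control labels: PC then NC, drawn without replacement
    labels = pd.Series("none", index=proteins, dtype=object)
    picked = rng.choice(n, size=config.n_pc_controls + config.n_nc_controls, replace=False)
    pc_idx = picked[: config.n_pc_controls]
    nc_idx = picked[config.n_pc_controls:]
    labels.iloc[pc_idx] = "PC"
    labels.iloc[nc_idx] = "NC"

    # enrichment truth per non-reference condition: 80% of PCs are enriched,
    # the remainder of the target count comes from unlabeled proteins; NCs
    # are never enriched.
    enriched = pd.DataFrame(False, index=proteins, columns=nonref)
    n_target = int(round(config.frac_enriched * n))
    none_idx = np.flatnonzero((labels == "none").to_numpy())
    for cond in nonref:
        if n_target == 0:
            continue
        n_from_pc = min(int(round(PC_ENRICHED_FRACTION * len(pc_idx))), n_target)
        chosen_pc = rng.choice(pc_idx, size=n_from_pc, replace=False) if n_from_pc else []
        n_rest = min(n_target - n_from_pc, len(none_idx))
        chosen_none = rng.choice(none_idx, size=n_rest, replace=False) if n_rest else []
        rows = np.concatenate([np.asarray(chosen_pc, int), np.asarray(chosen_none, int)])
        enriched.iloc[rows, enriched.columns.get_loc(cond)] = True
    true_log2fc = enriched.astype(float) * config.effect_size_log2

    # per-channel condition effect matrix (proteins x channels)
    effect = np.zeros((n, n_ch))
    chan_list = design.channels
    for k, ch in enumerate(chan_list):
        cond = design.channel_to_condition[ch]
        if cond in nonref:
            effect[:, k] = true_log2fc[cond].to_numpy()

    baseline = rng.normal(_BASELINE_MEAN_LOG2, _BASELINE_SD_LOG2, size=n)
    noise = rng.normal(0.0, config.noise_sd_log2, size=(n, n_ch))
    log2_true = baseline[:, None] + effect + noise
    true_intensity = np.exp2(log2_true)

    impurity = default_impurity_matrix(config)
    observed = true_intensity @ impurity.values.T

    if config.missing_rate > 0:
        mask = rng.random(size=(n, n_ch)) < config.missing_rate
        observed = np.where(mask, np.nan, observed)

    lo, hi = config.min_peptides_range
    peptides = pd.Series(rng.integers(lo, hi + 1, size=n), index=proteins,
                         name="n_unique_peptides")

    matrix = ReporterMatrix(
        pd.DataFrame(observed, index=proteins, columns=chan_list),
        peptides,
    )
    truth = GroundTruth(enriched, true_log2fc, labels)
    return matrix, design, truth


def simulate_control_lists(truth: GroundTruth) -> tuple[list[str], list[str]]:
    """Extract the PC (secreted-annotation) and NC (TF-annotation) gene lists."""
    return truth.pc_proteins(), truth.nc_proteins()
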