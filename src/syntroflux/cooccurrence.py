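"""Coverage-profile co-occurrence screen.

Replicate samples are averaged into experiment-level profiles, experiments
lacking the dominant community members are dropped, and pairwise Pearson
correlations with two-sided p-values are computed across MAG coverage
profiles.  Pairs failing the significance threshold (p >= 0.05) are masked.
A centered-log-ratio transform is available as an option for users worried
about compositional artifacts, but plain Pearson on the raw profiles is the
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class CoverageMatrix:
    """MAG x sample coverage (or relative abundance) matrix.

    ``replicate_map`` assigns every sample column to an experiment
    identifier; replicates of one experiment are averaged before
    correlation.
    """
    values: pd.DataFrame                  # rows MAGs, columns samples
    replicate_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("coverage values must be non-negative")
        missing = [c for c in self.values.columns if c not in self.replicate_map]
        if self.replicate_map and missing:
            raise ValueError(f"samples missing from replicate map: {missing}")
        if not self.replicate_map:
            self.replicate_map = {c: c for c in self.values.columns}

    @property
    def mag_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class CorrelationResult:
    r: pd.DataFrame          # MAG x MAG Pearson r
    p: pd.DataFrame          # two-sided p-values
    significant: pd.DataFrame  # boolean mask, True where p < alpha
    alpha: float = ALPHA


def average_replicates(matrix: CoverageMatrix) -> pd.DataFrame:
    """Collapse replicate samples to experiment-level means.

    Returns a MAG x experiment frame with one column per experiment
    identifier (arithmetic mean across its replicates).
    """
    groups: dict[str, list[str]] = {}
    for sample, exp in matrix.replicate_map.items():
        groups.setdefault(exp, []).append(sample)
    for exp, samples in groups.items():
        if not samples:
            raise ValueError(f"experiment '{exp}' has no samples")
    cols = {exp: matrix.values[samples].mean(axis=1)
            for exp, samples in sorted(groups.items())}
    return pd.DataFrame(cols)


def filter_dominant(matrix: pd.DataFrame, dominant_ids: list[str],
                    min_fraction: float = 0.01) -> pd.DataFrame:
    """Keep experiments whose summed dominant-species abundance reaches the
    threshold (inclusive).  Expects relative abundances in [0, 1] columns.
    """
    missing = [d for d in dominant_ids if d not in matrix.index]
    if missing:
        raise KeyError(f"dominant ids not in matrix: {missing}")
    dominant_sum = matrix.loc[dominant_ids].sum(axis=0)
    keep = dominant_sum >= min_fraction
    if not keep.any():
        logger.warning("no experiment passes the dominant-species filter")
    return matrix.loc[:, keep]


def pearson_matrix(matrix: pd.DataFrame, alpha: float = ALPHA) -> CorrelationResult:
    """All-pairs Pearson correlation with two-sided p-values.

    Requires at least 3 experiment columns.  Rows with zero variance get
    undefined (NaN) correlations, reported as missing and never significant.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 experiments, got {n}")
    X = matrix.values.astype(float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant coverage rows; correlations undefined",
                       int(constant.sum()))

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))

    # two-sided p from the t transform, matching scipy.stats.pearsonr
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, np.where(constant, np.nan, 0.0))

    ids = list(matrix.index)
    r_df = pd.DataFrame(r, index=ids, columns=ids)
    p_df = pd.DataFrame(p, index=ids, columns=ids)
    mask = (p_df < alpha) & r_df.notna()
    return CorrelationResult(r=r_df, p=p_df, significant=mask, alpha=alpha)


def clr_transform(matrix: pd.DataFrame, pseudocount: float = 1e-9) -> pd.DataFrame:
    """Centered log-ratio transform per experiment column (optional
    pre-processing for compositional data)."""
    logged = np.log(matrix + pseudocount)
    return logged - logged.mean(axis=0)
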