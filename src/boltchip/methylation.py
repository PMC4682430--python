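"""Two-colour MeDIP-chip processing.

Each array hybridizes the anti-5-methylcytosine immunoprecipitated fraction
(Cy5) of one genotype against its input DNA (Cy3). Processing per sample:

1. select quality probes — above background in both channels (the
   ``2.6 * BG_SD`` rule per channel), non-saturated, non-outlier, and with
   similar signal ranks between the two dyes;
2. linear dye normalization — a single multiplicative factor equalizing the
   mean Cy5 and mean Cy3 signal over the quality set;
3. per-probe ``log2(Cy5'/Cy3)`` methylation-enrichment ratios (positive =
   methylated relative to input);
4. DMR calling on the ratio matrix with the shared fold-change + t-test core,
   at a primary tier (default raw p < 0.01) and a screen tier (p < 0.05).

Replication for testing is across genotypes within a tolerance group: one
immunoprecipitation was performed per genotype, so the three genotypes of a
group are the biological replicates of its condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._stats import differential_table
from .expression import BACKGROUND_K, PipelineError

logger = logging.getLogger(__name__)

TWO_COLOUR_COLUMNS = [
    "probe_id",
    "sample_id",
    "cy3_signal",
    "cy5_signal",
    "cy3_bg_sub",
    "cy3_bg_sd",
    "cy5_bg_sub",
    "cy5_bg_sd",
    "cy3_saturated",
    "cy5_saturated",
    "cy3_outlier",
    "cy5_outlier",
]

#: Default rank-similarity tolerance as a fraction of the probe count.
RANK_TOLERANCE = 0.05


@dataclass
class MethylationRatioMatrix:
    """Probe x sample matrix of dye-normalized log2(Cy5'/Cy3) ratios."""

    values: pd.DataFrame
    scale_factor: dict[str, float] = field(default_factory=dict)
    quality_set: dict[str, list[str]] = field(default_factory=dict)


def select_quality_probes(
    sample: pd.DataFrame, rank_tolerance: float = RANK_TOLERANCE
) -> pd.Index:
    """Probes usable for dye normalization in one sample.

    A probe qualifies when each channel is above background
    (``bg_sub > 2.6 * bg_sd``), neither channel is saturated or an outlier,
    and the probe's signal ranks in the two channels differ by at most
    ``rank_tolerance * N`` (ranks taken over all N probes of the sample,
    average rank for ties).
    """
    if len(sample) < 10:
        raise PipelineError("need >= 10 probes per sample for quality selection")
    n = len(sample)
    clean = (
        (sample["cy3_bg_sub"] > BACKGROUND_K * sample["cy3_bg_sd"])
        & (sample["cy5_bg_sub"] > BACKGROUND_K * sample["cy5_bg_sd"])
        & ~sample["cy3_saturated"].astype(bool)
        & ~sample["cy5_saturated"].astype(bool)
        & ~sample["cy3_outlier"].astype(bool)
        & ~sample["cy5_outlier"].astype(bool)
    )
    rank3 = rankdata(sample["cy3_signal"].to_numpy(dtype=float))
    rank5 = rankdata(sample["cy5_signal"].to_numpy(dtype=float))
    concordant = np.abs(rank3 - rank5) <= rank_tolerance * n
    selected = sample.loc[clean.to_numpy() & concordant, "probe_id"]
    return pd.Index(selected, name="probe_id")


def normalize_two_colour(
    sample: pd.DataFrame, quality_set: pd.Index
) -> tuple[pd.Series, float]:
    """Dye-normalized log ratios for one sample.

    The linear correction rescales Cy5 by
    ``scale = mean(Cy3 over quality set) / mean(Cy5 over quality set)`` so the
    two channels agree on average over the quality probes, then reports
    ``log2(scale * cy5 / cy3)`` per probe. Probes with a non-positive channel
    value are masked (NaN). Returns (log_ratio series indexed by probe_id,
    scale factor).
    """
    if len(quality_set) == 0:
        raise PipelineError("empty quality set: cannot normalize this sample")
    indexed = sample.set_index("probe_id")
    q = indexed.loc[quality_set]
    mean_cy5 = q["cy5_signal"].mean()
    if not mean_cy5 > 0:
        raise PipelineError("mean Cy5 over the quality set is not positive")
    scale = q["cy3_signal"].mean() / mean_cy5
    cy3 = indexed["cy3_signal"].astype(float)
    cy5 = indexed["cy5_signal"].astype(float)
    valid = (cy3 > 0) & (cy5 > 0)
    ratio = pd.Series(np.nan, index=indexed.index, name="log_ratio")
    ratio[valid] = np.log2(scale * cy5[valid] / cy3[valid])
    return ratio, float(scale)


def build_ratio_matrix(
    measurements: pd.DataFrame, rank_tolerance: float = RANK_TOLERANCE
) -> MethylationRatioMatrix:
    """Quality selection + linear dye normalization for every sample."""
    columns: dict[str, pd.Series] = {}
    scales: dict[str, float] = {}
    quality: dict[str, list[str]] = {}
    for sample_id, sample in measurements.groupby("sample_id", sort=True):
        qset = select_quality_probes(sample, rank_tolerance=rank_tolerance)
        ratio, scale = normalize_two_colour(sample, qset)
        columns[str(sample_id)] = ratio
        scales[str(sample_id)] = scale
        quality[str(sample_id)] = list(qset)
    values = pd.DataFrame(columns)
    values.index.name = "probe_id"
    return MethylationRatioMatrix(values=values, scale_factor=scales, quality_set=quality)


def call_dmrs(
    ratio_matrix: MethylationRatioMatrix | pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha_primary: float = 0.01,
    alpha_screen: float = 0.05,
    adjust: Literal["bh", "none"] = "none",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Call differentially methylated regions between S and R groups.

    The shared fold-change + t-test core runs on the log-ratio matrix; rows
    are tiered: ``dmr`` when the gate passes at ``alpha_primary``, ``screen``
    when only at ``alpha_screen``. ``significant`` refers to the primary tier.
    Directions are ``hyper_in_S``/``hyper_in_R``.
    """
    values = (
        ratio_matrix.values
        if isinstance(ratio_matrix, MethylationRatioMatrix)
        else ratio_matrix
    )
    result = differential_table(
        values,
        design,
        fc_threshold=fc_threshold,
        alpha=alpha_primary,
        adjust=adjust,
        equal_var=equal_var,
        label_high="hyper_in_S",
        label_low="hyper_in_R",
    )
    p_gate = result["p_adj"] if adjust == "bh" else result["p_raw"]
    gate = result["fold_change"] >= fc_threshold
    result["tier"] = np.select(
        [gate & (p_gate < alpha_primary), gate & (p_gate < alpha_screen)],
        ["dmr", "screen"],
        default="none",
    )
    result["significant"] = result["tier"] == "dmr"
    return result


def run_methylation_pipeline(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha_primary: float = 0.01,
    alpha_screen: float = 0.05,
    rank_tolerance: float = RANK_TOLERANCE,
    adjust: Literal["bh", "none"] = "none",
) -> tuple[pd.DataFrame, MethylationRatioMatrix, pd.Index]:
    """Condition-level flag filter + dye normalization + DMR calling.

    Probe filtering reuses the one-colour rule with per-channel flags: a
    probe must pass all flags in every replicate of at least one condition.
    Returns (calls, ratio matrix, retained probe index).
    """
    from .expression import filter_probes

    flags = measurements.copy()
    flags["pass_all"] = (
        (flags["cy3_bg_sub"] > BACKGROUND_K * flags["cy3_bg_sd"])
        & (flags["cy5_bg_sub"] > BACKGROUND_K * flags["cy5_bg_sd"])
        & ~flags["cy3_saturated"].astype(bool)
        & ~flags["cy5_saturated"].astype(bool)
        & ~flags["cy3_outlier"].astype(bool)
        & ~flags["cy5_outlier"].astype(bool)
    )
    retained = filter_probes(flags, design)
    if retained.empty:
        raise PipelineError("no probe passed condition-level filtering")
    matrix = build_ratio_matrix(measurements, rank_tolerance=rank_tolerance)
    matrix.values = matrix.values.loc[matrix.values.index.intersection(retained)].sort_index()
    calls = call_dmrs(
        matrix,
        design,
        fc_threshold=fc_threshold,
        alpha_primary=alpha_primary,
        alpha_screen=alpha_screen,
        adjust=adjust,
    )
    return calls, matrix, retained


__all__ = [
    "MethylationRatioMatrix",
    "RANK_TOLERANCE",
    "TWO_COLOUR_COLUMNS",
    "build_ratio_matrix",
    "call_dmrs",
    "normalize_two_colour",
    "run_methylation_pipeline",
    "select_quality_probes",
]
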