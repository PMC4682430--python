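"""One-colour expression array processing.

The processing chain mirrors standard single-channel long-oligo array practice
for a genotype-contrast design (3 bolting-sensitive vs 3 bolting-resistant
genotypes, one array per genotype):

1. per-feature quality flags, with the "well above background" rule
   ``gBGSubSignal > 2.6 * gBG_SD``;
2. condition-level filtering — a probe is kept when it passes every flag in
   all replicates of at least one condition;
3. normalization: per chip to the 75th percentile, per probe to the median
   across chips, then log2;
4. differential calling: fold-change gate plus two-sample t-test with
   Benjamini-Hochberg adjustment;
5. average-linkage hierarchical clustering on 1 - Pearson r distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._linkage import average_linkage, leaf_order, pearson_distance, to_newick
from ._stats import StatsError, differential_table

logger = logging.getLogger(__name__)

#: Default "well above background" multiplier on the local background SD.
BACKGROUND_K = 2.6

SIGNAL_COLUMNS = [
    "probe_id",
    "sample_id",
    "raw_signal",
    "bg_sub_signal",
    "bg_sd",
    "is_saturated",
    "is_nonuniform_outlier",
]


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class FlagResult:
    above_background: bool
    pass_all: bool


@dataclass
class NormalizedMatrix:
    """Probe x sample matrix of normalized log2 signals with provenance."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    merge_tree: np.ndarray  # scipy linkage matrix
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        return to_newick(self.merge_tree, self.labels)


def evaluate_flags(
    bg_sub_signal: float,
    bg_sd: float,
    is_saturated: bool = False,
    is_nonuniform_outlier: bool = False,
    k: float = BACKGROUND_K,
) -> FlagResult:
    """Evaluate the per-feature quality flags for one measurement.

    ``above_background`` applies the strict inequality
    ``bg_sub_signal > k * bg_sd``; missing values fail. ``pass_all``
    additionally requires a non-saturated, uniform feature.
    """
    try:
        # NaN comparisons are False, so missing numeric values fail the rule.
        above = bool(float(bg_sub_signal) > k * float(bg_sd))
    except (TypeError, ValueError):
        above = False
    pass_all = above and not bool(is_saturated) and not bool(is_nonuniform_outlier)
    return FlagResult(above_background=above, pass_all=pass_all)


def flag_table(signals: pd.DataFrame, k: float = BACKGROUND_K) -> pd.DataFrame:
    """Vectorized flag evaluation over a long-format signal table.

    Returns the table with boolean ``above_background`` and ``pass_all``
    columns appended.
    """
    out = signals.copy()
    bg_sub = pd.to_numeric(out["bg_sub_signal"], errors="coerce")
    bg_sd = pd.to_numeric(out["bg_sd"], errors="coerce")
    above = (bg_sub > k * bg_sd).fillna(False)
    out["above_background"] = above
    out["pass_all"] = (
        above
        & ~out["is_saturated"].astype(bool)
        & ~out["is_nonuniform_outlier"].astype(bool)
    )
    return out


def filter_probes(flags: pd.DataFrame, design: pd.DataFrame) -> pd.Index:
    """Probes passing all flags in every replicate of at least one condition.

    ``flags`` is long-format with probe_id, sample_id and pass_all columns;
    ``design`` maps sample_id to condition. A probe/sample pair absent from
    the table counts as a failure.
    """
    merged = flags.merge(design[["sample_id", "condition"]], on="sample_id")
    if merged.empty:
        raise PipelineError("no overlap between signal table and sample design")
    n_per_condition = design.groupby("condition")["sample_id"].nunique()
    if (n_per_condition < 1).any() or len(n_per_condition) < 2:
        raise PipelineError("both conditions must contain samples")
    per = merged.groupby(["probe_id", "condition"])["pass_all"].agg(["sum", "size"])
    per["n_expected"] = n_per_condition.reindex(
        per.index.get_level_values("condition")
    ).to_numpy()
    all_pass = (per["sum"] == per["n_expected"]) & (per["size"] == per["n_expected"])
    retained = all_pass.groupby("probe_id").any()
    return pd.Index(sorted(retained[retained].index), name="probe_id")


def normalize_one_colour(raw: pd.DataFrame) -> NormalizedMatrix:
    """Normalize a probe x sample raw-signal matrix.

    Each chip is scaled to its 75th percentile, each probe is centred on its
    median across chips, and values are log2-transformed. Non-positive raw
    signals are masked; probes left without any finite value are excluded
    (logged). Per-chip scale factors and per-probe medians are recorded in
    the provenance.
    """
    values = raw.astype(float).where(raw > 0)
    p75 = values.quantile(0.75, axis=0)
    if (~(p75 > 0)).any():
        bad = p75.index[~(p75 > 0)].tolist()
        raise PipelineError(f"chip 75th percentile not positive for samples {bad}")
    values = values / p75
    medians = values.median(axis=1)
    keep = medians > 0
    dropped = values.index[~keep].tolist()
    if dropped:
        logger.info("normalize_one_colour: excluded %d all-masked probes", len(dropped))
    values = values.loc[keep].div(medians[keep], axis=0)
    matrix = np.log2(values)
    return NormalizedMatrix(
        values=matrix,
        provenance={
            "chip_scale_p75": p75.to_dict(),
            "probe_median": medians[keep].to_dict(),
            "order": "chip-scaling -> probe-centering -> log2",
            "excluded_probes": dropped,
        },
    )


def call_differential(
    matrix: NormalizedMatrix | pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    adjust: Literal["bh", "none"] = "bh",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Call differentially expressed sequences between S and R genotypes.

    Fold change is the geometric-mean ratio ``2**|mean_S - mean_R|`` of log2
    values; significance requires the fold-change gate and the (BH-adjusted by
    default) t-test p below ``alpha``. Directions are ``up_in_S``/``up_in_R``.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    result = differential_table(
        values,
        design,
        fc_threshold=fc_threshold,
        alpha=alpha,
        adjust=adjust,
        equal_var=equal_var,
        label_high="up_in_S",
        label_low="up_in_R",
    )
    result["tier"] = np.where(result["significant"], "deg", "none")
    return result


def cluster_features(
    matrix: NormalizedMatrix | pd.DataFrame,
    axis: Literal["probes", "samples"] = "probes",
) -> ClusterResult:
    """Average-linkage hierarchical clustering on 1 - Pearson r distance.

    Zero-variance items are dropped with a warning (their correlation is
    undefined). Items are pre-sorted by identifier so ties break
    deterministically.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if axis == "samples":
        values = values.T
    elif axis != "probes":
        raise PipelineError(f"unknown clustering axis {axis!r}")
    values = values.loc[sorted(values.index.astype(str))]
    variable = values.std(axis=1) > 0
    if (~variable).any():
        warnings.warn(
            f"dropping {int((~variable).sum())} zero-variance items before clustering",
            stacklevel=2,
        )
        values = values.loc[variable]
    if len(values) < 2:
        raise PipelineError("need at least 2 variable items to cluster")
    tree = average_linkage(pearson_distance(values))
    labels = values.index.astype(str).tolist()
    return ClusterResult(merge_tree=tree, labels=labels, leaf_order=leaf_order(tree, labels))


def signals_to_matrix(signals: pd.DataFrame, column: str = "raw_signal") -> pd.DataFrame:
    """Pivot a long-format signal table to a probe x sample matrix."""
    return signals.pivot(index="probe_id", columns="sample_id", values=column)


def run_expression_pipeline(
    signals: pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    adjust: Literal["bh", "none"] = "bh",
    k_background: float = BACKGROUND_K,
) -> tuple[pd.DataFrame, NormalizedMatrix, pd.Index]:
    """Flags -> filter -> normalize -> call, returning (calls, matrix, retained)."""
    flags = flag_table(signals, k=k_background)
    retained = filter_probes(flags, design)
    if retained.empty:
        raise PipelineError("no probe passed condition-level filtering")
    raw = signals_to_matrix(signals).loc[retained]
    matrix = normalize_one_colour(raw)
    calls = call_differential(
        matrix, design, fc_threshold=fc_threshold, alpha=alpha, adjust=adjust
    )
    return calls, matrix, retained


__all__ = [
    "BACKGROUND_K",
    "ClusterResult",
    "FlagResult",
    "NormalizedMatrix",
    "PipelineError",
    "StatsError",
    "call_differential",
    "cluster_features",
    "evaluate_flags",
    "filter_probes",
    "flag_table",
    "normalize_one_colour",
    "run_expression_pipeline",
    "signals_to_matrix",
]
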