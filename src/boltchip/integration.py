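"""Joint DEG/DMR analysis and mitochondrial methylome profiling.

Sequences called both differentially expressed and differentially methylated
(DEMSs) are the intersection of the two significant call sets; for those, the
relationship between methylation and expression is quantified with Pearson and
Spearman correlations on paired normalized values (per genotype by default,
group means optionally). Cross-platform agreement (microarray vs qPCR fold
changes) uses Pearson correlation on log2 fold changes of the shared genes.

The organelle part maps dye-normalized log ratios onto the mitochondrial
genome as per-group mean tracks, partitions the genome into coding
(ORF/tRNA/rRNA) and non-coding regions from a GFF3 annotation, tests the
R-vs-S and coding-vs-non-coding contrasts, and detects DMR-rich loci by 1-D
single-linkage clustering of significant probe positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from ._stats import split_groups
from .array_design import PROBE_LENGTH

logger = logging.getLogger(__name__)

#: Annotation feature types counted as coding sequence on the organelle map.
CODING_FEATURES = ("ORF", "tRNA", "rRNA", "gene", "CDS")


class IntegrationError(ValueError):
    pass


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


@dataclass
class MitoTrack:
    """Positioned per-group mean log-ratio profile of the organelle genome."""

    positions: np.ndarray  # probe starts, bp, sorted
    mean_r: np.ndarray
    mean_s: np.ndarray
    is_coding: np.ndarray  # per probe, overlap with the coding partition
    genome_length: int
    coding_intervals: np.ndarray  # merged (start, end) pairs
    cpg_islands: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    probe_ids: list[str] = field(default_factory=list)

    @property
    def mean_overall(self) -> np.ndarray:
        return (self.mean_r + self.mean_s) / 2.0


@dataclass(frozen=True)
class DmrLocus:
    start: int
    end: int
    probe_ids: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.probe_ids)

    @property
    def span(self) -> int:
        return self.end - self.start


def find_dems(
    degs: pd.DataFrame,
    dmrs: pd.DataFrame,
    expression_matrix: pd.DataFrame | None = None,
    methylation_matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sequences significant in both the DEG and DMR call sets.

    Symmetric set intersection on ``significant`` ids, ordered by id. When the
    normalized matrices are supplied, per-genotype values and S/R group means
    from both platforms are attached (columns ``expr_<sample>``,
    ``meth_<sample>``, ``expr_S/expr_R/meth_S/meth_R`` if the sample names
    encode the groups via their leading R/S letter).
    """
    deg_ids = set(degs.index[degs["significant"].astype(bool)])
    dmr_ids = set(dmrs.index[dmrs["significant"].astype(bool)])
    joint = sorted(deg_ids & dmr_ids)
    out = pd.DataFrame(index=pd.Index(joint, name="sequence_id"))
    out["deg_direction"] = degs.loc[joint, "direction"]
    out["dmr_direction"] = dmrs.loc[joint, "direction"]
    for prefix, matrix in (("expr", expression_matrix), ("meth", methylation_matrix)):
        if matrix is None:
            continue
        missing = [i for i in joint if i not in matrix.index]
        if missing:
            raise IntegrationError(
                f"{prefix} matrix lacks values for DEMS ids: {missing}"
            )
        sub = matrix.loc[joint]
        for col in sub.columns:
            out[f"{prefix}_{col}"] = sub[col]
        groups = {g: [c for c in sub.columns if str(c).upper().startswith(g)] for g in "SR"}
        for g, cols in groups.items():
            if cols:
                out[f"{prefix}_{g}"] = sub[cols].mean(axis=1)
    return out


def meth_expr_correlation(
    records: pd.DataFrame,
    level: Literal["per_genotype", "group_mean"] = "per_genotype",
) -> CorrelationResult:
    """Correlation between paired methylation and expression values of DEMSs.

    ``per_genotype`` pairs each sequence's per-genotype values (six pairs per
    sequence for a 3+3 panel); ``group_mean`` pairs the S and R group means
    (two pairs per sequence). Pearson is computed on the raw pairs, Spearman
    on average ranks, both with two-sided p-values.
    """
    meth, expr = _paired_values(records, level)
    if len(meth) < 3:
        raise IntegrationError("need >= 3 paired values for correlation")
    if np.std(meth) == 0 or np.std(expr) == 0:
        raise IntegrationError("zero variance: correlation undefined")
    pear = stats.pearsonr(meth, expr)
    spear = stats.spearmanr(meth, expr)
    return CorrelationResult(
        pearson_r=float(pear.statistic),
        pearson_p=float(pear.pvalue),
        spearman_rho=float(spear.statistic),
        spearman_p=float(spear.pvalue),
        n=len(meth),
    )


def _paired_values(records: pd.DataFrame, level: str) -> tuple[np.ndarray, np.ndarray]:
    if level == "group_mean":
        cols = [("meth_S", "expr_S"), ("meth_R", "expr_R")]
    elif level == "per_genotype":
        meth_cols = [
            c for c in records.columns
            if c.startswith("meth_") and c not in ("meth_S", "meth_R")
        ]
        cols = [(m, "expr_" + m[len("meth_"):]) for m in meth_cols]
        cols = [(m, e) for m, e in cols if e in records.columns]
    else:
        raise IntegrationError(f"unknown correlation level {level!r}")
    missing = [c for pair in cols for c in pair if c not in records.columns]
    if missing or not cols:
        raise IntegrationError(f"records lack paired value columns: {missing or level}")
    meth = np.concatenate([records[m].to_numpy(float) for m, _ in cols])
    expr = np.concatenate([records[e].to_numpy(float) for _, e in cols])
    ok = np.isfinite(meth) & np.isfinite(expr)
    return meth[ok], expr[ok]


def compare_platform_fold_changes(
    fc_a: pd.Series, fc_b: pd.Series, log_transform: bool = True
) -> CorrelationResult:
    """Pearson agreement of per-gene fold changes from two platforms.

    Fold changes are compared on the log2 scale (set ``log_transform=False``
    when the inputs are already log ratios). Requires >= 3 shared genes.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise IntegrationError("need >= 3 shared genes to compare platforms")
    a = fc_a.loc[shared].to_numpy(float)
    b = fc_b.loc[shared].to_numpy(float)
    if log_transform:
        a, b = np.log2(a), np.log2(b)
    pear = stats.pearsonr(a, b)
    spear = stats.spearmanr(a, b)
    return CorrelationResult(
        pearson_r=float(pear.statistic),
        pearson_p=float(pear.pvalue),
        spearman_rho=float(spear.statistic),
        spearman_p=float(spear.pvalue),
        n=len(shared),
    )


# ---------------------------------------------------------------------------
# Mitochondrial methylome


def read_annotation(gff3_path) -> pd.DataFrame:
    """Load organelle annotation intervals from GFF3 (0-based half-open)."""
    gr = pr.read_gff3(str(gff3_path))
    return gr.df[["Chromosome", "Feature", "Start", "End"]]


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=int)
    order = np.argsort(intervals[:, 0])
    merged = [list(intervals[order[0]])]
    for start, end in intervals[order[1:]]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=int)


def mito_methylome_profile(
    ratio_matrix: pd.DataFrame,
    probe_coordinates: pd.Series,
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    genome_length: int,
    probe_length: int = PROBE_LENGTH,
) -> MitoTrack:
    """Per-position R/S mean log-ratio track with a coding/non-coding partition.

    ``probe_coordinates`` maps probe_id -> start (bp, 0-based) on the organelle
    genome; probes without a coordinate are excluded (logged). A probe counts
    as coding when its interval overlaps the merged union of ORF/tRNA/rRNA
    annotation intervals. No smoothing is applied.
    """
    s_ids, r_ids = split_groups(design)
    have_coord = ratio_matrix.index.intersection(probe_coordinates.index)
    dropped = len(ratio_matrix.index) - len(have_coord)
    if dropped:
        logger.info("mito profile: %d probes without coordinates excluded", dropped)
    coords = probe_coordinates.loc[have_coord].astype(int)
    if (coords < 0).any() or (coords + probe_length > genome_length).any():
        raise IntegrationError("probe coordinates outside the organelle genome")
    order = np.argsort(coords.to_numpy(), kind="stable")
    probe_ids = coords.index.to_numpy()[order]
    positions = coords.to_numpy()[order]
    sub = ratio_matrix.loc[probe_ids]

    coding_mask = annotation["Feature"].isin(CODING_FEATURES)
    coding = _merge_intervals(
        annotation.loc[coding_mask, ["Start", "End"]].to_numpy(int)
    )
    cpg = annotation.loc[
        annotation["Feature"].str.lower().str.contains("cpg"), ["Start", "End"]
    ].to_numpy(int)
    is_coding = _overlaps(positions, positions + probe_length, coding)

    return MitoTrack(
        positions=positions,
        mean_r=sub[r_ids].mean(axis=1).to_numpy(float),
        mean_s=sub[s_ids].mean(axis=1).to_numpy(float),
        is_coding=is_coding,
        genome_length=int(genome_length),
        coding_intervals=coding,
        cpg_islands=cpg,
        probe_ids=list(probe_ids),
    )


def _overlaps(starts: np.ndarray, ends: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Whether each [start, end) overlaps any of the sorted merged intervals."""
    if len(intervals) == 0:
        return np.zeros(len(starts), dtype=bool)
    iv_starts, iv_ends = intervals[:, 0], intervals[:, 1]
    idx = np.searchsorted(iv_starts, ends, side="left") - 1
    prev = np.clip(idx, 0, len(intervals) - 1)
    hit_prev = (idx >= 0) & (iv_ends[prev] > starts)
    nxt = np.clip(idx + 1, 0, len(intervals) - 1)
    hit_next = (idx + 1 < len(intervals)) & (iv_starts[nxt] < ends)
    return hit_prev | hit_next


def compare_track_groups(
    track: MitoTrack,
    contrast: Literal["R_vs_S", "coding_vs_noncoding"],
) -> dict:
    """Test a contrast on the organelle track.

    ``R_vs_S`` is a paired two-sided t-test across probes on the per-probe R
    and S group means (the same probes are measured in both groups);
    ``coding_vs_noncoding`` is a two-sample t-test on per-probe overall means
    grouped by the annotation partition. Returns the statistic, two-sided p,
    mean difference, and its direction. Probes are treated as spatially
    independent.
    """
    if contrast == "R_vs_S":
        a, b = track.mean_r, track.mean_s
        if len(a) < 10:
            raise IntegrationError("need >= 10 probes for the R-vs-S contrast")
        res = stats.ttest_rel(a, b)
        diff = float(np.mean(a - b))
        direction = "R>S" if diff > 0 else "S>R"
    elif contrast == "coding_vs_noncoding":
        values = track.mean_overall
        coding = values[track.is_coding]
        noncoding = values[~track.is_coding]
        if len(coding) < 10 or len(noncoding) < 10:
            raise IntegrationError("need >= 10 probes on each side of the contrast")
        res = stats.ttest_ind(noncoding, coding)
        diff = float(np.mean(noncoding) - np.mean(coding))
        direction = "noncoding>coding" if diff > 0 else "coding>noncoding"
    else:
        raise IntegrationError(f"unknown contrast {contrast!r}")
    return {
        "contrast": contrast,
        "t_stat": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_difference": diff,
        "direction": direction,
    }


def find_dmr_rich_loci(
    dmr_probe_positions: Sequence[int] | pd.Series,
    max_gap: int = 5000,
    min_probes: int = 3,
    probe_length: int = PROBE_LENGTH,
    probe_ids: Sequence[str] | None = None,
) -> list[DmrLocus]:
    """1-D single-linkage clustering of DMR probe positions into loci.

    Consecutive sorted positions at most ``max_gap`` bp apart join the same
    locus; loci with fewer than ``min_probes`` members are discarded. A locus
    spans from its first probe start to its last probe end. The result is
    independent of the input order.
    """
    if probe_ids is None:
        if isinstance(dmr_probe_positions, pd.Series):
            probe_ids = [str(i) for i in dmr_probe_positions.index]
        else:
            probe_ids = [f"probe_{p}" for p in dmr_probe_positions]
    pairs = sorted(zip((int(p) for p in dmr_probe_positions), probe_ids))
    loci: list[DmrLocus] = []
    cluster: list[tuple[int, str]] = []
    for pos, pid in pairs:
        if cluster and pos - cluster[-1][0] > max_gap:
            loci.append(_make_locus(cluster, probe_length))
            cluster = []
        cluster.append((pos, pid))
    if cluster:
        loci.append(_make_locus(cluster, probe_length))
    return [l for l in loci if l.count >= min_probes]


def _make_locus(cluster: list[tuple[int, str]], probe_length: int) -> DmrLocus:
    return DmrLocus(
        start=cluster[0][0],
        end=cluster[-1][0] + probe_length,
        probe_ids=tuple(pid for _, pid in cluster),
    )


def track_to_bedgraph(track: MitoTrack, group: Literal["R", "S"], path, chrom: str = "mito") -> None:
    """Write one group's mean track as bedGraph."""
    values = track.mean_r if group == "R" else track.mean_s
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": track.positions,
            "end": track.positions + PROBE_LENGTH,
            "value": values,
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)
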