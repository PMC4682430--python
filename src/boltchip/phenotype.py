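"""Bolting phenotype metrics and SNP-based genotype clustering.

Bolting tolerance of biennial beet genotypes is scored after cold exposure
with two metrics: the bolting index (BI), the percentage of plants that have
bolted, and the bolting delay (BD), the mean number of days to visible bolting
initiation among the plants that bolted. Genotypes reaching a high final BI
after the longest cold treatment are classed sensitive (S), those staying low
resistant (R). Genetic relatedness is summarized by identity-by-state (IBS)
distance over a biallelic SNP matrix with average-linkage clustering and a
principal-coordinate variance summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from ._linkage import average_linkage, leaf_order, to_newick

#: Cold durations (weeks) of the standard vernalization series.
COLD_DURATIONS = (0, 3, 9, 18)

#: Final-BI classification thresholds (%), anchored to the observed extremes
#: (sensitive genotypes reach 75-100%, the weakest resistant response is 15%).
SENSITIVE_MIN_BI = 75.0
RESISTANT_MAX_BI = 20.0


class PhenotypeError(ValueError):
    pass


@dataclass
class BoltingPhenotype:
    """Per-plant bolting observations for one genotype.

    ``observations`` columns: duration_weeks, plant_id, bolt_day (NaN for
    plants that never bolted; censored plants still count in BI denominators).
    """

    genotype_id: str
    observations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def at_duration(self, duration: int) -> pd.DataFrame:
        return self.observations[self.observations["duration_weeks"] == duration]


def bolting_index(phenotype: BoltingPhenotype, duration: int) -> float:
    """Percentage of plants bolted at the given cold duration."""
    obs = phenotype.at_duration(duration)
    n = len(obs)
    if n == 0:
        raise PhenotypeError(
            f"no plants observed for {phenotype.genotype_id} at {duration} weeks"
        )
    return 100.0 * obs["bolt_day"].notna().sum() / n


def bolting_delay(phenotype: BoltingPhenotype, duration: int) -> float:
    """Mean day of bolting among bolted plants at the given duration.

    Censored (never-bolting) plants are excluded from the average; with no
    bolters the delay is undefined and an error is raised rather than zero.
    """
    days = phenotype.at_duration(duration)["bolt_day"].dropna()
    if days.empty:
        raise PhenotypeError(
            f"bolting delay undefined for {phenotype.genotype_id}: no bolted plants"
        )
    return float(days.mean())


def bi_curve(phenotype: BoltingPhenotype) -> pd.Series:
    durations = sorted(phenotype.observations["duration_weeks"].unique())
    return pd.Series(
        {d: bolting_index(phenotype, d) for d in durations}, name=phenotype.genotype_id
    )


def classify_tolerance(
    curve: pd.Series,
    sensitive_min: float = SENSITIVE_MIN_BI,
    resistant_max: float = RESISTANT_MAX_BI,
) -> str:
    """Classify a BI curve as ``"S"``, ``"R"`` or ``"intermediate"``.

    The decision uses the BI at the final (longest) cold duration: sensitive
    at >= ``sensitive_min`` %, resistant at <= ``resistant_max`` %.
    """
    if curve.empty:
        raise PhenotypeError("empty bolting-index curve")
    final = curve.loc[max(curve.index)]
    if pd.isna(final):
        raise PhenotypeError("final-duration bolting index missing")
    if final >= sensitive_min:
        return "S"
    if final <= resistant_max:
        return "R"
    return "intermediate"


# ---------------------------------------------------------------------------
# SNP clustering


@dataclass
class GenotypeClustering:
    distance: pd.DataFrame
    merge_tree: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    pc_variance_fraction: float  # fraction of variance on the first two PCo axes

    def to_newick(self) -> str:
        return to_newick(self.merge_tree, self.labels)


def ibs_distance(snps: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - identity-by-state distance over a genotype x marker matrix.

    Genotypes are coded 0/1/2 (NaN missing); per pair the IBS proportion is
    ``mean(1 - |a - b| / 2)`` over markers called in both genotypes.
    """
    mat = snps.to_numpy(dtype=float)
    n = mat.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(mat[i]) & np.isfinite(mat[j])
            if not both.any():
                raise PhenotypeError(
                    f"no shared called markers between genotypes "
                    f"{snps.index[i]!r} and {snps.index[j]!r}"
                )
            ibs = 1.0 - np.abs(mat[i, both] - mat[j, both]) / 2.0
            dist[i, j] = dist[j, i] = 1.0 - ibs.mean()
    return pd.DataFrame(dist, index=snps.index, columns=snps.index)


def cluster_genotypes(snps: pd.DataFrame) -> GenotypeClustering:
    """Average-linkage IBS clustering with a principal-coordinate summary.

    Markers missing in every genotype are dropped. The variance summary is the
    fraction of total (positive-eigenvalue) variance carried by the first two
    principal coordinates of the IBS distance matrix; it is reported, not
    thresholded.
    """
    if len(snps) < 3:
        raise PhenotypeError("need >= 3 genotypes to cluster")
    snps = snps.loc[:, snps.notna().any(axis=0)]
    dist = ibs_distance(snps)
    tree = average_linkage(dist.to_numpy())
    labels = [str(i) for i in snps.index]
    ordination = pcoa(
        DistanceMatrix(dist.to_numpy(), ids=labels), number_of_dimensions=min(len(snps) - 1, 3)
    )
    frac = float(ordination.proportion_explained.iloc[:2].sum())
    return GenotypeClustering(
        distance=dist,
        merge_tree=tree,
        labels=labels,
        leaf_order=leaf_order(tree, labels),
        pc_variance_fraction=frac,
    )


def read_phenotypes(path) -> list[BoltingPhenotype]:
    """Load per-plant phenotype observations from TSV.

    Columns: genotype_id, duration_weeks, plant_id, bolt_day (empty = censored).
    """
    table = pd.read_csv(path, sep="\t")
    return [
        BoltingPhenotype(genotype_id=str(g), observations=obs.reset_index(drop=True))
        for g, obs in table.groupby("genotype_id", sort=True)
    ]


def phenotype_summary(phenotypes: list[BoltingPhenotype]) -> pd.DataFrame:
    """Per-genotype BI at each duration, final BD where defined, and class."""
    rows = []
    for p in phenotypes:
        curve = bi_curve(p)
        final = max(curve.index)
        try:
            bd = bolting_delay(p, final)
        except PhenotypeError:
            bd = np.nan
        rows.append(
            {
                "genotype_id": p.genotype_id,
                **{f"bi_{d}w": v for d, v in curve.items()},
                "bd_final_days": bd,
                "tolerance_class": classify_tolerance(curve),
            }
        )
    return pd.DataFrame(rows)
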