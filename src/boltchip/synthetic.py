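"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design — a panel of three bolting-resistant
(R1-R3) and three bolting-sensitive (S1-S3) biennial sugar beet genotypes, one
one-colour expression array and one two-colour MeDIP array per genotype — with
planted ground truth:

* 169 differentially expressed sequences, 82 up in S and 87 up in R;
* 111 differentially methylated sequences, all hypermethylated in S;
* 14 jointly differential (DEMS) sequences shared between the two sets;
* a mitochondrial track with R above S genome-wide, non-coding above coding,
  and two DMR-rich loci of 10-15 kb hypermethylated in R;
* a biallelic SNP matrix whose two genetic clusters are drawn independently
  of the tolerance groups.

Noise model: log-normal signals with additive Gaussian noise on the log2
scale; two-colour arrays additionally carry a per-sample multiplicative Cy5
dye bias that the linear normalization must remove. The error model is a
modelling choice (the study reports none); all its parameters live in
:class:`SimulationConfig`.

Every generator derives its randomness from ``config.seed`` through
independent named substreams, so each output table is bit-identical across
runs and across call orders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fixtures
from .array_design import PROBE_LENGTH, tile_sequence
from .phenotype import BoltingPhenotype

logger = logging.getLogger(__name__)

SATURATION_SCALE = 65_535.0

_STREAMS = {
    "truth": 11,
    "panel": 13,
    "expression": 17,
    "medip": 19,
    "mito": 23,
    "snp": 29,
    "dye": 31,
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-structure and noise parameters of the synthetic datasets.

    Defaults are desk-scale (~10x fewer probes than the real arrays);
    ``full_scale()`` restores the full 53 752 / 227 242 probe counts.
    """

    seed: int = 0
    n_resistant: int = 3
    n_sensitive: int = 3
    n_expr_probes: int = 5000
    n_meth_probes: int = 20000
    n_planted_degs: int = 169
    n_deg_up_in_s: int = 82
    n_deg_up_in_r: int = 87
    n_planted_dmrs: int = 111
    n_dems: int = 14
    deg_effect: float = 1.6  # log2 shift of a planted DEG in its group
    dmr_effect: float = 1.5  # log2-ratio shift of a planted DMR in S
    noise_sd: float = 0.2  # per-measurement log2 noise
    flag_failure_rate: float = 0.01  # per probe/sample saturation-or-outlier rate
    background_fail_rate: float = 0.10  # fraction of probes below background
    dye_bias_factor: float = 1.5  # per-sample Cy5 bias drawn in [1/f, f]
    n_plants: int = 12
    mito_length: int = fixtures.MITO_GENOME_BP
    n_mito_orfs: int = 40
    n_mito_rnas: int = 25
    n_cpg_islands: int = 15
    mito_baseline: float = -0.5  # organelle log ratios sit below zero
    mito_r_offset: float = 0.3  # R-over-S genome-wide methylation offset
    mito_noncoding_offset: float = 0.4  # non-coding over coding offset
    mito_dmr_effect: float = 1.2  # extra R shift inside the DMR-rich loci
    mito_locus_spans: tuple[int, int] = (12_000, 14_500)
    n_snps: int = 708
    snp_missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_deg_up_in_s + self.n_deg_up_in_r != self.n_planted_degs:
            raise ConfigError("direction split must sum to n_planted_degs")
        if self.n_dems > min(self.n_planted_degs, self.n_planted_dmrs) and self.n_dems:
            raise ConfigError("n_dems cannot exceed either planted call set")
        for name in ("flag_failure_rate", "background_fail_rate", "snp_missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_planted_degs > self.n_expr_probes:
            raise ConfigError("cannot plant more DEGs than expression probes")
        if self.n_planted_dmrs > self.n_meth_probes:
            raise ConfigError("cannot plant more DMRs than methylation probes")
        if self.mito_length < 10_000:
            raise ConfigError("mito_length must be >= 10 kb")

    def full_scale(self) -> "SimulationConfig":
        return replace(self, n_expr_probes=53_752, n_meth_probes=227_242)

    @property
    def genotypes(self) -> list[str]:
        return [f"R{i}" for i in range(1, self.n_resistant + 1)] + [
            f"S{i}" for i in range(1, self.n_sensitive + 1)
        ]


@dataclass
class GroundTruth:
    """Planted effects, keyed by ids resolvable in the generated tables."""

    deg_directions: dict[str, str] = field(default_factory=dict)
    dmr_directions: dict[str, str] = field(default_factory=dict)
    dems_ids: list[str] = field(default_factory=list)
    background_fail_expr: list[str] = field(default_factory=list)
    background_fail_meth: list[str] = field(default_factory=list)
    mito_offsets: dict[str, float] = field(default_factory=dict)
    mito_locus_windows: list[tuple[int, int]] = field(default_factory=list)
    snp_clusters: dict[str, int] = field(default_factory=dict)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


def expression_probe_ids(config: SimulationConfig) -> list[str]:
    return [f"SEQ{i:06d}" for i in range(config.n_expr_probes)]


def methylation_probe_ids(config: SimulationConfig) -> list[str]:
    """Methylation ids share the expression namespace where possible; the
    remainder are methylation-only regions."""
    shared = expression_probe_ids(config)[: config.n_meth_probes]
    extra = [f"MREG{i:06d}" for i in range(config.n_meth_probes - len(shared))]
    return shared + extra


def plant_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted DEG/DMR/DEMS id sets (one shared seeded substream).

    Both array generators call this, so the joint (DEMS) structure is
    consistent without the generators sharing state. Background-failing
    probes are drawn first and excluded from planting, which keeps planted
    effects recoverable in the noiseless limit.
    """
    rng = _rng(config, "truth")
    expr_ids = np.array(expression_probe_ids(config))
    meth_ids = np.array(methylation_probe_ids(config))

    n_bg_e = round(config.background_fail_rate * len(expr_ids))
    bg_expr = set(rng.choice(expr_ids, size=n_bg_e, replace=False))
    n_bg_m = round(config.background_fail_rate * len(meth_ids))
    bg_meth = set(rng.choice(meth_ids, size=n_bg_m, replace=False))

    meth_id_set = set(meth_ids)
    shared_ok = [
        i for i in expr_ids if i in meth_id_set and i not in bg_expr and i not in bg_meth
    ]
    if len(shared_ok) < config.n_dems:
        raise ConfigError("shared id namespace too small for the requested DEMS count")
    dems = sorted(rng.choice(np.array(shared_ok), size=config.n_dems, replace=False))

    deg_pool = np.array(
        [i for i in expr_ids if i not in bg_expr and i not in set(dems)]
    )
    other_degs = rng.choice(deg_pool, size=config.n_planted_degs - config.n_dems, replace=False)
    deg_ids = np.concatenate([np.array(dems, dtype=other_degs.dtype), other_degs])
    directions = np.array(
        ["up_in_S"] * config.n_deg_up_in_s + ["up_in_R"] * config.n_deg_up_in_r
    )
    rng.shuffle(directions)
    deg_directions = dict(zip(deg_ids.tolist(), directions.tolist()))

    dmr_pool = np.array(
        [i for i in meth_ids if i not in bg_meth and i not in deg_directions]
    )
    other_dmrs = rng.choice(dmr_pool, size=config.n_planted_dmrs - config.n_dems, replace=False)
    dmr_ids = np.concatenate([np.array(dems, dtype=other_dmrs.dtype), other_dmrs])
    dmr_directions = {i: "hyper_in_S" for i in dmr_ids.tolist()}

    return GroundTruth(
        deg_directions=deg_directions,
        dmr_directions=dmr_directions,
        dems_ids=list(dems),
        background_fail_expr=sorted(bg_expr),
        background_fail_meth=sorted(bg_meth),
    )


def sample_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: one array per genotype, condition = leading R/S letter."""
    return pd.DataFrame(
        {
            "sample_id": config.genotypes,
            "genotype_id": config.genotypes,
            "condition": [g[0] for g in config.genotypes],
        }
    )


def generate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, list[BoltingPhenotype]]:
    """Genotype panel with bolting-index curves matching the study structure.

    Sensitive genotypes start bolting from 9 weeks of cold and reach a final
    BI of 75-100% with bolting delays of 17-55 d; resistant genotypes stay at
    or below 20% (at most two bolters of twelve, delays around 85 d).
    """
    rng = _rng(config, "panel")
    design = sample_design(config)
    phenotypes = []
    durations = (0, 3, 9, 18)
    for genotype in config.genotypes:
        sensitive = genotype.startswith("S")
        rows = []
        for duration in durations:
            if sensitive:
                if duration < 9:
                    n_bolted = 0
                elif duration == 9:
                    n_bolted = int(rng.integers(2, config.n_plants // 2 + 1))
                else:
                    frac = rng.uniform(0.75, 1.0)
                    n_bolted = max(int(np.ceil(frac * config.n_plants)), 9)
                days = rng.integers(17, 56, size=n_bolted)
            else:
                n_bolted = int(rng.integers(0, 3)) if duration == 18 else 0
                days = rng.integers(80, 91, size=n_bolted)
            for plant in range(config.n_plants):
                rows.append(
                    {
                        "duration_weeks": duration,
                        "plant_id": f"{genotype}_p{plant + 1:02d}",
                        "bolt_day": float(days[plant]) if plant < n_bolted else np.nan,
                    }
                )
        phenotypes.append(
            BoltingPhenotype(genotype_id=genotype, observations=pd.DataFrame(rows))
        )
    return design, phenotypes


def _true_log2_matrix(
    ids: list[str],
    samples: list[str],
    baseline: np.ndarray,
    effects: dict[str, str],
    effect_size: float,
    high_label: str,
) -> np.ndarray:
    """Baseline per probe plus the planted group shift."""
    values = np.tile(baseline[:, None], (1, len(samples)))
    id_pos = {p: i for i, p in enumerate(ids)}
    s_cols = [j for j, s in enumerate(samples) if s.startswith("S")]
    r_cols = [j for j, s in enumerate(samples) if s.startswith("R")]
    for probe, direction in effects.items():
        cols = s_cols if direction == high_label else r_cols
        values[id_pos[probe], cols] += effect_size
    return values


def _qc_columns(
    rng: np.random.Generator,
    signal: np.ndarray,
    bg_fail: np.ndarray,
    flag_ok: np.ndarray,
    flag_rate: float,
) -> dict[str, np.ndarray]:
    """Background and flag columns consistent with their own semantics.

    ``bg_fail`` marks probes whose local background SD is too high for the
    2.6 x SD rule in every sample; saturation/outlier flags are drawn at
    ``flag_rate`` only where ``flag_ok`` allows (non-planted probes), and
    saturated features carry max-scale signals.
    """
    n_probes, n_samples = signal.shape
    bg_sub = signal.copy()
    bg_sd = bg_sub / (2.6 * 2.0)
    bg_sd[bg_fail, :] = bg_sub[bg_fail, :] / (2.6 * 0.5)
    saturated = (rng.random(signal.shape) < flag_rate / 2) & flag_ok[:, None]
    outlier = (rng.random(signal.shape) < flag_rate / 2) & flag_ok[:, None]
    signal = signal.copy()
    signal[saturated] = SATURATION_SCALE
    return {
        "signal": signal,
        "bg_sub": bg_sub,
        "bg_sd": bg_sd,
        "saturated": saturated,
        "outlier": outlier,
    }


def generate_expression_signals(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """One-colour signal table with planted DEGs.

    Baseline log2 expression per probe is N(8, 1.5); a planted DEG is shifted
    by ``deg_effect`` in its designated group; measurement noise is
    N(0, noise_sd) on the log2 scale. Returns a long-format table with the
    one-colour signal columns plus the ground truth.
    """
    if truth is None:
        truth = plant_truth(config)
    rng = _rng(config, "expression")
    ids = expression_probe_ids(config)
    samples = config.genotypes
    baseline = rng.normal(8.0, 1.5, size=len(ids))
    values = _true_log2_matrix(
        ids, samples, baseline, truth.deg_directions, config.deg_effect, "up_in_S"
    )
    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    raw = np.power(2.0, values)
    bg_fail = np.isin(ids, truth.background_fail_expr)
    flag_ok = ~(np.isin(ids, list(truth.deg_directions)) | bg_fail)
    qc = _qc_columns(rng, raw, bg_fail, flag_ok, config.flag_failure_rate)
    n, m = len(ids), len(samples)
    table = pd.DataFrame(
        {
            "probe_id": np.repeat(ids, m),
            "sample_id": np.tile(samples, n),
            "raw_signal": qc["signal"].ravel(),
            "bg_sub_signal": qc["bg_sub"].ravel(),
            "bg_sd": qc["bg_sd"].ravel(),
            "is_saturated": qc["saturated"].ravel(),
            "is_nonuniform_outlier": qc["outlier"].ravel(),
        }
    )
    return table, truth


def dye_biases(config: SimulationConfig) -> dict[str, float]:
    """Per-sample Cy5 dye-bias factors, drawn in ``[1/f, f]``.

    A single substream keyed only by the seed serves both the nuclear and the
    organelle generator: the organelle probes belong to the same physical
    array as the nuclear ones, so each sample has one dye bias.
    """
    rng = _rng(config, "dye")
    return {
        s: float(config.dye_bias_factor ** rng.uniform(-1.0, 1.0))
        for s in config.genotypes
    }


def _two_colour_table(
    rng: np.random.Generator,
    ids: list[str],
    samples: list[str],
    true_ratio: np.ndarray,
    noise_sd: float,
    dye_bias: dict[str, float],
    bg_fail: np.ndarray,
    flag_ok: np.ndarray,
    flag_rate: float,
    abundance_mean: float = 10.0,
) -> pd.DataFrame:
    abundance = np.power(2.0, rng.normal(abundance_mean, 1.0, size=len(ids)))
    cy3 = np.tile(abundance[:, None], (1, len(samples)))
    bias = np.array([dye_bias[s] for s in samples])
    noisy_ratio = true_ratio + rng.normal(0.0, noise_sd, size=true_ratio.shape)
    cy5 = cy3 * np.power(2.0, noisy_ratio) * bias[None, :]
    qc3 = _qc_columns(rng, cy3, bg_fail, flag_ok, flag_rate)
    qc5 = _qc_columns(rng, cy5, bg_fail, flag_ok, flag_rate)
    n, m = len(ids), len(samples)
    return pd.DataFrame(
        {
            "probe_id": np.repeat(ids, m),
            "sample_id": np.tile(samples, n),
            "cy3_signal": qc3["signal"].ravel(),
            "cy5_signal": qc5["signal"].ravel(),
            "cy3_bg_sub": qc3["bg_sub"].ravel(),
            "cy3_bg_sd": qc3["bg_sd"].ravel(),
            "cy5_bg_sub": qc5["bg_sub"].ravel(),
            "cy5_bg_sd": qc5["bg_sd"].ravel(),
            "cy3_saturated": qc3["saturated"].ravel(),
            "cy5_saturated": qc5["saturated"].ravel(),
            "cy3_outlier": qc3["outlier"].ravel(),
            "cy5_outlier": qc5["outlier"].ravel(),
        }
    )


def generate_medip_signals(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-colour MeDIP signal table with planted hyper-in-S DMRs.

    True log ratios are zero at baseline; planted DMRs gain ``dmr_effect`` in
    the sensitive genotypes. Each sample's Cy5 channel is multiplied by a
    drawn dye-bias factor that the linear normalization must recover.
    """
    if truth is None:
        truth = plant_truth(config)
    rng = _rng(config, "medip")
    ids = methylation_probe_ids(config)
    samples = config.genotypes
    true_ratio = _true_log2_matrix(
        ids,
        samples,
        np.zeros(len(ids)),
        truth.dmr_directions,
        config.dmr_effect,
        "hyper_in_S",
    )
    bg_fail = np.isin(ids, truth.background_fail_meth)
    flag_ok = ~(np.isin(ids, list(truth.dmr_directions)) | bg_fail)
    table = _two_colour_table(
        rng,
        ids,
        samples,
        true_ratio,
        config.noise_sd,
        dye_biases(config),
        bg_fail,
        flag_ok,
        config.flag_failure_rate,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Mitochondrial dataset


def _pack_intervals(
    rng: np.random.Generator,
    genome_length: int,
    lengths: list[int],
    occupied: list[tuple[int, int]],
    max_attempts: int = 2000,
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for length in lengths:
        for attempt in range(max_attempts):
            start = int(rng.integers(0, genome_length - length))
            end = start + length
            if all(end <= s or start >= e for s, e in taken):
                placed.append((start, end))
                taken.append((start, end))
                break
        else:
            raise ConfigError("interval packing failed; loosen counts or lengths")
    return placed


def generate_mito_dataset(
    config: SimulationConfig,
) -> tuple[str, pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Synthetic organelle genome, annotation, signals, and coordinates.

    Returns (genome sequence, annotation table, two-colour signal table,
    probe-coordinate series, ground truth). The genome is random sequence of
    ``mito_length`` bp; ORFs and tRNA/rRNA intervals are packed without
    overlap; probes tile the genome at 100 bp. True log ratios carry the
    planted structure: R above S genome-wide, non-coding above coding, two
    DMR-rich windows (spans per config) extra-hypermethylated in R. Interval
    packing retries with an advanced seed when it fails (logged).

    The organelle probes sit on the same physical array as the nuclear probes
    of :func:`generate_medip_signals` and share its per-sample dye biases.
    The linear dye normalization equalizes channel means, so on an
    organelle-only table the genome-wide group offset would be absorbed into
    the scale factors; pool this table with the nuclear table before building
    the ratio matrix and restrict to organelle probe ids afterwards, as the
    workflow runner does.
    """
    config_try = config
    for advance in range(5):
        rng = _rng(config_try, "mito")
        try:
            annotation, windows = _mito_annotation(rng, config_try)
            break
        except ConfigError:
            logger.warning("mito interval packing failed; advancing seed")
            config_try = replace(config_try, seed=config_try.seed + 100_003)
    else:
        raise ConfigError("mito interval packing failed after seed advances")

    genome = "".join(rng.choice(list("ACGT"), size=config.mito_length))
    probes = tile_sequence(
        "MITO", config.mito_length, spacing=100, design_class="mito_genome"
    )
    ids = [p.probe_id for p in probes]
    starts = np.array([p.start for p in probes])
    coords = pd.Series(starts, index=pd.Index(ids, name="probe_id"), name="start")

    coding_mask = annotation["Feature"].isin(("ORF", "tRNA", "rRNA"))
    coding = annotation.loc[coding_mask, ["Start", "End"]].to_numpy(int)
    probe_coding = np.zeros(len(ids), dtype=bool)
    for s, e in coding:
        probe_coding |= (starts + PROBE_LENGTH > s) & (starts < e)

    samples = config.genotypes
    r_cols = np.array([s.startswith("R") for s in samples])
    base = np.full(len(ids), config.mito_baseline)
    base[~probe_coding] += config.mito_noncoding_offset
    true_ratio = np.tile(base[:, None], (1, len(samples)))
    true_ratio[:, r_cols] += config.mito_r_offset
    in_window = np.zeros(len(ids), dtype=bool)
    for w_start, w_end in windows:
        in_window |= (starts >= w_start) & (starts + PROBE_LENGTH <= w_end)
    true_ratio[np.ix_(in_window, r_cols)] += config.mito_dmr_effect

    bg_fail = np.zeros(len(ids), dtype=bool)
    flag_ok = ~in_window
    table = _two_colour_table(
        rng,
        ids,
        samples,
        true_ratio,
        config.noise_sd,
        dye_biases(config),
        bg_fail,
        flag_ok,
        config.flag_failure_rate,
    )
    truth = GroundTruth(
        dmr_directions={i: "hyper_in_R" for i, w in zip(ids, in_window) if w},
        mito_offsets={
            "r_minus_s": config.mito_r_offset,
            "noncoding_minus_coding": config.mito_noncoding_offset,
            "locus_effect": config.mito_dmr_effect,
        },
        mito_locus_windows=[tuple(w) for w in windows],
    )
    return genome, annotation, table, coords, truth


def _mito_annotation(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    length = config.mito_length
    # Structure is preserved proportionally on shorter test genomes: the
    # configured feature counts and DMR-locus spans refer to the full-length
    # organelle genome and scale down with it.
    scale = min(1.0, length / fixtures.MITO_GENOME_BP)
    span1, span2 = (max(500, round(s * scale)) for s in config.mito_locus_spans)
    w1 = int(rng.integers(0, length // 2 - span1))
    w2 = int(rng.integers(length // 2, length - span2))
    windows = [(w1, w1 + span1), (w2, w2 + span2)]

    n_orfs = max(3, round(config.n_mito_orfs * scale))
    n_rnas = max(2, round(config.n_mito_rnas * scale))
    n_cpgs = max(1, round(config.n_cpg_islands * scale))
    orf_lengths = rng.integers(300, 2001, size=n_orfs).tolist()
    rna_lengths = rng.integers(70, 3001, size=n_rnas).tolist()
    orfs = _pack_intervals(rng, length, orf_lengths, [])
    rnas = _pack_intervals(rng, length, rna_lengths, orfs)
    cpg_lengths = rng.integers(200, 1001, size=n_cpgs).tolist()
    cpgs = _pack_intervals(rng, length, cpg_lengths, [])

    rows = (
        [{"Chromosome": "MITO", "Feature": "ORF", "Start": s, "End": e} for s, e in orfs]
        + [
            {"Chromosome": "MITO", "Feature": rng.choice(["tRNA", "rRNA"]), "Start": s, "End": e}
            for s, e in rnas
        ]
        + [
            {"Chromosome": "MITO", "Feature": "CpG_island", "Start": s, "End": e}
            for s, e in cpgs
        ]
    )
    annotation = pd.DataFrame(rows).sort_values(["Start", "End"]).reset_index(drop=True)
    return annotation, windows


def generate_snp_matrix(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Biallelic SNP matrix with two clusters independent of tolerance groups.

    Each marker has cluster-specific allele frequencies drawn from a U-shaped
    Beta(0.5, 0.5); genotype calls are Binomial(2, p). Cluster membership is
    assigned by the seeded generator without reference to the R/S labels.
    """
    if config.n_snps < 10:
        raise ConfigError("n_snps must be >= 10")
    rng = _rng(config, "snp")
    genotypes = config.genotypes
    while True:
        labels = rng.integers(0, 2, size=len(genotypes))
        if 0 < labels.sum() < len(genotypes):
            break
    freqs = rng.beta(0.5, 0.5, size=(2, config.n_snps))
    calls = rng.binomial(2, freqs[labels, :]).astype(float)
    missing = rng.random(calls.shape) < config.snp_missing_rate
    calls[missing] = np.nan
    matrix = pd.DataFrame(
        calls,
        index=pd.Index(genotypes, name="genotype_id"),
        columns=[f"SNP{i:04d}" for i in range(config.n_snps)],
    )
    truth = GroundTruth(snp_clusters=dict(zip(genotypes, labels.tolist())))
    return matrix, truth


# ---------------------------------------------------------------------------
# Fixtures and file output


def load_fixtures() -> dict:
    """Packaged in-study tables and the Cot design constants."""
    return {
        "probe_counts": fixtures.load_probe_counts(),
        "flowering_genes": fixtures.load_flowering_genes(),
        "dems_table": fixtures.load_dems_table(),
        "cot_constants": fixtures.cot_constants(),
        "mito_genome_bp": fixtures.MITO_GENOME_BP,
    }


def write_fasta(sequence: str, path, name: str = "MITO") -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write the annotation table as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, row in enumerate(annotation.itertuples(index=False)):
            fh.write(
                f"{row.Chromosome}\tboltchip\t{row.Feature}\t{row.Start + 1}\t{row.End}"
                f"\t.\t+\t.\tID={row.Feature}_{k:04d}\n"
            )


def write_phenotypes(phenotypes: list[BoltingPhenotype], path) -> None:
    frames = []
    for p in phenotypes:
        obs = p.observations.copy()
        obs.insert(0, "genotype_id", p.genotype_id)
        frames.append(obs)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
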