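"""Cot-filtration design math and tiling microarray probe design.

Two concerns live here. First, the reassociation-kinetics arithmetic used to
plan a Cot filtration: the single-copy Cot1/2 of a genome is estimated from
the E. coli standard by scaling its Cot1/2 with the genome-size ratio, and
~80% of the single-copy component is expected to reassociate within the two
Cot decades around that estimate. Second, the probe-design engine that places
60-mer oligonucleotide probes on source sequences, either one(-or-two) probes
per transcript for the expression array or dense class-specific tilings for
the methylation array.

Coordinates are 0-based, half-open ``[start, start + 60)`` (BED convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

PROBE_LENGTH = 60

DesignClass = Literal[
    "public_est", "mito_genome", "cot_contig", "candidate_gene", "marker", "control"
]

#: Start-to-start tiling spacing (bp) per design class on the methylation array.
METHYLATION_SPACING: dict[str, int] = {
    "public_est": 100,
    "mito_genome": 100,
    "cot_contig": 50,
    "marker": 50,
    "candidate_gene": 30,
}

KNOWN_CLASSES = frozenset(
    {"public_est", "mito_genome", "cot_contig", "candidate_gene", "marker", "control"}
)


class DesignError(ValueError):
    """Invalid design parameter or configuration."""


@dataclass(frozen=True)
class CotParameters:
    """Inputs of the single-copy Cot1/2 estimate.

    cot_half_coli : E. coli Cot1/2, M s.
    genome_coli   : E. coli genome size, bp.
    genome_org    : 1C DNA content of the organism of interest, bp.
    """

    cot_half_coli: float
    genome_coli: float
    genome_org: float

    def __post_init__(self) -> None:
        for name in ("cot_half_coli", "genome_coli", "genome_org"):
            if not getattr(self, name) > 0:
                raise DesignError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CotEstimate:
    """Single-copy Cot1/2 estimate with its two-decade reassociation window."""

    y: float
    window_low: float
    window_high: float

    @property
    def y_2sf(self) -> float:
        """The estimate rounded to two significant figures, as conventionally reported."""
        return round_sig(self.y, 2)


@dataclass(frozen=True)
class ProbeRecord:
    """A 60-mer probe placed on a source sequence."""

    probe_id: str
    source_id: str
    start: int
    length: int = PROBE_LENGTH
    design_class: str = "public_est"
    channel_role: str = "methylation"

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class SourceRecord:
    """A design input sequence with its class label.

    ``sequence`` may be None when only the length is known (tiling does not
    need base content); ``ambiguous`` requests a second discriminating probe
    on the expression design.
    """

    source_id: str
    length: int
    design_class: str
    sequence: str | None = None
    ambiguous: bool = False


@dataclass
class DesignTable:
    """An ordered probe collection with its per-class spacing and control block."""

    probes: list[ProbeRecord]
    spacing_by_class: dict[str, int] = field(default_factory=dict)
    control_block: dict[str, int] = field(default_factory=dict)
    mode: str = "methylation"

    def __len__(self) -> int:
        return len(self.probes)

    def to_frame(self, sources: dict[str, SourceRecord] | None = None) -> pd.DataFrame:
        rows = []
        for p in self.probes:
            seq = ""
            if sources is not None and p.source_id in sources:
                s = sources[p.source_id].sequence
                if s is not None:
                    seq = s[p.start : p.end]
            rows.append(
                {
                    "probe_id": p.probe_id,
                    "source_id": p.source_id,
                    "start": p.start,
                    "end": p.end,
                    "design_class": p.design_class,
                    "sequence": seq,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["probe_id", "source_id", "start", "end", "design_class", "sequence"],
        )


def round_sig(x: float, digits: int = 2) -> float:
    """Round ``x`` to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def estimate_single_copy_cot_half(params: CotParameters) -> CotEstimate:
    """Estimate the single-copy Cot1/2 of a genome from the E. coli standard.

    The estimate scales the E. coli Cot1/2 by the genome-size ratio::

        y = cot_half_coli * genome_org / genome_coli

    and the two-decade window (0.1*y, 10*y) brackets the Cot range over which
    ~80% of the single-copy component reassociates.
    """
    y = params.cot_half_coli * params.genome_org / params.genome_coli
    low, high = cot_decade_window(y)
    return CotEstimate(y=y, window_low=low, window_high=high)


def cot_decade_window(y: float) -> tuple[float, float]:
    """Two-decade reassociation window (0.1*y, 10*y) around a Cot1/2 value."""
    if not y > 0:
        raise DesignError("y must be strictly positive")
    return 0.1 * y, 10.0 * y


def tile_sequence(
    source_id: str,
    source_length: int,
    spacing: int,
    probe_len: int = PROBE_LENGTH,
    design_class: str = "public_est",
    channel_role: str = "methylation",
) -> list[ProbeRecord]:
    """Place probes at 0, spacing, 2*spacing, ... keeping only fully contained ones.

    Returns ``floor((L - probe_len)/spacing) + 1`` probes for ``L >= probe_len``;
    a too-short source yields an empty list with a warning rather than an error,
    so bulk designs skip fragments gracefully.
    """
    if spacing < 1:
        raise DesignError("spacing must be >= 1 bp")
    if source_length < probe_len:
        warnings.warn(
            f"source {source_id!r} shorter than probe length "
            f"({source_length} < {probe_len} bp): no probes designed",
            stacklevel=2,
        )
        return []
    n = (source_length - probe_len) // spacing + 1
    pad = len(str(max(n - 1, 1) * spacing))
    return [
        ProbeRecord(
            probe_id=f"{source_id}:{i * spacing:0{pad}d}",
            source_id=source_id,
            start=i * spacing,
            length=probe_len,
            design_class=design_class,
            channel_role=channel_role,
        )
        for i in range(n)
    ]


def _expression_probes(source: SourceRecord) -> list[ProbeRecord]:
    """One probe per transcript at the 5' end; a second, maximally displaced
    probe when the source is flagged as ambiguous with respect to similar
    transcripts."""
    if source.length < PROBE_LENGTH:
        warnings.warn(
            f"source {source.source_id!r} shorter than probe length: skipped",
            stacklevel=3,
        )
        return []
    probes = [
        ProbeRecord(
            probe_id=f"{source.source_id}:p1",
            source_id=source.source_id,
            start=0,
            design_class=source.design_class,
            channel_role="expression",
        )
    ]
    last_start = source.length - PROBE_LENGTH
    if source.ambiguous and last_start > 0:
        probes.append(
            ProbeRecord(
                probe_id=f"{source.source_id}:p2",
                source_id=source.source_id,
                start=last_start,
                design_class=source.design_class,
                channel_role="expression",
            )
        )
    return probes


def build_design(
    sources: Iterable[SourceRecord],
    mode: Literal["expression", "methylation"],
    spacing_overrides: dict[str, int] | None = None,
) -> DesignTable:
    """Build a deterministic design table for one array platform.

    Expression mode places one probe per source (two for ambiguity-flagged
    sources); methylation mode tiles each source at its class spacing
    (public EST / mitochondrial genome 100 bp, Cot contigs and markers 50 bp,
    candidate genes 30 bp, overridable). Probes are ordered by source_id then
    start, so identical inputs give byte-identical tables.
    """
    if mode not in ("expression", "methylation"):
        raise DesignError(f"unknown design mode {mode!r}")
    spacing = dict(METHYLATION_SPACING)
    if spacing_overrides:
        spacing.update(spacing_overrides)

    probes: list[ProbeRecord] = []
    for source in sorted(sources, key=lambda s: s.source_id):
        if source.design_class not in KNOWN_CLASSES:
            raise DesignError(
                f"unknown design_class {source.design_class!r} for source "
                f"{source.source_id!r}"
            )
        if mode == "expression":
            probes.extend(_expression_probes(source))
        else:
            probes.extend(
                tile_sequence(
                    source.source_id,
                    source.length,
                    spacing[source.design_class],
                    design_class=source.design_class,
                    channel_role="methylation",
                )
            )
    seen: set[str] = set()
    for p in probes:
        if p.probe_id in seen:
            raise DesignError(f"duplicate probe_id {p.probe_id!r}")
        seen.add(p.probe_id)
    return DesignTable(probes=probes, spacing_by_class=spacing, mode=mode)


def add_reproducibility_controls(
    design: DesignTable, n_control: int = 50, n_replicates: int = 10
) -> DesignTable:
    """Append the replicated reproducibility-control block.

    The platform carries ``n_control`` distinct control probes, each spotted
    ``n_replicates`` times; the originals are untouched and the multiplicity is
    recorded in ``control_block``.
    """
    if n_control < 1 or n_replicates < 1:
        raise DesignError("n_control and n_replicates must be >= 1")
    if not design.probes:
        raise DesignError("cannot add controls to an empty design")
    controls = [
        ProbeRecord(
            probe_id=f"CTRL{c:03d}:rep{r:02d}",
            source_id=f"CTRL{c:03d}",
            start=0,
            design_class="control",
            channel_role=design.mode,
        )
        for c in range(1, n_control + 1)
        for r in range(1, n_replicates + 1)
    ]
    block = {f"CTRL{c:03d}": n_replicates for c in range(1, n_control + 1)}
    return DesignTable(
        probes=design.probes + controls,
        spacing_by_class=dict(design.spacing_by_class),
        control_block={**design.control_block, **block},
        mode=design.mode,
    )


# ---------------------------------------------------------------------------
# I/O


def read_sources(
    fasta_path: str | Path, class_map_path: str | Path
) -> list[SourceRecord]:
    """Load design sources from a FASTA file and a TSV class map.

    The class map has columns source_id, design_class and optionally
    ambiguity_flag (0/1).
    """
    cmap = pd.read_csv(class_map_path, sep="\t", dtype={"source_id": str})
    if "ambiguity_flag" not in cmap.columns:
        cmap["ambiguity_flag"] = 0
    classes = cmap.set_index("source_id")
    sources = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in classes.index:
            raise DesignError(f"source {rec.id!r} missing from class map")
        row = classes.loc[rec.id]
        sources.append(
            SourceRecord(
                source_id=rec.id,
                length=len(rec.seq),
                design_class=str(row["design_class"]),
                sequence=str(rec.seq),
                ambiguous=bool(int(row["ambiguity_flag"])),
            )
        )
    return sources


def write_design(
    design: DesignTable,
    tsv_path: str | Path,
    bed_path: str | Path | None = None,
    sources: Sequence[SourceRecord] | None = None,
) -> None:
    """Write a design table as TSV and optionally BED6 probe intervals."""
    source_map = {s.source_id: s for s in sources} if sources else None
    frame = design.to_frame(source_map)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": frame["source_id"],
                "start": frame["start"],
                "end": frame["end"],
                "name": frame["probe_id"],
                "score": 0,
                "strand": "+",
            }
        )
        bed.to_csv(bed_path, sep="\t", index=False, header=False)
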