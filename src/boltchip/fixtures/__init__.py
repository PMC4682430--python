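"""Packaged in-study reference tables and constants.

The study's published summary tables are shipped as plain TSV files so that
desk-scale analyses can be checked against the printed accounting without any
network access:

* probe-count accounting per design/filtration step (both array platforms),
* flowering-pathway candidate genes with group-mean normalized methylation and
  expression levels,
* the 14 jointly differentially methylated and expressed sequences (DEMSs)
  with their group-mean normalized values.

Physical constants for the reassociation-kinetics design math and the
mitochondrial genome length used for tiling are exposed as module constants.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: E. coli genome size in bp, the kinetic standard of the Cot design math.
ECOLI_GENOME_BP = 4.639e6
#: E. coli Cot1/2 in M s.
ECOLI_COT_HALF = 4.545455
#: Sugar beet 1C DNA content in bp.
SUGAR_BEET_1C_BP = 1.223e9
#: Sugar beet mitochondrial genome length in bp (GenBank BA000009).
MITO_GENOME_BP = 368_799


def _read(name: str) -> pd.DataFrame:
    with resources.files("boltchip.fixtures").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_probe_counts() -> pd.DataFrame:
    """Probe accounting per platform and sequence origin.

    Columns: platform, origin, submitted_label, submitted, designed, filtered,
    called. ``origin == "total"`` rows carry the per-platform totals.
    """
    return _read("table1_probe_counts.tsv")


def load_flowering_genes() -> pd.DataFrame:
    """Flowering-pathway candidate genes with group-mean normalized values.

    One row per probe group; methylation/expression columns are NaN where the
    corresponding probes were eliminated by filtration.
    """
    return _read("table2_flowering_genes.tsv")


def load_dems_table() -> pd.DataFrame:
    """The 14 DEMS accessions with group-mean methylation/expression values."""
    return _read("table3_dems.tsv")


def filtration_percentages() -> dict[str, float]:
    """Filtered/designed probe percentages per platform, one decimal.

    Computed from the packaged accounting table, not stored.
    """
    t = load_probe_counts()
    totals = t[t["origin"] == "total"].set_index("platform")
    return {
        platform: round(100.0 * row["filtered"] / row["designed"], 1)
        for platform, row in totals.iterrows()
    }


def cot_constants() -> dict[str, float]:
    """Constants for the single-copy Cot1/2 estimate, keyed by field name."""
    return {
        "cot_half_coli": ECOLI_COT_HALF,
        "genome_coli": ECOLI_GENOME_BP,
        "genome_org": SUGAR_BEET_1C_BP,
    }
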