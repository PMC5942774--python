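"""Bundled worked-example data from the biomining copper-resistance study.

The TSV shipped with the package pairs genes from five copper-bioleaching
consortium strains with homologs in counterpart non-consortium strains and
carries their published per-gene CIB values, split into a copper-resistance
block and an oxidative-stress (ROS) block.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

#: genes whose coding sequences could be recovered from the 2014 COG
#: protein database when building the reference gene set, and the total
#: number of genes that database lists.
COG_GENES_RECOVERED = 1_737_559
COG_GENES_TOTAL = 1_785_722


def load_copper_ros_table() -> pd.DataFrame:
    """Load the bundled copper/ROS homolog-pair CIB table."""
    ref = importlib.resources.files("cibkit") / "data" / "copper_ros_gene_cib.tsv"
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def block_means(table: pd.DataFrame | None = None, decimals: int = 3) -> pd.DataFrame:
    """Mean CIB per block for consortium and counterpart columns.

    Returns a DataFrame indexed by block with columns
    ``mean_consortium`` and ``mean_counterpart``, rounded to ``decimals``.
    """
    if table is None:
        table = load_copper_ros_table()
    out = (
        table.groupby("block")[["cib_consortium", "cib_counterpart"]]
        .mean()
        .round(decimals)
    )
    out.columns = ["mean_consortium", "mean_counterpart"]
    return out


def percent_recovered(n_recovered: int = COG_GENES_RECOVERED,
                      n_total: int = COG_GENES_TOTAL,
                      decimals: int = 1) -> float:
    """Percentage of genes recovered, rounded to ``decimals`` places."""
    if n_total <= 0 or n_recovered < 0 or n_recovered > n_total:
        raise ValueError("need 0 <= n_recovered <= n_total, n_total > 0")
    return round(100.0 * n_recovered / n_total, decimals)
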