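"""Packaged reference tables from the sorghum lobed-leaf mapping study.

Two small tables travel with the package: the 22 candidate genomic
intervals called by the ED scan of the sorghum lobed-leaf F2 experiment
(with their per-interval gene and transcript counts), and the observed F2
phenotype segregation counts.  They drive the worked examples and the
summary cross-checks.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .ed_scan import CandidateRegion

__all__ = [
    "load_candidate_region_table",
    "candidate_regions_from_table",
    "load_segregation_counts",
]

_DATA = files("edmap") / "data"


def load_candidate_region_table() -> pd.DataFrame:
    """The published candidate-interval table (coordinates in Mb)."""
    with (_DATA / "candidate_regions_sorghum.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def candidate_regions_from_table(table: pd.DataFrame | None = None) -> list[CandidateRegion]:
    """Convert the Mb-coordinate table into :class:`CandidateRegion` records.

    Positions are converted to 1-based bp (rounded from the printed Mb
    values); gene and transcript counts ride along for summarization.
    ``n_above``/``n_total``/``peak_ed`` are not published per interval and
    are recorded as zero.
    """
    table = table if table is not None else load_candidate_region_table()
    regions = []
    for row in table.itertuples(index=False):
        regions.append(
            CandidateRegion(
                chrom=row.chrom,
                start_bp=round(row.start_mb * 1e6),
                end_bp=round(row.end_mb * 1e6),
                n_above=0,
                n_total=0,
                peak_ed=0.0,
                n_genes=int(row.n_genes),
                n_transcripts=int(row.n_transcripts),
            )
        )
    return regions


def load_segregation_counts() -> tuple[int, int]:
    """Observed F2 phenotype counts as ``(n_wild_type, n_mutant)``."""
    with (_DATA / "segregation_counts_sorghum.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t").set_index("phenotype")["count"]
    return int(table["wild_type"]), int(table["mutant"])
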