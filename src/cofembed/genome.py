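"""Genomic annotation of genes and peaks.

Coordinates are 0-based half-open throughout. The transcription start site
(TSS) of a gene is the body start on the plus strand and the last base of the
body on the minus strand; "upstream" is strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
PEAK_COLUMNS = ["peak_id", "chrom", "start", "end"]


@dataclass
class GenomicAnnotation:
    """Gene bodies (with strand/TSS) and peak intervals.

    Parameters
    ----------
    genes
        DataFrame with columns ``gene_id, chrom, start, end, strand``.
    peaks
        DataFrame with columns ``peak_id, chrom, start, end``.
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame

    def __post_init__(self):
        self.genes = self.genes.reset_index(drop=True).copy()
        self.peaks = self.peaks.reset_index(drop=True).copy()
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise ValueError(f"genes missing column {col!r}")
        for col in PEAK_COLUMNS:
            if col not in self.peaks.columns:
                raise ValueError(f"peaks missing column {col!r}")
        for df, what in ((self.genes, "gene"), (self.peaks, "peak")):
            bad = df.index[df["start"] >= df["end"]]
            if len(bad):
                row = df.loc[bad[0]]
                raise ValueError(
                    f"{what} {row.iloc[0]!r}: start {row['start']} >= end {row['end']}"
                )
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        if self.peaks["peak_id"].duplicated().any():
            raise ValueError("duplicate peak ids in annotation")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        self.genes["tss"] = np.where(
            self.genes["strand"] == "+", self.genes["start"], self.genes["end"] - 1
        )

    def gene_body_lengths(self) -> pd.Series:
        return (self.genes["end"] - self.genes["start"]).rename("body_length")

    def peak_midpoints(self) -> pd.Series:
        return ((self.peaks["start"] + self.peaks["end"]) // 2).rename("midpoint")
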