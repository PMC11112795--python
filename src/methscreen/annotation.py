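"""Gene annotation container and promoter geometry.

Genomic intervals are 0-based half-open in memory and on disk (BED
convention); the transcription start site (TSS) is stored as a 1-based
position, matching the cytosine-table coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]

#: promoter window around the TSS: (upstream, downstream) in bp, strand-aware
DEFAULT_PROMOTER_WINDOW = (2000, 500)


@dataclass
class GeneSet:
    """A set of gene records with unique ids, sorted by coordinate."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=GENE_COLUMNS)
        if len(df):
            if df["gene_id"].duplicated().any():
                dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
                raise ParameterError(f"duplicate gene_id {dup!r}")
            if (df["start"] >= df["end"]).any():
                raise ParameterError("gene start must be < end")
            if not df["strand"].isin(["+", "-"]).all():
                raise ParameterError("strand must be '+' or '-'")
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
                drop=True
            )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def promoter_intervals(
        self, window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW
    ) -> pd.DataFrame:
        """0-based half-open promoter interval per gene, strand-aware.

        For a plus-strand gene the window spans ``upstream`` bp before the
        TSS through ``downstream`` bp after it; minus-strand mirrored.
        """
        up, down = window
        df = self.records
        out = df[["gene_id", "chrom", "strand"]].copy()
        plus = df["strand"] == "+"
        # 1-based [tss-up, tss+down] -> 0-based [tss-up-1, tss+down)
        out["start"] = (df["tss"] - up - 1).where(plus, df["tss"] - down - 1)
        out["end"] = (df["tss"] + down).where(plus, df["tss"] + up)
        out["start"] = out["start"].clip(lower=0)
        return out


def write_genes_bed(genes: GeneSet, path) -> None:
    """BED6-style TSV: chrom, start, end, gene_id, tss, strand."""
    df = genes.records
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["gene_id"],
            "score": df["tss"],
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> GeneSet:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if bed.empty:
        return GeneSet()
    return GeneSet(
        pd.DataFrame(
            {
                "gene_id": bed["name"],
                "chrom": bed["chrom"],
                "strand": bed["strand"],
                "start": bed["start"].astype(int),
                "end": bed["end"].astype(int),
                "tss": bed["score"].astype(int),
            }
        )
    )
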