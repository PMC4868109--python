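"""Sparse per-chromosome contact matrices at a fixed bin resolution.

Filtered PETs are aggregated into 2-D genomic windows: upper-triangular
bin pairs (bin_i <= bin_j) on each chromosome.  Bin k covers the
half-open interval [k*r, (k+1)*r).  The two standard resolutions are
5 kb and 25 kb; any positive resolution is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import ChromSizes, PETSet

TRIPLET_COLUMNS = ["chrom", "bin_i", "bin_j", "count"]


def pos_to_bin(pos: int | np.ndarray, resolution_bp: int):
    """floor(pos / resolution); bin intervals are half-open."""
    return np.floor_divide(pos, resolution_bp)


@dataclass(frozen=True)
class BinGrid:
    """Binning scheme: a resolution over a chromosome-sizes table."""

    resolution_bp: int
    sizes: ChromSizes

    def __post_init__(self):
        if self.resolution_bp <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution_bp}")

    def n_bins(self, chrom: str) -> int:
        return ceil(self.sizes[chrom] / self.resolution_bp)

    def bin_table(self) -> pd.DataFrame:
        """BED-style bin table (chrom, start, end) over all chromosomes."""
        rows = []
        r = self.resolution_bp
        for chrom, length in self.sizes.sizes.items():
            for k in range(self.n_bins(chrom)):
                rows.append((chrom, k * r, min((k + 1) * r, length)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class ContactMatrix:
    """Sparse intra-chromosomal contact counts per upper-triangular bin pair.

    ``df`` has columns chrom, bin_i, bin_j, count with bin_i <= bin_j and
    count > 0; the sum of counts equals the number of PETs binned.
    """

    grid: BinGrid
    df: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.df["count"].sum())

    def n_windows(self) -> int:
        return len(self.df)

    def keys(self) -> np.ndarray:
        """Encoded int64 key per bin pair, unique across chromosomes."""
        return _encode_keys(self.df, self.grid)

    def to_triplet_tsv(self, path: str | Path, header: bool = True) -> None:
        self.df.to_csv(path, sep="\t", header=header, index=False)


def _encode_keys(df: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    order = grid.sizes.order_index()
    max_bins = max(grid.n_bins(c) for c in grid.sizes.names)
    c = df["chrom"].map(order).to_numpy(dtype=np.int64)
    i = df["bin_i"].to_numpy(dtype=np.int64)
    j = df["bin_j"].to_numpy(dtype=np.int64)
    return (c * max_bins + i) * max_bins + j


def bin_pets(pets: PETSet, grid: BinGrid) -> ContactMatrix:
    """Count filtered PETs per 2-D bin pair.

    Each PET increments exactly one (bin_i, bin_j) pair with
    bin_i <= bin_j (guaranteed by canonical anchor order).  Input must be
    intra-chromosomal only; an inter-chromosomal record is a contract
    violation.
    """
    if not pets.is_intra.all():
        raise ContractError("bin_pets received inter-chromosomal records; filter first")
    df = pets.df
    if len(df) == 0:
        empty = pd.DataFrame({c: [] for c in TRIPLET_COLUMNS})
        return ContactMatrix(grid=grid, df=empty.astype({"bin_i": np.int64, "bin_j": np.int64, "count": np.int64}))
    r = grid.resolution_bp
    binned = pd.DataFrame(
        {
            "chrom": df["chrom1"].to_numpy(),
            "bin_i": pos_to_bin(df["pos1"].to_numpy(), r),
            "bin_j": pos_to_bin(df["pos2"].to_numpy(), r),
        }
    )
    counts = (
        binned.groupby(["chrom", "bin_i", "bin_j"], sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["count"] = counts["count"].astype(np.int64)
    return ContactMatrix(grid=grid, df=counts)


def read_triplet_tsv(path: str | Path, grid: BinGrid) -> ContactMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df[TRIPLET_COLUMNS].astype({"bin_i": np.int64, "bin_j": np.int64, "count": np.int64})
    return ContactMatrix(grid=grid, df=df)
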