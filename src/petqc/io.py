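"""Reading, canonicalizing, deduplicating and filtering paired-end tags.

A PET (paired-end tag) is one proximity-ligation product observed as a
mapped read pair: two genomic anchors, each with a strand.  All quality
assessment downstream operates on the *filtered* PET population: unique
intra-chromosomal PETs whose anchors are separated by more than a span
threshold (default 10 kb), which removes the short-range diagonal signal
that would otherwise dominate the statistics.

Coordinates are stored 0-based (BEDPE convention); the 4DN ``.pairs``
format is 1-based and converted on read/write.  Records are canonicalized
so that ``(chrom1, pos1) <= (chrom2, pos2)`` in chromosome-file order,
strands travelling with their anchors.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

PET_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name -> length (bp) mapping.

    The file order defines the canonical chromosome order used when
    orienting PET anchors, so results are stable across naming schemes
    (chr1/chr2/... vs 1/2/... vs scaffold names).
    """

    sizes: Mapping[str, int]

    def __post_init__(self):
        sizes = dict(self.sizes)
        if len(sizes) == 0:
            raise FormatError("chromosome sizes mapping is empty")
        for name, length in sizes.items():
            if int(length) <= 0:
                raise FormatError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "sizes", sizes)

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        """Read a UCSC-style two-column chrom.sizes file."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise FormatError(f"{path}, line {ln}: expected 'name length'")
                try:
                    sizes[fields[0]] = int(fields[1])
                except ValueError as exc:
                    raise FormatError(f"{path}, line {ln}: bad length {fields[1]!r}") from exc
        return cls(sizes)

    @property
    def names(self) -> list[str]:
        return list(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def order_index(self) -> dict[str, int]:
        """Chromosome name -> rank in file order."""
        return {name: i for i, name in enumerate(self.sizes)}


@dataclass
class PETSet:
    """A collection of canonicalized paired-end tags.

    Backed by a DataFrame with columns chrom1, pos1, strand1, chrom2,
    pos2, strand2 (positions 0-based).  ``n_skipped`` counts input
    records dropped because their chromosome was absent from ``sizes``.
    """

    df: pd.DataFrame
    sizes: ChromSizes
    label: str = ""
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PETSet):
            return NotImplemented
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        return a.equals(b)

    @property
    def is_intra(self) -> np.ndarray:
        return (self.df["chrom1"] == self.df["chrom2"]).to_numpy()

    @property
    def spans(self) -> np.ndarray:
        """pos2 - pos1; meaningful for intra-chromosomal records only."""
        return (self.df["pos2"] - self.df["pos1"]).to_numpy()

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        sizes: ChromSizes,
        label: str = "",
        n_skipped: int = 0,
        canonicalize: bool = True,
    ) -> "PETSet":
        df = df[PET_COLUMNS].reset_index(drop=True)
        df = df.astype({"pos1": np.int64, "pos2": np.int64})
        if canonicalize:
            df = _canonicalize(df, sizes)
        return cls(df=df, sizes=sizes, label=label, n_skipped=n_skipped)

    def take(self, indices: np.ndarray) -> "PETSet":
        """Row subset by positional indices (already-canonical records)."""
        return replace(self, df=self.df.iloc[indices].reset_index(drop=True))


def _canonicalize(df: pd.DataFrame, sizes: ChromSizes) -> pd.DataFrame:
    """Orient each record so (chrom1, pos1) <= (chrom2, pos2).

    Chromosome order is the ChromSizes file order; strands travel with
    their anchors.  Ties in (chrom, pos) are broken on strand ("+"
    before "-") so the normal form is unique even for coordinate-
    identical anchors.  Idempotent.
    """
    if len(df) == 0:
        return df.reset_index(drop=True)
    order = sizes.order_index()
    o1 = df["chrom1"].map(order).to_numpy()
    o2 = df["chrom2"].map(order).to_numpy()
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    tied = (o1 == o2) & (p1 == p2)
    swap = (o1 > o2) | ((o1 == o2) & (p1 > p2)) | (tied & (s1 > s2))
    if not swap.any():
        return df.reset_index(drop=True)
    out = df.copy().reset_index(drop=True)
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
        out.loc[swap, a] = vb[swap]
        out.loc[swap, b] = va[swap]
    return out


def _finalize(
    raw: pd.DataFrame, sizes: ChromSizes, label: str
) -> PETSet:
    """Drop records on unknown chromosomes (tallied), canonicalize."""
    known = raw["chrom1"].isin(sizes.sizes) & raw["chrom2"].isin(sizes.sizes)
    n_skipped = int((~known).sum())
    kept = raw.loc[known]
    return PETSet.from_frame(kept, sizes, label=label, n_skipped=n_skipped)


def read_bedpe(path: str | Path, sizes: ChromSizes, label: str | None = None) -> PETSet:
    """Read a BEDPE file (>=6 tab-separated columns, 0-based half-open).

    Anchor position is the start coordinate of each mate's interval.
    Strand columns 9-10 are optional and default to "+"/"+".  Records on
    chromosomes absent from ``sizes`` are skipped and tallied in
    ``PETSet.n_skipped``; a malformed line raises :class:`FormatError`
    naming the line number.
    """
    rows: list[tuple] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}, line {ln}: expected >=6 tab-separated fields, got {len(f)}")
            try:
                pos1, pos2 = int(f[1]), int(f[4])
            except ValueError as exc:
                raise FormatError(f"{path}, line {ln}: non-integer coordinate") from exc
            s1 = f[8] if len(f) > 9 else "+"
            s2 = f[9] if len(f) > 9 else "+"
            rows.append((f[0], pos1, s1, f[3], pos2, s2))
    raw = pd.DataFrame(rows, columns=PET_COLUMNS)
    return _finalize(raw, sizes, label or str(path))


def read_pairs(path: str | Path, sizes: ChromSizes, label: str | None = None) -> PETSet:
    """Read a 4DN ``.pairs`` text file.

    Header lines start with ``#``; body columns are
    readID chrom1 pos1 chrom2 pos2 strand1 strand2 with 1-based
    positions, converted here to the internal 0-based convention.
    """
    rows: list[tuple] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise FormatError(
                    f"{path}, line {ln}: expected 7 columns "
                    "(readID chrom1 pos1 chrom2 pos2 strand1 strand2)"
                )
            try:
                pos1, pos2 = int(f[2]) - 1, int(f[4]) - 1
            except ValueError as exc:
                raise FormatError(f"{path}, line {ln}: non-integer position") from exc
            rows.append((f[1], pos1, f[5], f[3], pos2, f[6]))
    raw = pd.DataFrame(rows, columns=PET_COLUMNS)
    return _finalize(raw, sizes, label or str(path))


def write_bedpe(pets: PETSet, path: str | Path) -> None:
    """Write as 10-column BEDPE; anchors become 1 bp intervals."""
    df = pets.df
    out = pd.DataFrame(
        {
            "chrom1": df["chrom1"],
            "start1": df["pos1"],
            "end1": df["pos1"] + 1,
            "chrom2": df["chrom2"],
            "start2": df["pos2"],
            "end2": df["pos2"] + 1,
            "name": ".",
            "score": ".",
            "strand1": df["strand1"],
            "strand2": df["strand2"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_pairs(pets: PETSet, path: str | Path) -> None:
    """Write as 4DN ``.pairs`` text (1-based positions)."""
    buf = _io.StringIO()
    buf.write("## pairs format v1.0\n")
    buf.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
    for name, length in pets.sizes.sizes.items():
        buf.write(f"#chromsize: {name} {length}\n")
    df = pets.df
    out = pd.DataFrame(
        {
            "readID": [f"pet{i}" for i in range(len(df))],
            "chrom1": df["chrom1"],
            "pos1": df["pos1"] + 1,
            "chrom2": df["chrom2"],
            "pos2": df["pos2"] + 1,
            "strand1": df["strand1"],
            "strand2": df["strand2"],
        }
    )
    out.to_csv(buf, sep="\t", header=False, index=False)
    Path(path).write_text(buf.getvalue())


def deduplicate(pets: PETSet, use_strands: bool = True) -> PETSet:
    """Collapse clonal (PCR-duplicate) PETs to one record each.

    The default key is the full (chrom1,pos1,strand1,chrom2,pos2,strand2)
    tuple: identical coordinates with a different strand configuration
    are distinct ligation products.  ``use_strands=False`` relaxes the
    key to coordinates only.  First occurrence wins; order is preserved.
    """
    key = PET_COLUMNS if use_strands else ["chrom1", "pos1", "chrom2", "pos2"]
    df = pets.df.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    return replace(pets, df=df)


def filter_long_range(pets: PETSet, span_threshold_bp: int = 10_000) -> PETSet:
    """Keep intra-chromosomal PETs with span strictly > threshold.

    The result is the "filtered PETs" population on which all QC
    indicators are computed.  Idempotent.
    """
    if span_threshold_bp < 0:
        raise ValueError(f"span threshold must be >= 0, got {span_threshold_bp}")
    keep = pets.is_intra & (pets.spans > span_threshold_bp)
    df = pets.df.loc[keep].reset_index(drop=True)
    return replace(pets, df=df)


@dataclass(frozen=True)
class LibraryStats:
    """Summary counts for one PET library.

    filtered_pets counts unique intra-chromosomal PETs with anchor span
    strictly greater than ``span_threshold_bp``.
    """

    total_pets: int
    unique_pets: int
    intra_pets: int
    inter_pets: int
    filtered_pets: int
    span_threshold_bp: int = 10_000

    def __post_init__(self):
        if self.unique_pets > self.total_pets:
            raise ValueError("unique_pets > total_pets")
        if self.intra_pets + self.inter_pets != self.unique_pets:
            raise ValueError("intra + inter != unique")
        if self.filtered_pets > self.intra_pets:
            raise ValueError("filtered_pets > intra_pets")

    def to_dict(self) -> dict:
        return {
            "total_pets": self.total_pets,
            "unique_pets": self.unique_pets,
            "intra_pets": self.intra_pets,
            "inter_pets": self.inter_pets,
            "filtered_pets": self.filtered_pets,
            "span_threshold_bp": self.span_threshold_bp,
        }


def library_stats(pets_raw: PETSet, span_threshold_bp: int = 10_000) -> LibraryStats:
    """Compute the library summary from an as-read (pre-dedup) PETSet."""
    unique = deduplicate(pets_raw)
    intra = int(unique.is_intra.sum())
    filtered = filter_long_range(unique, span_threshold_bp)
    return LibraryStats(
        total_pets=len(pets_raw),
        unique_pets=len(unique),
        intra_pets=intra,
        inter_pets=len(unique) - intra,
        filtered_pets=len(filtered),
        span_threshold_bp=span_threshold_bp,
    )
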