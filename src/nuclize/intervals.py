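"""Genomic interval primitives and the nucleosome coordinate system.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention);
1-based dialects (DANPOS tables) are converted on read.  The central object
is :class:`NucleosomeMap` — a per-chromosome sorted, non-overlapping set of
nucleosome intervals with stable integer ids.  The map is the fixed
coordinate system onto which every ChIP/input fragment is projected: a
fragment belongs to the nucleosome whose interval contains its midpoint
(at most one, because the map partitions the bases it covers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

#: Conventional ordering of the five marks handled by default; also the
#: sort order used when rendering multivalent category labels.
DEFAULT_MARKS = ("H3K4me3", "H3K9ac", "H3K9me3", "H3K27ac", "H3K27me3")


@dataclass(frozen=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Fragment:
    """One sequenced DNA fragment (a paired-end-derived interval)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment [{self.start}, {self.end}) is empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class NucleosomePosition:
    """One called nucleosome: interval plus dyad (point location)."""

    id: int
    chrom: str
    start: int
    end: int
    dyad: int
    occupancy: float = float("nan")


def fragment_table(chroms, starts, ends) -> pd.DataFrame:
    """Build the canonical fragment DataFrame (chrom, start, end, midpoint)."""
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
        }
    )
    if len(df) and (df["end"] <= df["start"]).any():
        bad = int((df["end"] <= df["start"]).idxmax())
        raise ValueError(f"empty fragment interval at row {bad}")
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df


class NucleosomeMap:
    """Sorted, non-overlapping nucleosome intervals with stable ids.

    Ids are assigned 0..n-1 in (chrom, start) order at construction and act
    as row indices into :attr:`table`.  Use :meth:`from_intervals` for raw
    (possibly unsorted / overlapping) calls; the plain constructor validates
    and rejects unsorted or overlapping input.
    """

    REQUIRED = ("chrom", "start", "end", "dyad")

    def __init__(self, table: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"nucleosome table missing column {col!r}")
        if len(table) == 0:
            raise ValueError("nucleosome map is empty")
        table = table.reset_index(drop=True)
        for chrom, sub in table.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(np.diff(starts) < 0):
                raise ValueError(f"map not sorted by start on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping nucleosomes on {chrom}")
            if np.any((sub["dyad"] < starts) | (sub["dyad"] >= ends)):
                raise ValueError(f"dyad outside its interval on {chrom}")
        if "occupancy" not in table.columns:
            table["occupancy"] = np.nan
        table["nucleosome_id"] = np.arange(len(table), dtype=np.int64)
        self.table = table
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in table.groupby("chrom", sort=False):
            self._by_chrom[chrom] = (
                sub["nucleosome_id"].to_numpy(),
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
            )

    # -- construction -------------------------------------------------

    @classmethod
    def from_intervals(cls, table: pd.DataFrame) -> "NucleosomeMap":
        """Sort, overlap-trim and id-assign raw nucleosome calls.

        Overlapping neighbours are trimmed at the midpoint of their overlap
        so the map partitions covered bases; an interval fully contained in
        its predecessor is dropped.  Dyads are clamped into the trimmed
        interval; a missing/NaN dyad becomes the interval midpoint.
        """
        df = table.copy().reset_index(drop=True)
        if "dyad" not in df.columns:
            df["dyad"] = np.nan
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )
        keep = np.ones(len(df), dtype=bool)
        starts = df["start"].to_numpy().copy()
        ends = df["end"].to_numpy().copy()
        chroms = df["chrom"].to_numpy()
        prev = -1
        for i in range(len(df)):
            if prev >= 0 and chroms[i] == chroms[prev]:
                if ends[i] <= ends[prev]:  # contained duplicate call
                    keep[i] = False
                    continue
                if starts[i] < ends[prev]:
                    boundary = (starts[i] + ends[prev]) // 2
                    ends[prev] = boundary
                    starts[i] = boundary
            prev = i
        df["start"] = starts
        df["end"] = ends
        df = df[keep & (df["end"] > df["start"])].reset_index(drop=True)
        dyad = df["dyad"].to_numpy(dtype=float)
        missing = ~np.isfinite(dyad)
        dyad[missing] = ((df["start"] + df["end"]) // 2)[missing]
        df["dyad"] = np.clip(
            dyad.astype(np.int64), df["start"], df["end"] - 1
        )
        cols = ["chrom", "start", "end", "dyad"]
        if "occupancy" in df.columns:
            cols.append("occupancy")
        return cls(df[cols])

    # -- basic protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def __iter__(self) -> Iterator[NucleosomePosition]:
        for row in self.table.itertuples(index=False):
            yield NucleosomePosition(
                id=int(row.nucleosome_id),
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                dyad=int(row.dyad),
                occupancy=float(row.occupancy),
            )

    def chrom_sizes(self) -> dict[str, int]:
        """Upper coordinate bound per chromosome implied by the map."""
        return {c: int(ends[-1]) for c, (_, _, ends) in self._by_chrom.items()}

    # -- assignment ----------------------------------------------------

    def assign(self, chroms, positions) -> np.ndarray:
        """Vectorized point→nucleosome assignment (binary search).

        Returns the nucleosome id containing each position under half-open
        semantics, or -1 where no nucleosome contains it (including
        chromosomes absent from the map).
        """
        chroms = np.asarray(chroms)
        pos = np.asarray(positions, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for chrom in pd.unique(chroms):
            sel = np.flatnonzero(chroms == chrom)
            entry = self._by_chrom.get(chrom)
            if entry is None:
                continue
            ids, starts, ends = entry
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            inside = (idx >= 0) & (pos[sel] < ends[np.clip(idx, 0, None)])
            out[sel[inside]] = ids[idx[inside]]
        return out

    def assign_fragment(self, fragment: Fragment) -> int | None:
        """Assign one fragment by midpoint; None if no nucleosome contains it."""
        nid = self.assign([fragment.chrom], [fragment.midpoint])[0]
        return None if nid < 0 else int(nid)
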