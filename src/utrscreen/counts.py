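"""Tidy 8mer count tables with reads-per-million normalization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

COLUMNS = ["motif", "population", "replicate", "count"]

MILLION = 1_000_000


class EmptyLibraryError(ValueError):
    """A (population, replicate) library contains zero reads; RPM is undefined."""


@dataclass(frozen=True)
class CountTable:
    """Raw 8mer counts along (motif, population, replicate), optionally with RPM.

    The underlying frame is tidy: one row per (motif, population, replicate)
    with a non-negative integer ``count`` and, after :meth:`with_rpm`, an
    ``rpm`` column satisfying ``rpm = count * 1e6 / library_total`` so that
    RPM sums to one million within every library.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if len(self.df) and (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, int]]
    ) -> "CountTable":
        """Build from an iterable of (motif, population, replicate, count)."""
        df = pd.DataFrame(list(records), columns=COLUMNS)
        return cls(df)

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, int], Mapping[str, int]]
    ) -> "CountTable":
        """Build from ``{(population, replicate): {motif: count}}``."""
        rows = [
            (motif, pop, rep, int(c))
            for (pop, rep), per_motif in counts.items()
            for motif, c in per_motif.items()
        ]
        return cls.from_records(rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"motif": str, "population": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    # -- derived views -----------------------------------------------------

    @property
    def has_rpm(self) -> bool:
        return "rpm" in self.df.columns

    def library_sizes(self) -> pd.Series:
        """Total read count per (population, replicate) library."""
        return self.df.groupby(["population", "replicate"])["count"].sum()

    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    def motifs(self) -> list[str]:
        return sorted(self.df["motif"].unique())

    def counts_for(self, population: str, replicate: int) -> pd.Series:
        """Per-motif counts of one library, indexed by motif."""
        sub = self.df[
            (self.df["population"] == population)
            & (self.df["replicate"] == replicate)
        ]
        return sub.set_index("motif")["count"]

    def replicates(self, population: str) -> list[int]:
        sub = self.df[self.df["population"] == population]
        return sorted(sub["replicate"].unique())

    # -- transforms --------------------------------------------------------

    def with_rpm(self) -> "CountTable":
        """Return a copy with the ``rpm`` column populated per library.

        Raises
        ------
        EmptyLibraryError
            If any library present in the table has zero total reads.
        """
        sizes = self.library_sizes()
        empty = sizes[sizes == 0]
        if len(empty):
            raise EmptyLibraryError(
                f"zero-read libraries, RPM undefined: {list(empty.index)}"
            )
        df = self.df.copy()
        totals = df.set_index(["population", "replicate"]).index.map(sizes)
        df["rpm"] = df["count"].to_numpy() * (MILLION / np.asarray(totals, float))
        return CountTable(df)

    def aggregate_replicates(self, mode: str = "sum") -> "CountTable":
        """Collapse replicates within each population.

        ``mode='sum'`` adds raw counts (default; preserves count statistics at
        low depth); ``mode='mean'`` averages them, rounding to nearest integer.
        The collapsed table carries replicate id 0.
        """
        if mode not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation mode: {mode!r}")
        grouped = self.df.groupby(["motif", "population"], as_index=False)["count"]
        df = grouped.sum() if mode == "sum" else grouped.mean()
        if mode == "mean":
            df["count"] = df["count"].round().astype(int)
        df["replicate"] = 0
        return CountTable(df[COLUMNS])

    def rpm_matrix(self) -> pd.DataFrame:
        """Motif x population RPM matrix (requires RPM; replicates must be collapsed)."""
        if not self.has_rpm:
            raise ValueError("call with_rpm() first")
        if self.df.groupby(["motif", "population"]).size().max() > 1:
            raise ValueError("collapse replicates before pivoting to a matrix")
        return self.df.pivot(index="motif", columns="population", values="rpm").fillna(
            0.0
        )
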