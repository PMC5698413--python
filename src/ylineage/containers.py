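"""Core in-memory containers shared across the pipeline.

Three tabular objects circulate between modules:

``VariantMatrix``
    A samples x sites genotype table for haploid Y-chromosome SNPs, with
    per-sample read depth.  Genotypes are coded ancestral/derived/missing
    (plus a transient heterozygous code for raw diploid-coded calls that
    have not yet been cleaned).

``RegionMask``
    Sorted, non-overlapping keep-intervals on chrY in BED convention
    (0-based, half-open).  Variant positions are 1-based per VCF, and the
    conversion between the two conventions lives here and nowhere else.

``STRHaplotypeTable``
    A samples x STR-loci repeat-count table with a population label and an
    optional sampling longitude per sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# Genotype codes for VariantMatrix.genotypes
ANCESTRAL = 0
DERIVED = 1
HETEROZYGOUS = 2  # raw diploid-coded call; removed by filtering
MISSING = -1

#: chrY length in hg19/GRCh37, used when writing VCF headers.
CHRY_LENGTH_HG19 = 59_373_566


@dataclass
class VariantMatrix:
    """Haploid genotype matrix over ordered chrY sites.

    Parameters
    ----------
    positions
        1-based site positions, strictly increasing.
    samples
        Ordered sample identifiers.
    genotypes
        ``(n_samples, n_sites)`` int8 array with codes ``ANCESTRAL``,
        ``DERIVED``, ``HETEROZYGOUS`` or ``MISSING``.
    depth
        Optional ``(n_samples, n_sites)`` read-depth array.
    ids
        Optional variant names (defaults to ``chrY:<pos>``).
    """

    positions: np.ndarray
    samples: list[str]
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = list(self.samples)
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        n, m = len(self.samples), len(self.positions)
        if self.genotypes.shape != (n, m):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{n} samples x {m} sites"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != (n, m):
                raise ValueError("depth shape does not match genotypes")
        if self.ids is None:
            self.ids = [f"chrY:{p}" for p in self.positions]
        else:
            self.ids = list(self.ids)
            if len(self.ids) != m:
                raise ValueError("ids length does not match number of sites")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def take_sites(self, index: np.ndarray) -> "VariantMatrix":
        """Return a copy restricted to the given site index (order kept)."""
        index = np.asarray(index)
        return VariantMatrix(
            positions=self.positions[index],
            samples=list(self.samples),
            genotypes=self.genotypes[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            ids=[self.ids[i] for i in np.atleast_1d(index)],
        )

    def take_samples(self, index: np.ndarray) -> "VariantMatrix":
        index = np.asarray(index)
        return VariantMatrix(
            positions=self.positions.copy(),
            samples=[self.samples[i] for i in index],
            genotypes=self.genotypes[index, :],
            depth=None if self.depth is None else self.depth[index, :],
            ids=list(self.ids),
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing genotype calls."""
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return np.mean(self.genotypes == MISSING, axis=1)

    def mean_depth(self) -> np.ndarray:
        """Per-sample mean read depth over current sites."""
        if self.depth is None:
            raise ValueError("VariantMatrix has no depth information")
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return np.mean(self.depth, axis=1)

    def equals(self, other: "VariantMatrix") -> bool:
        if self.samples != other.samples or self.ids != other.ids:
            return False
        if not np.array_equal(self.positions, other.positions):
            return False
        if not np.array_equal(self.genotypes, other.genotypes):
            return False
        if (self.depth is None) != (other.depth is None):
            return False
        if self.depth is not None and not np.array_equal(
            np.asarray(self.depth, dtype=np.int64),
            np.asarray(other.depth, dtype=np.int64),
        ):
            return False
        return True


@dataclass
class RegionMask:
    """Keep-intervals on chrY, 0-based half-open as in BED."""

    intervals: np.ndarray  # shape (k, 2)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if len(iv):
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("mask intervals must satisfy start < end")
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("mask intervals overlap or are unsorted")
        self.intervals = iv

    @property
    def kept_length(self) -> int:
        """Total kept length in bp."""
        if not len(self.intervals):
            return 0
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, positions_1based: np.ndarray) -> np.ndarray:
        """Boolean membership of 1-based positions in the keep set."""
        pos0 = np.asarray(positions_1based, dtype=np.int64) - 1
        if not len(self.intervals):
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], pos0, side="right") - 1
        inside = idx >= 0
        inside[inside] &= pos0[inside] < self.intervals[idx[inside], 1]
        return inside


RESERVED_STR_COLUMNS = ("sample", "population", "longitude")


@dataclass
class STRHaplotypeTable:
    """Y-STR repeat-count panel with population labels.

    Wraps a DataFrame whose first columns are ``sample``, ``population``
    and (optionally) ``longitude``; every remaining column is an STR locus
    holding integer repeat counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("sample", "population"):
            if col not in df.columns:
                raise ValueError(f"STR table is missing required column {col!r}")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample identifier {dup!r}")
        self.data = df.reset_index(drop=True)

    @property
    def loci(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_STR_COLUMNS]

    @property
    def samples(self) -> list[str]:
        return list(self.data["sample"])

    @property
    def populations(self) -> pd.Series:
        return self.data["population"]

    @property
    def longitudes(self) -> pd.Series | None:
        if "longitude" in self.data.columns:
            return self.data["longitude"]
        return None

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def matrix(self, loci: Sequence[str] | None = None) -> np.ndarray:
        """Repeat counts as an ``(n_samples, n_loci)`` int array."""
        loci = list(loci) if loci is not None else self.loci
        sub = self.data[loci]
        if sub.isna().any().any():
            raise ValueError("STR table contains missing repeat counts")
        return sub.to_numpy(dtype=np.int64)

    def subset(self, mask: np.ndarray) -> "STRHaplotypeTable":
        return STRHaplotypeTable(self.data.loc[np.asarray(mask)].reset_index(drop=True))

    def haplotype_tuples(self, loci: Sequence[str] | None = None) -> list[tuple[int, ...]]:
        return [tuple(row) for row in self.matrix(loci)]
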