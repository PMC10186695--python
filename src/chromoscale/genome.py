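"""Binned-genome coordinate system and per-bin signal tracks.

All coordinates are 0-based, half-open (BED convention); a position ``pos``
falls in bin ``pos // bin_size``.  The last bin of a chromosome may be
partial; bins tile each chromosome exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinnedGenome", "SignalTrack", "read_chrom_sizes", "write_chrom_sizes"]


class BinnedGenome:
    """A genome partitioned into fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bp, in the desired order.
    bin_size
        Bin width in bp.
    """

    def __init__(self, chrom_sizes: dict[str, int], bin_size: int):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        for name, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.bin_size = int(bin_size)
        self.chroms: list[str] = list(chrom_sizes)
        self._n_bins = {
            c: int(math.ceil(s / bin_size)) for c, s in self.chrom_sizes.items()
        }
        offs, total = {}, 0
        for c in self.chroms:
            offs[c] = total
            total += self._n_bins[c]
        self._offsets = offs
        self.total_bins = total

    # -- basic queries -------------------------------------------------
    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Local bin index of a position on its chromosome."""
        if not 0 <= pos <= self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return min(int(pos) // self.bin_size, self._n_bins[chrom] - 1)

    def global_index(self, chrom: str, local_bin: int) -> int:
        return self._offsets[chrom] + local_bin

    def bin_start(self, chrom: str, local_bin: int) -> int:
        return local_bin * self.bin_size

    def bin_end(self, chrom: str, local_bin: int) -> int:
        return min((local_bin + 1) * self.bin_size, self.chrom_sizes[chrom])

    def bin_length(self, chrom: str, local_bin: int) -> int:
        """True bp length of a bin (partial last bin counted at true length)."""
        return self.bin_end(chrom, local_bin) - self.bin_start(chrom, local_bin)

    def bin_lengths(self, chrom: str) -> np.ndarray:
        n = self._n_bins[chrom]
        lengths = np.full(n, self.bin_size, dtype=np.int64)
        lengths[-1] = self.chrom_sizes[chrom] - (n - 1) * self.bin_size
        return lengths

    def bins_frame(self) -> pd.DataFrame:
        """All bins as a BED-like DataFrame (chrom, start, end)."""
        rows = []
        for c in self.chroms:
            n = self._n_bins[c]
            starts = np.arange(n) * self.bin_size
            ends = np.minimum(starts + self.bin_size, self.chrom_sizes[c])
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def coarsen(self, factor: int) -> "BinnedGenome":
        """Grid at ``factor`` times the current bin size."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return BinnedGenome(self.chrom_sizes, self.bin_size * factor)

    def same_grid(self, other: "BinnedGenome") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chroms == other.chroms
            and self.chrom_sizes == other.chrom_sizes
        )

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, BinnedGenome) and self.same_grid(other)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BinnedGenome({len(self.chroms)} chroms, "
            f"bin_size={self.bin_size}, total_bins={self.total_bins})"
        )


@dataclass
class SignalTrack:
    """Grid-aligned per-bin values (e.g. H3K27ac coverage, gene density).

    ``values`` maps chromosome -> float array of length ``grid.n_bins(chrom)``;
    missing data is NaN.
    """

    grid: BinnedGenome
    values: dict[str, np.ndarray]
    name: str = "signal"

    def __post_init__(self):
        for c in self.grid.chroms:
            v = np.asarray(self.values.get(c, np.full(self.grid.n_bins(c), np.nan)),
                           dtype=float)
            if v.shape != (self.grid.n_bins(c),):
                raise ValueError(f"track length mismatch on {c}")
            self.values[c] = v

    @classmethod
    def from_bedgraph(cls, path, grid: BinnedGenome, name: str = "signal",
                      agg: str = "mean") -> "SignalTrack":
        """Load a bedGraph, averaging (bp-weighted) or summing into grid bins."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         comment="#", dtype={"chrom": str})
        return cls.from_intervals(df, grid, name=name, agg=agg)

    @classmethod
    def from_intervals(cls, df: pd.DataFrame, grid: BinnedGenome,
                       name: str = "signal", agg: str = "mean") -> "SignalTrack":
        values = {c: np.zeros(grid.n_bins(c)) for c in grid.chroms}
        covered = {c: np.zeros(grid.n_bins(c)) for c in grid.chroms}
        for row in df.itertuples(index=False):
            if row.chrom not in values:
                continue
            b0 = int(row.start) // grid.bin_size
            b1 = min((int(row.end) - 1) // grid.bin_size, grid.n_bins(row.chrom) - 1)
            for b in range(b0, b1 + 1):
                lo = max(int(row.start), grid.bin_start(row.chrom, b))
                hi = min(int(row.end), grid.bin_end(row.chrom, b))
                bp = max(hi - lo, 0)
                values[row.chrom][b] += row.value * bp
                covered[row.chrom][b] += bp
        if agg == "mean":
            for c in grid.chroms:
                lengths = grid.bin_lengths(c).astype(float)
                values[c] = values[c] / lengths
        return cls(grid, values, name=name)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.grid.chroms:
                v = self.values[c]
                for b in range(len(v)):
                    if np.isnan(v[b]):
                        continue
                    fh.write(f"{c}\t{self.grid.bin_start(c, b)}"
                             f"\t{self.grid.bin_end(c, b)}\t{v[b]:.6g}\n")

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.grid.chroms])


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")
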