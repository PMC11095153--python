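"""Core in-memory containers shared by every pipeline stage.

All genomic intervals are 0-based half-open (BED convention); the bin holding
base-pair position ``p`` is ``p // bin_size``.  The transcription start site of
a minus-strand gene is the last base of its annotated interval (``end - 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end", "signal"]


@dataclass
class GenomeModel:
    """Chromosome names/lengths, a fixed bin grid and a per-bin GC track.

    GC content is supplied as data (a fraction in [0, 1] per bin); the package
    never parses genome sequence itself.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    bin_size: int
    gc: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom in self.chrom_names:
            length = self.chrom_lengths[chrom]
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            if chrom in self.gc:
                g = np.asarray(self.gc[chrom], dtype=float)
                if g.shape != (self.n_bins(chrom),):
                    raise ValueError(
                        f"GC track for {chrom} has {g.shape[0]} bins, "
                        f"expected {self.n_bins(chrom)}"
                    )
                if np.any((g < 0) | (g > 1)):
                    raise ValueError("GC fractions must lie in [0, 1]")
                self.gc[chrom] = g

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    def rebinned(self, bin_size: int) -> "GenomeModel":
        """Same chromosomes on a different bin grid (GC track dropped)."""
        return GenomeModel(
            chrom_names=list(self.chrom_names),
            chrom_lengths=dict(self.chrom_lengths),
            bin_size=bin_size,
        )


@dataclass
class PeakSet:
    """A sorted table of (chrom, start, end, signal) intervals."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "signal" not in df.columns:
            df["signal"] = 1.0
        df = df[PEAK_COLUMNS]
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative interval coordinates")
            if (df["start"] >= df["end"]).any():
                raise ValueError("intervals must satisfy start < end")
            if (df["signal"] < 0).any():
                raise ValueError("peak signal must be non-negative")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    @classmethod
    def from_records(cls, records) -> "PeakSet":
        return cls(pd.DataFrame(records, columns=PEAK_COLUMNS))

    @classmethod
    def empty(cls) -> "PeakSet":
        return cls(pd.DataFrame(columns=PEAK_COLUMNS))


@dataclass
class SignalTrack:
    """Mean per-bp signal in fixed genomic bins, one vector per chromosome."""

    values: dict[str, np.ndarray]
    bin_size: int
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite signal on {chrom}")
            if np.any(vec < 0):
                raise ValueError(f"negative signal on {chrom}")
            self.values[chrom] = vec

    def mean_over_interval(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean per-bp signal over [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        vec = self.values[chrom]
        bs = self.bin_size
        total = 0.0
        width = 0
        first = start // bs
        last = (end - 1) // bs
        for b in range(first, min(last, len(vec) - 1) + 1):
            lo = max(start, b * bs)
            hi = min(end, (b + 1) * bs)
            if hi > lo:
                total += vec[b] * (hi - lo)
                width += hi - lo
        return total / width if width else 0.0

    def sum_over_interval(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted summed per-bp signal over [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        vec = self.values[chrom]
        bs = self.bin_size
        total = 0.0
        first = start // bs
        last = (end - 1) // bs
        for b in range(first, min(last, len(vec) - 1) + 1):
            lo = max(start, b * bs)
            hi = min(end, (b + 1) * bs)
            if hi > lo:
                total += vec[b] * (hi - lo)
        return total


def _pair_key(chrom_a: str, chrom_b: str) -> tuple[str, str]:
    return (chrom_a, chrom_b)


@dataclass
class ContactMap:
    """Binned chromatin contact matrices.

    ``cis`` maps each chromosome to a dense symmetric count matrix; ``trans``
    maps an ordered chromosome pair (genome order) to a rectangular matrix
    stored once.  ``total_contacts`` is the literal sum over every stored
    entry (cis off-diagonals therefore contribute twice — the convention is
    applied consistently wherever totals are used).
    """

    bin_size: int
    cis: dict[str, np.ndarray]
    trans: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, mat in self.cis.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError(f"cis matrix for {chrom} is not square")
            if np.any(mat < 0):
                raise ValueError(f"negative counts on {chrom}")
            if not np.array_equal(mat, mat.T):
                raise ValueError(f"cis matrix for {chrom} is not symmetric")
            self.cis[chrom] = mat
        for key, mat in self.trans.items():
            mat = np.asarray(mat, dtype=float)
            if np.any(mat < 0):
                raise ValueError(f"negative counts on pair {key}")
            self.trans[key] = mat

    @property
    def total_contacts(self) -> float:
        total = sum(float(m.sum()) for m in self.cis.values())
        total += sum(float(m.sum()) for m in self.trans.values())
        return total

    def cis_total(self, chrom: str) -> float:
        return float(self.cis[chrom].sum())

    def scaled(self, factor: float) -> "ContactMap":
        return ContactMap(
            bin_size=self.bin_size,
            cis={c: m * factor for c, m in self.cis.items()},
            trans={k: m * factor for k, m in self.trans.items()},
        )


@dataclass
class GeneAnnotation:
    """Gene table: id, chromosome, strand and TSS (plus optional body span)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "tss"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dupes = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {list(dupes[:3])}")
        bad = ~self.df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("strand must be '+' or '-'")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def promoter_windows(self, halfwidth: int = 2500) -> pd.DataFrame:
        """Promoter window [tss - hw, tss + hw) per gene, clipped at 0."""
        out = self.df[["gene_id", "chrom", "tss"]].copy()
        out["start"] = np.maximum(out["tss"] - halfwidth, 0)
        out["end"] = out["tss"] + halfwidth
        return out[["gene_id", "chrom", "start", "end"]]
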