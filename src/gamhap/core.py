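"""Window grids and shared containers.

All genomic coordinates follow the BED convention: 0-based, half-open.
A *window grid* is a ``pandas.DataFrame`` with columns ``chrom``, ``start``,
``stop``, sorted by chromosome (in input order) then start, with
non-overlapping windows of constant size except possibly the last window of
each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_COLUMNS = ("chrom", "start", "stop")


class GamhapError(Exception):
    """Base class for user-facing errors."""


class ConfigurationError(GamhapError):
    """Invalid configuration values."""


class DataIntegrityError(GamhapError):
    """Inputs violate a documented invariant."""


def make_windows(chrom_sizes: dict[str, int], window_size: int) -> pd.DataFrame:
    """Tile each chromosome into fixed-size windows (BED3 grid).

    The terminal window of a chromosome may be shorter than ``window_size``.
    """
    if window_size <= 0:
        raise ConfigurationError(f"window_size must be positive, got {window_size}")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ConfigurationError(f"chromosome {chrom!r} has non-positive length {size}")
        starts = np.arange(0, size, window_size, dtype=np.int64)
        stops = np.minimum(starts + window_size, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "stop": stops}))
    return pd.concat(rows, ignore_index=True)


def chromosome_codes(windows: pd.DataFrame) -> np.ndarray:
    """Integer chromosome id per window, in order of first appearance."""
    codes, _ = pd.factorize(windows["chrom"], use_na_sentinel=False)
    return codes.astype(np.int64)


def grids_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b):
        return False
    return all(a[c].reset_index(drop=True).equals(b[c].reset_index(drop=True)) for c in GRID_COLUMNS)


def require_same_grid(a: pd.DataFrame, b: pd.DataFrame, what: str = "inputs") -> None:
    if not grids_equal(a, b):
        raise DataIntegrityError(f"{what} are not on the same window grid")


@dataclass
class CoverageTable:
    """Per-sample, per-window nucleotide coverage (total and per-haplotype).

    ``total``, ``cast`` and ``s129`` map sample id -> int64 array aligned with
    ``windows``. The invariant ``cast + s129 <= total`` holds cell-wise.
    """

    windows: pd.DataFrame
    total: dict[str, np.ndarray] = field(default_factory=dict)
    cast: dict[str, np.ndarray] = field(default_factory=dict)
    s129: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.total)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def validate(self) -> None:
        n = self.n_windows
        for sample in self.samples:
            t, c, s = self.total[sample], self.cast[sample], self.s129[sample]
            if len(t) != n or len(c) != n or len(s) != n:
                raise DataIntegrityError(f"sample {sample!r}: coverage length mismatch with grid")
            if (t < 0).any() or (c < 0).any() or (s < 0).any():
                raise DataIntegrityError(f"sample {sample!r}: negative coverage")
            if (c + s > t).any():
                raise DataIntegrityError(
                    f"sample {sample!r}: phased coverage exceeds total coverage"
                )

    def add_sample(self, sample: str, total: np.ndarray, cast: np.ndarray, s129: np.ndarray) -> None:
        self.total[sample] = np.asarray(total, dtype=np.int64)
        self.cast[sample] = np.asarray(cast, dtype=np.int64)
        self.s129[sample] = np.asarray(s129, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        """Long TSV layout: chrom, start, stop, sample, total_cov, cast_cov, s129_cov."""
        parts = []
        for sample in self.samples:
            part = self.windows.copy()
            part["sample"] = sample
            part["total_cov"] = self.total[sample]
            part["cast_cov"] = self.cast[sample]
            part["s129_cov"] = self.s129[sample]
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CoverageTable":
        required = set(GRID_COLUMNS) | {"sample", "total_cov", "cast_cov", "s129_cov"}
        missing = required - set(frame.columns)
        if missing:
            raise DataIntegrityError(f"coverage table missing columns: {sorted(missing)}")
        samples = list(dict.fromkeys(frame["sample"]))
        first = frame[frame["sample"] == samples[0]]
        windows = first[list(GRID_COLUMNS)].reset_index(drop=True)
        table = cls(windows=windows)
        for sample in samples:
            sub = frame[frame["sample"] == sample]
            if len(sub) != len(windows):
                raise DataIntegrityError(f"sample {sample!r}: window grid differs across samples")
            table.add_sample(
                sample,
                sub["total_cov"].to_numpy(),
                sub["cast_cov"].to_numpy(),
                sub["s129_cov"].to_numpy(),
            )
        table.validate()
        return table

    @classmethod
    def from_tsv(cls, path) -> "CoverageTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class SegregationTable:
    """Boolean windows x samples matrix for one phase."""

    phase: str  # "unphased" | "cast" | "s129"
    windows: pd.DataFrame
    values: pd.DataFrame  # boolean, columns = sample ids

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=bool)

    def to_tsv(self, path) -> None:
        out = pd.concat(
            [self.windows.reset_index(drop=True), self.values.astype(int).reset_index(drop=True)],
            axis=1,
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, phase: str = "unphased") -> "SegregationTable":
        frame = pd.read_csv(path, sep="\t")
        windows = frame[list(GRID_COLUMNS)]
        values = frame.drop(columns=list(GRID_COLUMNS)).astype(bool)
        return cls(phase=phase, windows=windows, values=values)


def write_bedgraph(windows: pd.DataFrame, values: np.ndarray, path) -> None:
    out = windows.copy()
    out["value"] = values
    out.to_csv(path, sep="\t", index=False, header=False)
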