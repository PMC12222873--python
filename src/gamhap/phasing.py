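"""Positive-window calling and haplotype phasing (segregation-table core).

Per sample, an optimal nucleotide-coverage threshold is chosen as the lowest
coverage that maximizes the fraction of positive windows with at least one
neighbouring positive window on the same chromosome. The same threshold is
then applied to the haplotype-specific (SNP-read) coverage to phase windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CoverageTable,
    DataIntegrityError,
    GamhapError,
    SegregationTable,
    chromosome_codes,
)

PHASE_UNASSIGNED = 0
PHASE_CAST = 1
PHASE_S129 = 2
PHASE_BOTH = 3


class UnsuitableSampleError(GamhapError):
    """Sample has no signal from which to derive a threshold."""


@dataclass
class SampleThreshold:
    sample: str
    threshold: int
    neighbor_fraction: float


def neighbor_fraction(positive: np.ndarray, chrom_codes: np.ndarray) -> float:
    """Fraction of positive windows with >= 1 adjacent positive window.

    Adjacency is index +/- 1 on the same chromosome; chromosome ends have
    one-sided neighbourhoods. Returns 0.0 when there are no positive windows.
    """
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    if n_pos == 0:
        return 0.0
    left = np.zeros_like(positive)
    right = np.zeros_like(positive)
    left[1:] = positive[:-1] & (chrom_codes[1:] == chrom_codes[:-1])
    right[:-1] = positive[1:] & (chrom_codes[:-1] == chrom_codes[1:])
    has_neighbor = positive & (left | right)
    return float(has_neighbor.sum()) / n_pos


def candidate_thresholds(coverage: np.ndarray, max_candidates: int = 256) -> np.ndarray:
    """Distinct nonzero coverage values, quantile-subsampled to a cap."""
    values = np.unique(coverage[coverage > 0])
    if len(values) == 0:
        raise UnsuitableSampleError("all-zero coverage: cannot derive a threshold")
    if len(values) > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        values = np.unique(np.quantile(values, qs, method="nearest").astype(values.dtype))
    return values


def compute_optimal_threshold(
    coverage: np.ndarray,
    chrom_codes: np.ndarray,
    candidates: np.ndarray | None = None,
    sample: str = "",
    max_candidates: int = 256,
) -> SampleThreshold:
    """Smallest candidate threshold maximizing the neighbour fraction."""
    coverage = np.asarray(coverage)
    if candidates is None:
        candidates = candidate_thresholds(coverage, max_candidates=max_candidates)
    else:
        candidates = np.sort(np.unique(np.asarray(candidates)))
        if len(candidates) == 0:
            raise UnsuitableSampleError("empty candidate threshold set")
    if not (coverage > 0).any():
        raise UnsuitableSampleError("all-zero coverage: cannot derive a threshold")

    best_t, best_frac = None, -1.0
    for t in candidates:
        frac = neighbor_fraction(coverage >= t, chrom_codes)
        if frac > best_frac:  # ties resolved by the lowest threshold
            best_t, best_frac = int(t), frac
    return SampleThreshold(sample=sample, threshold=best_t, neighbor_fraction=best_frac)


def call_positive_windows(coverage: np.ndarray, threshold: int) -> np.ndarray:
    """Window is positive iff total coverage >= threshold (boundary inclusive)."""
    if threshold < 1:
        raise DataIntegrityError(f"threshold must be >= 1, got {threshold}")
    return np.asarray(coverage) >= threshold


def phase_sample_windows(
    total: np.ndarray,
    cast: np.ndarray,
    s129: np.ndarray,
    threshold: int,
    positive: np.ndarray | None = None,
) -> np.ndarray:
    """Per-window phase codes for one sample.

    Only positive windows are eligible. CAST iff cast coverage >= threshold,
    S129 likewise; both conditions give the rare dual phase.
    """
    total = np.asarray(total)
    cast = np.asarray(cast)
    s129 = np.asarray(s129)
    if (cast + s129 > total).any():
        raise DataIntegrityError("phased coverage exceeds total coverage")
    if positive is None:
        positive = call_positive_windows(total, threshold)
    is_cast = positive & (cast >= threshold)
    is_s129 = positive & (s129 >= threshold)
    phase = np.full(len(total), PHASE_UNASSIGNED, dtype=np.int8)
    phase[is_cast] = PHASE_CAST
    phase[is_s129] = PHASE_S129
    phase[is_cast & is_s129] = PHASE_BOTH
    return phase


@dataclass
class SegregationResult:
    unphased: SegregationTable
    cast: SegregationTable
    s129: SegregationTable
    thresholds: dict[str, SampleThreshold]
    dropped_samples: list[str]
    dual_phased_fraction: float
    phasing_efficiency: dict[str, float]  # phase -> phased positives / positives


def build_segregation_tables(
    table: CoverageTable,
    include_dual: bool = True,
    max_candidates: int = 256,
) -> SegregationResult:
    """Call and phase every sample of a coverage table.

    Samples for which no threshold can be derived are dropped with a warning.
    ``include_dual=False`` keeps dual-phased windows out of both haplotype
    tables (they always stay in the unphased table).
    """
    table.validate()
    if len(table.samples) < 2:
        raise DataIntegrityError("need at least 2 samples to build segregation tables")
    codes = chromosome_codes(table.windows)

    thresholds: dict[str, SampleThreshold] = {}
    dropped: list[str] = []
    columns = {"unphased": {}, "cast": {}, "s129": {}}
    n_positive = 0
    n_phased = {"cast": 0, "s129": 0}
    n_dual = 0
    for sample in table.samples:
        total = table.total[sample]
        try:
            thr = compute_optimal_threshold(
                total, codes, sample=sample, max_candidates=max_candidates
            )
        except UnsuitableSampleError:
            warnings.warn(f"sample {sample!r} dropped: no usable coverage signal", stacklevel=2)
            dropped.append(sample)
            continue
        thresholds[sample] = thr
        positive = call_positive_windows(total, thr.threshold)
        phase = phase_sample_windows(
            total, table.cast[sample], table.s129[sample], thr.threshold, positive
        )
        is_dual = phase == PHASE_BOTH
        cast_col = (phase == PHASE_CAST) | (is_dual if include_dual else np.zeros_like(is_dual))
        s129_col = (phase == PHASE_S129) | (is_dual if include_dual else np.zeros_like(is_dual))
        columns["unphased"][sample] = positive
        columns["cast"][sample] = cast_col
        columns["s129"][sample] = s129_col
        n_positive += int(positive.sum())
        n_phased["cast"] += int(((phase == PHASE_CAST) | is_dual).sum())
        n_phased["s129"] += int(((phase == PHASE_S129) | is_dual).sum())
        n_dual += int(is_dual.sum())

    if not columns["unphased"]:
        raise DataIntegrityError("no sample yielded a usable threshold")

    tables = {
        phase: SegregationTable(
            phase=phase,
            windows=table.windows,
            values=pd.DataFrame(cols, index=table.windows.index),
        )
        for phase, cols in columns.items()
    }
    efficiency = {
        hap: (n_phased[hap] / n_positive if n_positive else float("nan"))
        for hap in ("cast", "s129")
    }
    return SegregationResult(
        unphased=tables["unphased"],
        cast=tables["cast"],
        s129=tables["s129"],
        thresholds=thresholds,
        dropped_samples=dropped,
        dual_phased_fraction=(n_dual / n_positive if n_positive else float("nan")),
        phasing_efficiency=efficiency,
    )
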