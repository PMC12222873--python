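"""Insulation scores, TAD border calling and A/B compartment analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, DataIntegrityError
from .matrices import ContactMatrix

DEFAULT_BORDER_SQUARE = 400_000


@dataclass
class InsulationTrack:
    resolution: int
    square_size: int
    values: np.ndarray  # raw mean-over-square insulation
    normalized: np.ndarray  # log2(value / chromosome mean)
    phase: str = "unphased"


def insulation_score(
    npmi: ContactMatrix, square_size: int, na_tolerance: float = 0.5
) -> InsulationTrack:
    """Mean contact intensity in the square flanking each bin.

    For bin ``i`` with ``s = square_size / resolution`` bins, the square is
    all pairs (a, b) with a in [i-s, i-1] and b in [i+1, i+s], clipped to the
    chromosome. NaN when more than ``na_tolerance`` of the square entries are
    masked. Normalized track is log2 of the ratio to the chromosome mean.
    """
    res = npmi.resolution
    if res <= 0 or square_size % res != 0:
        raise ConfigurationError("square size must be a positive multiple of the resolution")
    s = square_size // res
    if s < 2:
        raise ConfigurationError("insulation square must span at least 2 bins")
    m = npmi.matrix
    n = m.shape[0]
    values = np.full(n, np.nan)
    for i in range(n):
        a_lo, a_hi = max(0, i - s), i  # rows [i-s, i-1]
        b_lo, b_hi = i + 1, min(n, i + s + 1)  # cols [i+1, i+s]
        if a_hi <= a_lo or b_hi <= b_lo:
            continue
        square = m[a_lo:a_hi, b_lo:b_hi]
        finite = np.isfinite(square)
        if finite.sum() == 0 or finite.mean() < (1.0 - na_tolerance):
            continue
        values[i] = square[finite].mean()
    finite = np.isfinite(values)
    mean = values[finite].mean() if finite.any() else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.log2(values / mean)
    return InsulationTrack(
        resolution=res,
        square_size=square_size,
        values=values,
        normalized=normalized,
        phase=npmi.phase,
    )


@dataclass
class BorderSet:
    phase: str
    borders: pd.DataFrame  # columns: minimum (window idx), start_idx, stop_idx, depth

    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.borders["start_idx"], self.borders["stop_idx"]))


def call_tad_borders(track: InsulationTrack, phase: str | None = None) -> BorderSet:
    """Borders at strict local minima of insulation, widened by one bin each side.

    A minimum must lie strictly below two finite neighbours; chromosome-edge
    windows and candidates flanked by NaN are not called.
    """
    v = track.values
    n = len(v)
    if not np.isfinite(v).any():
        warnings.warn("all-NaN insulation track: no borders called", stacklevel=2)
        return BorderSet(
            phase=phase or track.phase,
            borders=pd.DataFrame(columns=["minimum", "start_idx", "stop_idx", "depth"]),
        )
    rows = []
    for i in range(n):
        if not np.isfinite(v[i]):
            continue
        left = v[i - 1] if i > 0 else np.nan
        right = v[i + 1] if i + 1 < n else np.nan
        # strict minimum against two finite neighbours; edges and NaN-flanked
        # candidates are not borders
        if np.isfinite(left) and np.isfinite(right) and v[i] < left and v[i] < right:
            rows.append((i, i - 1, i + 1, v[i]))
    borders = pd.DataFrame(rows, columns=["minimum", "start_idx", "stop_idx", "depth"])
    return BorderSet(phase=phase or track.phase, borders=borders)


def compare_border_sets(
    cast: BorderSet, s129: BorderSet, unphased: BorderSet | None = None, slack: int = 0
) -> dict[str, int]:
    """UpSet-style partition of border sets by interval overlap.

    Two borders match when their (3-window) intervals, each widened by
    ``slack`` windows, intersect. Returns counts keyed by membership
    combination, e.g. ``"cast"``, ``"cast+s129"``, ``"cast+s129+unphased"``.
    """
    sets = {"cast": cast.intervals(), "s129": s129.intervals()}
    if unphased is not None:
        sets["unphased"] = unphased.intervals()

    def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] - slack <= b[1] + slack and b[0] - slack <= a[1] + slack

    counts: dict[str, int] = {}
    for name, intervals in sets.items():
        for iv in intervals:
            members = [
                other
                for other, other_ivs in sets.items()
                if other == name or any(overlaps(iv, o) for o in other_ivs)
            ]
            key = "+".join(sorted(members))
            counts[key] = counts.get(key, 0) + 1
    # matched borders are counted once per membership set, not once per phase
    for key in list(counts):
        k = key.count("+") + 1
        if k > 1:
            counts[key] //= k
    return counts


@dataclass
class CompartmentTrack:
    values: np.ndarray  # normalized eigenvector, A in (0, 1], B in [-1, 0)
    labels: np.ndarray  # "A" / "B" / "" for NaN windows
    phase: str = "unphased"
    component: int = 1


def _oe_matrix(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    oe = np.full_like(matrix, np.nan, dtype=float)
    for off in range(n):
        d = np.diagonal(matrix, off)
        finite = np.isfinite(d)
        if finite.sum() == 0:
            continue
        expected = d[finite].mean()
        idx = np.arange(n - off)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(expected != 0, d / expected, np.nan)
        oe[idx, idx + off] = vals
        oe[idx + off, idx] = vals
    return oe


def call_compartments(
    coseg: ContactMatrix,
    gc_track: np.ndarray,
    phase: str | None = None,
    select_pc: str = "first",
    n_components: int = 3,
) -> CompartmentTrack:
    """A/B compartments from the observed/expected correlation matrix.

    Pipeline: expected = per-distance mean of observed; O/E elementwise;
    Pearson correlation matrix between O/E columns; eigendecomposition; the
    chosen component (first by default, or the best GC correlate among the
    top ``n_components`` with ``select_pc="by-gc"``) is oriented so positive
    values correlate positively with GC. Positive windows are A, negative B;
    values are min-max rescaled to (0, 1] and [-1, 0) per sign class.
    """
    if gc_track is None:
        raise ConfigurationError("GC track is required to orient compartments")
    gc_track = np.asarray(gc_track, dtype=float)
    m = coseg.matrix
    n = m.shape[0]
    if len(gc_track) != n:
        raise ConfigurationError("GC track must match the matrix grid")
    if n < 10:
        raise DataIntegrityError("need at least 10 usable windows")

    oe = _oe_matrix(m)
    good = np.isfinite(oe).sum(axis=0) > 1
    # drop rows that are constant across retained columns (zero variance)
    sub = oe[np.ix_(good, good)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        std = np.nanstd(sub, axis=0)
    good_idx = np.flatnonzero(good)
    keep = std > 0
    good_idx = good_idx[keep]
    sub = oe[np.ix_(good_idx, good_idx)]
    if len(good_idx) < 10:
        raise DataIntegrityError("degenerate matrix: too few variable windows")
    sub = np.nan_to_num(sub, nan=np.nanmean(sub))
    corr = np.corrcoef(sub)
    if not np.isfinite(corr).all():
        raise DataIntegrityError("degenerate correlation matrix")

    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order[:n_components]]

    gc_sub = gc_track[good_idx]
    correlations = []
    for k in range(eigvecs.shape[1]):
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(eigvecs[:, k], gc_sub)[0, 1]
        correlations.append(0.0 if not np.isfinite(c) else c)
    if select_pc == "by-gc":
        k = int(np.argmax(np.abs(correlations)))
    elif select_pc == "first":
        k = 0
    else:
        raise ConfigurationError(f"unknown select_pc mode {select_pc!r}")
    vec = eigvecs[:, k] * np.sign(correlations[k] if correlations[k] != 0 else 1.0)

    values = np.full(n, np.nan)
    values[good_idx] = vec
    labels = np.array([""] * n, dtype=object)
    labels[good_idx] = np.where(vec > 0, "A", "B")

    # per-sign min-max rescale: A -> (0, 1], B -> [-1, 0)
    out = np.full(n, np.nan)
    pos = values > 0
    neg = values < 0
    if pos.any():
        vmax = values[pos].max()
        out[pos] = values[pos] / vmax if vmax > 0 else 1.0
    if neg.any():
        vmin = values[neg].min()
        out[neg] = -values[neg] / vmin if vmin < 0 else -1.0
    zero = values == 0
    labels[zero] = "B"
    out[zero] = 0.0
    return CompartmentTrack(
        values=out, labels=labels, phase=phase or coseg.phase, component=k + 1
    )


def compartment_concordance(cast: CompartmentTrack, s129: CompartmentTrack) -> dict[str, float]:
    """Fractions of jointly-called windows in each AA/BB/AB/BA state."""
    if len(cast.labels) != len(s129.labels):
        raise DataIntegrityError("tracks are not on the same grid")
    called = (cast.labels != "") & (s129.labels != "")
    n = int(called.sum())
    if n == 0:
        raise DataIntegrityError("no jointly-called windows")
    out = {}
    for a in "AB":
        for b in "AB":
            out[a + b] = float(((cast.labels == a) & (s129.labels == b) & called).sum()) / n
    return out
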