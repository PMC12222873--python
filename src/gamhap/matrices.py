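"""Co-segregation and NPMI contact matrices, distance decay, z-scores and
allele-specific / strong contact calling.

All matrices are per-chromosome, symmetric, indexed by the window grid of
that chromosome. Masked windows are represented as NaN rows/columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataIntegrityError

NPMI_MIN_INTENSITY = 0.3
DELTA_Z_THRESHOLD = 1.0
STRONG_Z_THRESHOLD = 2.0
MAX_CONTACT_DISTANCE = 50_000_000

#: R ``ksmooth(kernel="normal")`` scales the kernel so its quartiles sit at
#: +/- 0.25 * bandwidth; sigma = 0.25 * bw / qnorm(0.75).
_KSMOOTH_SIGMA_FACTOR = 0.25 / 0.6744897501960817


@dataclass
class ContactMatrix:
    chromosome: str
    resolution: int
    matrix: np.ndarray
    kind: str  # "coseg-count" | "npmi" | "zscore"
    phase: str = "unphased"
    n_samples: int = 0
    marginals: np.ndarray | None = None


def cosegregation_matrix(
    seg_matrix: np.ndarray,
    chromosome: str = "",
    resolution: int = 0,
    phase: str = "unphased",
    max_distance: int | None = None,
) -> ContactMatrix:
    """Entry (i, j) = number of samples in which both windows are positive.

    ``seg_matrix`` is windows x samples boolean for a single chromosome.
    Entries beyond ``max_distance`` are left as NaN when a cap is given.
    """
    seg = np.asarray(seg_matrix, dtype=bool)
    if seg.size == 0:
        raise DataIntegrityError("empty segregation table")
    counts = (seg.astype(np.int64) @ seg.astype(np.int64).T).astype(float)
    marginals = seg.sum(axis=1).astype(np.int64)
    if max_distance is not None and resolution > 0:
        n = counts.shape[0]
        i, j = np.indices((n, n))
        counts[np.abs(i - j) * resolution > max_distance] = np.nan
    return ContactMatrix(
        chromosome=chromosome,
        resolution=resolution,
        matrix=counts,
        kind="coseg-count",
        phase=phase,
        n_samples=seg.shape[1],
        marginals=marginals,
    )


def npmi_normalize(coseg: ContactMatrix) -> ContactMatrix:
    """Normalized pointwise mutual information of window co-segregation.

    With p_i = marginal_i / M and p_ij = coseg_ij / M:
    NPMI = ln(p_ij / (p_i p_j)) / (-ln p_ij), natural log. Conventions:
    p_ij = 0 -> -1; p_ij = p_i = p_j -> 1; windows with zero marginal -> NaN;
    diagonal -> NaN.
    """
    if coseg.n_samples <= 0:
        raise DataIntegrityError("sample count must be positive")
    M = float(coseg.n_samples)
    marg = np.asarray(coseg.marginals, dtype=float)
    counts = coseg.matrix
    if ((marg == 0)[:, None] & (np.nan_to_num(counts) > 0)).any():
        raise DataIntegrityError("nonzero co-segregation with a zero marginal")
    p_i = marg / M
    p_ij = counts / M
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = -np.log(p_ij)
        npmi = np.log(p_ij / (p_i[:, None] * p_i[None, :])) / denom
    npmi = np.where(np.nan_to_num(p_ij) == 0, -1.0, npmi)
    # perfect co-segregation: p_ij == p_i == p_j > 0 (0/0 above)
    perfect = (p_ij == p_i[:, None]) & (p_ij == p_i[None, :]) & (np.nan_to_num(p_ij) > 0)
    npmi[perfect] = 1.0
    npmi[np.isnan(counts)] = np.nan
    bad = p_i == 0
    npmi[bad, :] = np.nan
    npmi[:, bad] = np.nan
    np.fill_diagonal(npmi, np.nan)
    return ContactMatrix(
        chromosome=coseg.chromosome,
        resolution=coseg.resolution,
        matrix=npmi,
        kind="npmi",
        phase=coseg.phase,
        n_samples=coseg.n_samples,
        marginals=coseg.marginals,
    )


@dataclass
class DecayCurve:
    log10_distance: np.ndarray  # 0.1-spaced evaluation grid
    mean_intensity: np.ndarray  # raw per-grid-point means (NaN where empty)
    smoothed: np.ndarray
    slopes: np.ndarray  # successive differences of the smoothed curve


def diagonal_means(matrix: np.ndarray) -> np.ndarray:
    """Mean value per genomic-distance offset (offset 1..n-1), NaN-aware."""
    n = matrix.shape[0]
    out = np.full(n - 1, np.nan)
    for off in range(1, n):
        d = np.diagonal(matrix, off)
        finite = d[np.isfinite(d)]
        if len(finite):
            out[off - 1] = finite.mean()
    return out


def decay_and_momentum(
    npmi: ContactMatrix, bandwidth: float = 0.3, grid_step: float = 0.1
) -> DecayCurve:
    """Distance decay on a log10 axis with Normal-kernel smoothing.

    Mean intensity per distance offset is binned onto a 0.1-spaced log10
    grid; the momentum (slope) track is the successive difference of the
    smoothed curve between adjacent breakpoints.
    """
    if npmi.resolution <= 0:
        raise DataIntegrityError("matrix resolution required for decay computation")
    means = diagonal_means(npmi.matrix)
    valid = np.isfinite(means)
    if valid.sum() < 2:
        raise DataIntegrityError("need at least 2 populated distance bins")
    distances = (np.arange(1, len(means) + 1) * npmi.resolution).astype(float)
    logd = np.log10(distances[valid])
    vals = means[valid]

    lo = np.floor(logd.min() / grid_step) * grid_step
    hi = np.ceil(logd.max() / grid_step) * grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    # raw per-grid-point means (nearest grid point)
    raw = np.full(len(grid), np.nan)
    assignment = np.rint((logd - lo) / grid_step).astype(int)
    for g in np.unique(assignment):
        raw[g] = vals[assignment == g].mean()

    sigma = _KSMOOTH_SIGMA_FACTOR * bandwidth
    diff = grid[:, None] - logd[None, :]
    weights = np.exp(-0.5 * (diff / sigma) ** 2)
    wsum = weights.sum(axis=1)
    with np.errstate(invalid="ignore"):
        smoothed = np.where(wsum > 0, weights @ vals / wsum, np.nan)
    slopes = np.diff(smoothed)
    return DecayCurve(log10_distance=grid, mean_intensity=raw, smoothed=smoothed, slopes=slopes)


def zscore_by_distance(npmi: ContactMatrix, per_distance: bool = True) -> ContactMatrix:
    """Standardize contacts to z-scores, by default within each distance stratum.

    Population standard deviation; sd = 0 strata map to z = 0. A global mode
    (single mean/sd over all finite off-diagonal entries) is available.
    """
    m = npmi.matrix
    n = m.shape[0]
    z = np.full_like(m, np.nan)
    if per_distance:
        for off in range(1, n):
            d = np.diagonal(m, off)
            finite = np.isfinite(d)
            if finite.sum() == 0:
                continue
            mean = d[finite].mean()
            sd = d[finite].std()
            # guard against pure floating-point residue on constant strata
            if sd <= 1e-12 * max(1.0, abs(mean)):
                sd = 0.0
            zd = np.where(finite, 0.0 if sd == 0 else (d - mean) / sd, np.nan)
            idx = np.arange(n - off)
            z[idx, idx + off] = zd
            z[idx + off, idx] = zd
    else:
        mask = np.isfinite(m) & ~np.eye(n, dtype=bool)
        if mask.sum():
            mean, sd = m[mask].mean(), m[mask].std()
            z[mask] = 0.0 if sd == 0 else (m[mask] - mean) / sd
    return ContactMatrix(
        chromosome=npmi.chromosome,
        resolution=npmi.resolution,
        matrix=z,
        kind="zscore",
        phase=npmi.phase,
        n_samples=npmi.n_samples,
        marginals=npmi.marginals,
    )


CLASS_CAST_SPECIFIC = "CAST-specific"
CLASS_S129_SPECIFIC = "S129-specific"
CLASS_STRONG_CAST = "strong-CAST"
CLASS_STRONG_S129 = "strong-S129"


def _upper_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def allele_specific_contacts(
    z_cast: ContactMatrix,
    z_s129: ContactMatrix,
    npmi_cast: ContactMatrix,
    npmi_s129: ContactMatrix,
    usable: np.ndarray | None = None,
    delta_threshold: float = DELTA_Z_THRESHOLD,
    npmi_min: float = NPMI_MIN_INTENSITY,
    max_distance: int = MAX_CONTACT_DISTANCE,
    intensity_mode: str = "gaining",
) -> pd.DataFrame:
    """Classify allele-specific contacts from delta z-scores.

    delta = z_cast - z_s129. CAST-specific iff delta >= +threshold and the
    NPMI intensity filter passes; S129-specific symmetrically. The intensity
    filter uses the gaining haplotype's map by default, or either map with
    ``intensity_mode="either"``. Pairs are restricted to ``max_distance`` and
    to usable (unmasked) windows.
    """
    shapes = {m.matrix.shape for m in (z_cast, z_s129, npmi_cast, npmi_s129)}
    if len(shapes) != 1:
        raise DataIntegrityError("matrices are not on the same grid")
    if intensity_mode not in ("gaining", "either"):
        raise DataIntegrityError(f"unknown intensity mode {intensity_mode!r}")
    n = z_cast.matrix.shape[0]
    i, j = _upper_pairs(n)
    res = z_cast.resolution
    keep = (j - i) * res <= max_distance
    if usable is not None:
        usable = np.asarray(usable, dtype=bool)
        keep &= usable[i] & usable[j]
    i, j = i[keep], j[keep]
    delta = z_cast.matrix[i, j] - z_s129.matrix[i, j]
    nc, ns = npmi_cast.matrix[i, j], npmi_s129.matrix[i, j]
    if intensity_mode == "gaining":
        cast_ok, s129_ok = nc > npmi_min, ns > npmi_min
    else:
        either = (nc > npmi_min) | (ns > npmi_min)
        cast_ok = s129_ok = either
    is_cast = (delta >= delta_threshold) & cast_ok
    is_s129 = (delta <= -delta_threshold) & s129_ok
    sel = is_cast | is_s129
    return pd.DataFrame(
        {
            "window_i": i[sel],
            "window_j": j[sel],
            "distance": (j[sel] - i[sel]) * res,
            "delta_z": delta[sel],
            "npmi_cast": nc[sel],
            "npmi_s129": ns[sel],
            "class": np.where(is_cast[sel], CLASS_CAST_SPECIFIC, CLASS_S129_SPECIFIC),
        }
    )


def strong_contacts(
    z: ContactMatrix,
    npmi: ContactMatrix,
    z_min: float = STRONG_Z_THRESHOLD,
    npmi_min: float = NPMI_MIN_INTENSITY,
    max_distance: int | None = None,
) -> pd.DataFrame:
    """Strongest contacts of one haplotype: z > 2.0 and NPMI > 0.3."""
    if z.matrix.shape != npmi.matrix.shape:
        raise DataIntegrityError("matrices are not on the same grid")
    n = z.matrix.shape[0]
    i, j = _upper_pairs(n)
    if max_distance is not None and z.resolution > 0:
        keep = (j - i) * z.resolution <= max_distance
        i, j = i[keep], j[keep]
    zv, nv = z.matrix[i, j], npmi.matrix[i, j]
    sel = (zv > z_min) & (nv > npmi_min)
    label = CLASS_STRONG_CAST if z.phase == "cast" else (
        CLASS_STRONG_S129 if z.phase == "s129" else "strong"
    )
    return pd.DataFrame(
        {
            "window_i": i[sel],
            "window_j": j[sel],
            "distance": (j[sel] - i[sel]) * z.resolution,
            "z": zv[sel],
            "npmi": nv[sel],
            "class": label,
        }
    )


def matrix_to_triplets(cm: ContactMatrix, windows: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangle triplet export: window_i BED, window_j BED, value."""
    n = cm.matrix.shape[0]
    i, j = _upper_pairs(n)
    vals = cm.matrix[i, j]
    keep = np.isfinite(vals)
    i, j, vals = i[keep], j[keep], vals[keep]
    w = windows.reset_index(drop=True)
    return pd.DataFrame(
        {
            "chrom_i": w["chrom"].to_numpy()[i],
            "start_i": w["start"].to_numpy()[i],
            "stop_i": w["stop"].to_numpy()[i],
            "chrom_j": w["chrom"].to_numpy()[j],
            "start_j": w["start"].to_numpy()[j],
            "stop_j": w["stop"].to_numpy()[j],
            "value": vals,
        }
    )
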