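"""Sample- and window-level quality control.

Pass criteria per sample: orphan-window percentage < 60, more than 50,000
uniquely mapped reads, and no cross-contamination flag (within-plate Jaccard
similarity of positive-window sets > 0.4). Dataset resolution is assessed by
comparing the co-segregation count distribution against a mean-matched
Poisson reference (Kendall's tau >= 0.95 after Yeo-Johnson transformation),
and undersampled windows are masked with the smoothed-WDF normalized-delta
rule plus a mappability floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataIntegrityError, chromosome_codes

ORPHAN_MAX_PCT = 60.0
MIN_READS = 50_000
JACCARD_MAX = 0.4
ND_MAX = 5.0
MAPPABILITY_MIN = 0.2
RESOLUTION_TAU_MIN = 0.95


@dataclass
class SampleQCRecord:
    sample: str
    mapped_reads: int
    orphan_pct: float  # NaN when undefined (no positive windows)
    genome_coverage_pct: float
    max_jaccard: float = float("nan")
    contaminated: bool = False
    passed: bool = False
    fail_reasons: list[str] = field(default_factory=list)


def orphan_percentage(positive: np.ndarray, chrom_codes: np.ndarray) -> float:
    """Percentage of positive windows with no adjacent positive window."""
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    if n_pos == 0:
        return float("nan")
    left = np.zeros_like(positive)
    right = np.zeros_like(positive)
    left[1:] = positive[:-1] & (chrom_codes[1:] == chrom_codes[:-1])
    right[:-1] = positive[1:] & (chrom_codes[:-1] == chrom_codes[1:])
    orphans = positive & ~(left | right)
    return 100.0 * float(orphans.sum()) / n_pos


def sample_metrics(
    sample: str,
    positive: np.ndarray,
    chrom_codes: np.ndarray,
    mapped_reads: int,
    orphan_max_pct: float = ORPHAN_MAX_PCT,
    min_reads: int = MIN_READS,
) -> SampleQCRecord:
    """QC metrics and provisional pass flag (contamination applied separately)."""
    positive = np.asarray(positive, dtype=bool)
    orphan = orphan_percentage(positive, chrom_codes)
    coverage_pct = 100.0 * float(positive.sum()) / len(positive)
    reasons = []
    if np.isnan(orphan):
        reasons.append("no-positive-windows")
    elif orphan >= orphan_max_pct:
        reasons.append("orphan-windows")
    if mapped_reads <= min_reads:  # strict ">50,000"
        reasons.append("low-read-count")
    return SampleQCRecord(
        sample=sample,
        mapped_reads=int(mapped_reads),
        orphan_pct=orphan,
        genome_coverage_pct=coverage_pct,
        passed=not reasons,
        fail_reasons=reasons,
    )


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return float((a & b).sum()) / union


def contamination_filter(
    columns: dict[str, np.ndarray], jaccard_max: float = JACCARD_MAX
) -> tuple[pd.DataFrame, set[str]]:
    """Pairwise Jaccard within one plate group; flag members of pairs > cutoff."""
    samples = list(columns)
    if len(samples) < 2:
        return pd.DataFrame(columns=["sample_a", "sample_b", "jaccard"]), set()
    rows = []
    flagged: set[str] = set()
    for a, b in combinations(samples, 2):
        j = jaccard(columns[a], columns[b])
        rows.append((a, b, j))
        if j > jaccard_max:
            flagged.update((a, b))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "jaccard"]), flagged


def apply_contamination(
    records: dict[str, SampleQCRecord], pairs: pd.DataFrame, flagged: set[str]
) -> None:
    """Fold contamination results into existing QC records (in place)."""
    for sample, record in records.items():
        mine = pairs[(pairs["sample_a"] == sample) | (pairs["sample_b"] == sample)]
        if len(mine):
            record.max_jaccard = float(mine["jaccard"].max())
        if sample in flagged:
            record.contaminated = True
            record.fail_reasons.append("cross-contamination")
            record.passed = False


def qc_dataset(
    seg_values: pd.DataFrame,
    chrom_codes: np.ndarray,
    mapped_reads: dict[str, int],
    plates: dict[str, str] | None = None,
    orphan_max_pct: float = ORPHAN_MAX_PCT,
    min_reads: int = MIN_READS,
    jaccard_max: float = JACCARD_MAX,
) -> pd.DataFrame:
    """Full sample QC over a segregation table; returns a report frame.

    ``plates`` maps sample -> plate group for the contamination check;
    by default all samples form one group.
    """
    records = {
        s: sample_metrics(
            s,
            seg_values[s].to_numpy(dtype=bool),
            chrom_codes,
            mapped_reads.get(s, 0),
            orphan_max_pct=orphan_max_pct,
            min_reads=min_reads,
        )
        for s in seg_values.columns
    }
    if plates is None:
        plates = {s: "plate1" for s in records}
    for plate in sorted(set(plates.values())):
        members = [s for s in records if plates.get(s) == plate]
        cols = {s: seg_values[s].to_numpy(dtype=bool) for s in members}
        pairs, flagged = contamination_filter(cols, jaccard_max=jaccard_max)
        apply_contamination({s: records[s] for s in members}, pairs, flagged)
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "mapped_reads": r.mapped_reads,
                "orphan_pct": r.orphan_pct,
                "genome_coverage_pct": r.genome_coverage_pct,
                "max_jaccard": r.max_jaccard,
                "contaminated": r.contaminated,
                "pass": r.passed,
                "fail_reasons": ",".join(r.fail_reasons),
            }
            for r in records.values()
        ]
    )


@dataclass
class ResolutionReport:
    resolution: int
    stratum: tuple[float, float]  # genomic distance bounds (bp), half-open
    tau: float
    passed: bool
    codetection_fraction: float
    n_pairs: int
    reason: str = ""


def _pair_counts_in_stratum(
    matrix: np.ndarray, resolution: int, lo: float, hi: float
) -> np.ndarray:
    n = matrix.shape[0]
    counts = []
    for off in range(1, n):
        dist = off * resolution
        if lo <= dist < hi:
            counts.append(np.diagonal(matrix, off))
    if not counts:
        return np.array([])
    return np.concatenate(counts)


def yeojohnson_poisson_tau(counts: np.ndarray, rng: np.random.Generator) -> float:
    """Kendall tau between transformed counts and a mean-matched Poisson sample.

    Both vectors are Yeo-Johnson transformed with the lambda fitted on the
    empirical counts, sorted (quantile-aligned) and correlated.
    """
    counts = np.asarray(counts, dtype=float)
    transformed, lam = stats.yeojohnson(counts)
    reference = rng.poisson(counts.mean(), size=len(counts)).astype(float)
    ref_transformed = stats.yeojohnson(reference, lmbda=lam)
    return float(stats.kendalltau(np.sort(transformed), np.sort(ref_transformed)).statistic)


def resolution_check(
    coseg_matrices: dict[str, np.ndarray],
    resolution: int,
    strata: list[tuple[float, float]],
    seed: int = 0,
    tau_min: float = RESOLUTION_TAU_MIN,
    min_pairs: int = 100,
) -> list[ResolutionReport]:
    """Kendall-tau comparison of co-segregation counts to a Poisson reference.

    For each distance stratum, raw co-segregation counts of all
    intrachromosomal pairs are pooled genome-wide, Yeo-Johnson transformed
    (lambda fitted by maximum likelihood on the empirical counts), and
    compared quantile-to-quantile against an equally sized, mean-matched
    Poisson sample pushed through the same transform.
    """
    rng = np.random.default_rng(seed)
    reports = []
    for lo, hi in strata:
        counts = np.concatenate(
            [_pair_counts_in_stratum(m, resolution, lo, hi) for m in coseg_matrices.values()]
        ) if coseg_matrices else np.array([])
        counts = counts[np.isfinite(counts)]
        if len(counts) < min_pairs:
            warnings.warn(f"stratum [{lo}, {hi}): only {len(counts)} pairs, skipped", stacklevel=2)
            reports.append(
                ResolutionReport(resolution, (lo, hi), float("nan"), False,
                                 float("nan"), len(counts), reason="empty-stratum")
            )
            continue
        codetect = float((counts >= 1).mean())
        if counts.max() == counts.min():
            reports.append(
                ResolutionReport(resolution, (lo, hi), float("nan"), False,
                                 codetect, len(counts), reason="degenerate-counts")
            )
            continue
        tau = yeojohnson_poisson_tau(counts, rng)
        reports.append(
            ResolutionReport(
                resolution, (lo, hi), float(tau), bool(tau >= tau_min), codetect, len(counts)
            )
        )
    return reports


REASON_ND = "undersampled-ND"
REASON_ND_NEIGHBOR = "neighbor-of-ND"
REASON_MAPPABILITY = "low-mappability"


def smooth_track(values: np.ndarray, chrom_codes: np.ndarray, span: int = 11) -> np.ndarray:
    """Centered moving mean per chromosome, edge-truncated."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    half = span // 2
    for code in np.unique(chrom_codes):
        idx = np.flatnonzero(chrom_codes == code)
        v = values[idx]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        n = len(v)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        out[idx] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def undersampling_mask(
    wdf: np.ndarray,
    mappability: np.ndarray,
    chrom_codes: np.ndarray,
    nd_max: float = ND_MAX,
    mappability_min: float = MAPPABILITY_MIN,
    span: int = 11,
    flank: int = 2,
) -> pd.DataFrame:
    """Window mask with exclusion reasons.

    ND = (raw - smoothed) / smoothed of the WDF track (11-window moving mean
    per chromosome). Windows with ND > ``nd_max`` (or undefined ND) are
    excluded together with ``flank`` windows on each side (same chromosome);
    windows below the mappability floor are excluded regardless.
    """
    wdf = np.asarray(wdf, dtype=float)
    mappability = np.asarray(mappability, dtype=float)
    if len(wdf) != len(mappability) or len(wdf) != len(chrom_codes):
        raise DataIntegrityError("WDF, mappability and grid must have equal length")
    smoothed = smooth_track(wdf, chrom_codes, span=span)
    with np.errstate(divide="ignore", invalid="ignore"):
        nd = (wdf - smoothed) / smoothed
    nd_bad = (smoothed == 0) | ~np.isfinite(nd) | (nd > nd_max)

    n = len(wdf)
    reason = np.array([""] * n, dtype=object)
    excluded = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(nd_bad):
        excluded[i] = True
        reason[i] = REASON_ND
    for i in np.flatnonzero(nd_bad):
        for j in range(max(0, i - flank), min(n, i + flank + 1)):
            if j != i and chrom_codes[j] == chrom_codes[i] and not excluded[j]:
                excluded[j] = True
                reason[j] = REASON_ND_NEIGHBOR
    low_map = mappability < mappability_min
    newly = low_map & ~excluded
    excluded |= low_map
    reason[newly] = REASON_MAPPABILITY

    return pd.DataFrame({"usable": ~excluded, "reason": reason, "nd": nd})
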