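"""Haplotype-resolved feature statistics.

Covers window detection frequency (compaction proxy), allele-specific
expression calling, peak phasing (log2 fold-change rule for ChIP marks,
D-score permutation rule for accessibility peaks), promoter-state
classification, isoform selection, circular permutation tests, regulatory
contact annotation, differential promoter methylation, thin-section allele
quantification and linear-genome feature co-occurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError, DataIntegrityError

# ---------------------------------------------------------------------------
# Window detection frequency

ASE_MIN_TOTAL = 20
ASE_MAX_PADJ = 0.05
ASE_MIN_ABS_LOG2FC = 1.0
ASE_MIN_TPM = 1.0

CHIP_MIN_READS = 10
CHIP_MIN_ABS_LOG2FC = 2.0

ATAC_MIN_READS = 10
ATAC_MAX_FDR = 0.01
ATAC_D_THRESHOLD = 0.3


@dataclass
class WdfTrack:
    unphased: np.ndarray
    cast: np.ndarray
    s129: np.ndarray
    differential: np.ndarray  # cast - s129; positive = decompaction in CAST


def wdf_tracks(
    unphased: np.ndarray, cast: np.ndarray, s129: np.ndarray
) -> WdfTrack:
    """Window detection frequency per phase from windows x samples matrices."""
    tracks = {}
    for name, seg in (("unphased", unphased), ("cast", cast), ("s129", s129)):
        seg = np.asarray(seg, dtype=bool)
        if seg.ndim != 2 or seg.shape[1] == 0:
            raise DataIntegrityError(f"{name}: need a windows x samples matrix with >= 1 sample")
        tracks[name] = seg.sum(axis=1) / seg.shape[1]
    if len({t.shape for t in tracks.values()}) != 1:
        raise DataIntegrityError("segregation tables are not on the same grid")
    return WdfTrack(
        unphased=tracks["unphased"],
        cast=tracks["cast"],
        s129=tracks["s129"],
        differential=tracks["cast"] - tracks["s129"],
    )


# ---------------------------------------------------------------------------
# Allele-specific expression

CLASS_CAST_ASE = "CAST-ASE"
CLASS_S129_ASE = "S129-ASE"
CLASS_BIALLELIC = "biallelic"
CLASS_MONO_CAST = "monoallelic-CAST"
CLASS_MONO_S129 = "monoallelic-S129"
CLASS_NO_SNP = "no-SNP"
CLASS_EXCLUDED = "excluded"


def _signed_log2_ratio(cast: np.ndarray, s129: np.ndarray) -> np.ndarray:
    """log2(cast / s129) with zero denominators/numerators as signed infinity."""
    cast = np.asarray(cast, dtype=float)
    s129 = np.asarray(s129, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(cast / s129)
    lfc[(cast > 0) & (s129 == 0)] = np.inf
    lfc[(cast == 0) & (s129 > 0)] = -np.inf
    lfc[(cast == 0) & (s129 == 0)] = np.nan
    return lfc


def ase_call(
    counts: pd.DataFrame,
    min_total: int = ASE_MIN_TOTAL,
    max_padj: float = ASE_MAX_PADJ,
    min_abs_log2fc: float = ASE_MIN_ABS_LOG2FC,
    min_tpm: float = ASE_MIN_TPM,
) -> pd.DataFrame:
    """Allele-specific expression calls for a gene count table.

    ``counts`` needs columns ``gene``, ``cast``, ``s129`` and ``tpm``.
    Features with no allelic reads are ``no-SNP``; features below the total
    coverage floor are ``excluded``. The rest are tested with a two-sided
    exact binomial test against 0.5 and BH-corrected; ASE requires adjusted
    p <= 0.05, |log2FC| >= 1 and TPM >= 1. ASE genes with one allele at zero
    are monoallelic.
    """
    cast = counts["cast"].to_numpy()
    s129 = counts["s129"].to_numpy()
    if (cast < 0).any() or (s129 < 0).any():
        raise DataIntegrityError("negative allelic counts")
    total = cast + s129
    tpm = counts["tpm"].to_numpy(dtype=float)

    out = counts.copy()
    out["total"] = total
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ase_ratio"] = np.where(total > 0, cast / np.maximum(total, 1), np.nan)
    out["log2fc"] = _signed_log2_ratio(cast, s129)

    tested = total >= min_total
    pvals = np.full(len(out), np.nan)
    for i in np.flatnonzero(tested):
        pvals[i] = stats.binomtest(int(cast[i]), int(total[i]), 0.5).pvalue
    padj = np.full(len(out), np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out["pvalue"] = pvals
    out["padj"] = padj

    classes = np.array([CLASS_EXCLUDED] * len(out), dtype=object)
    classes[total == 0] = CLASS_NO_SNP
    lfc = out["log2fc"].to_numpy()
    with np.errstate(invalid="ignore"):
        is_ase = tested & (padj <= max_padj) & (np.abs(lfc) >= min_abs_log2fc) & (tpm >= min_tpm)
    classes[tested] = CLASS_BIALLELIC
    classes[is_ase & (lfc > 0)] = CLASS_CAST_ASE
    classes[is_ase & (lfc < 0)] = CLASS_S129_ASE
    classes[is_ase & (s129 == 0)] = CLASS_MONO_CAST
    classes[is_ase & (cast == 0)] = CLASS_MONO_S129
    out["class"] = classes
    return out


# ---------------------------------------------------------------------------
# Peak phasing

PEAK_CAST = "CAST"
PEAK_S129 = "S129"
PEAK_COMMON = "common"
PEAK_UNPHASED = "unphased"


def phase_peaks(
    counts: pd.DataFrame,
    min_reads: int = CHIP_MIN_READS,
    min_abs_log2fc: float = CHIP_MIN_ABS_LOG2FC,
) -> pd.DataFrame:
    """ChIP peak phasing by allelic fold change.

    Peaks with fewer than 10 SNP-containing reads are unphased; |log2FC| > 2
    assigns the haplotype by sign; the rest are common. Zero denominators
    count as infinite fold change (allele-specific).
    """
    cast = counts["cast"].to_numpy()
    s129 = counts["s129"].to_numpy()
    total = cast + s129
    lfc = _signed_log2_ratio(cast, s129)
    classes = np.array([PEAK_COMMON] * len(counts), dtype=object)
    with np.errstate(invalid="ignore"):
        classes[lfc > min_abs_log2fc] = PEAK_CAST
        classes[lfc < -min_abs_log2fc] = PEAK_S129
    classes[total < min_reads] = PEAK_UNPHASED
    out = counts.copy()
    out["total"] = total
    out["log2fc"] = lfc
    out["class"] = classes
    return out


def d_score(cast: np.ndarray, s129: np.ndarray) -> np.ndarray:
    """Allelic reads-ratio imbalance: (cast - s129) / (cast + s129)."""
    cast = np.asarray(cast, dtype=float)
    s129 = np.asarray(s129, dtype=float)
    total = cast + s129
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(total > 0, (cast - s129) / total, np.nan)


def d_score_permutation_pvalue(
    cast: int,
    s129: int,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
    exact_max_reads: int = 15,
) -> float:
    """P(|D_null| >= |D_obs|) under random relabelling of each read.

    Each read is reassigned to CAST with probability 0.5, so the null |D| is
    |2k - n| / n with k ~ Binomial(n, 1/2). For n <= ``exact_max_reads`` the
    2**n relabellings are enumerated exactly; otherwise a Monte Carlo
    estimate with the add-one rule (1 + #null >= obs) / (1 + n_perm) is used.
    """
    n = int(cast) + int(s129)
    if n == 0:
        return float("nan")
    obs = abs(cast - s129) / n
    if n <= exact_max_reads:
        k = np.arange(n + 1)
        null = np.abs(2 * k - n) / n
        weights = stats.binom.pmf(k, n, 0.5)
        return float(weights[null >= obs - 1e-12].sum())
    if n_permutations < 1000:
        raise ConfigurationError("need at least 1000 permutations")
    if rng is None:
        rng = np.random.default_rng()
    ks = rng.binomial(n, 0.5, size=n_permutations)
    null = np.abs(2 * ks - n) / n
    return float(1 + (null >= obs - 1e-12).sum()) / (1 + n_permutations)


def atac_allelic_peaks(
    counts: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_reads: int = ATAC_MIN_READS,
    max_fdr: float = ATAC_MAX_FDR,
    d_threshold: float = ATAC_D_THRESHOLD,
    literal_inside_range: bool = False,
) -> pd.DataFrame:
    """D-score based allele-specific accessibility peak calling.

    ``counts`` needs ``peak`` plus ``cast_rep<k>``/``s129_rep<k>`` column
    pairs. A per-peak permutation p-value is computed on the replicate-pooled
    counts, BH-corrected across peaks. A peak is allele-specific when every
    replicate has >= ``min_reads`` reads and |D| >= ``d_threshold`` (set
    ``literal_inside_range=True`` for the inside-range variant), and the
    FDR-adjusted p-value is < 0.01; the pooled D sign gives the haplotype.
    """
    rep_ids = sorted(
        {c.split("_rep")[1] for c in counts.columns if c.startswith("cast_rep")}
    )
    if not rep_ids:
        raise DataIntegrityError("need cast_rep<k>/s129_rep<k> count columns")
    rng = np.random.default_rng(seed)
    cast_cols = [f"cast_rep{r}" for r in rep_ids]
    s129_cols = [f"s129_rep{r}" for r in rep_ids]
    cast_pool = counts[cast_cols].sum(axis=1).to_numpy()
    s129_pool = counts[s129_cols].sum(axis=1).to_numpy()

    out = counts.copy()
    for r in rep_ids:
        out[f"d_rep{r}"] = d_score(counts[f"cast_rep{r}"].to_numpy(),
                                   counts[f"s129_rep{r}"].to_numpy())
    out["d_pooled"] = d_score(cast_pool, s129_pool)

    pvals = np.array([
        d_score_permutation_pvalue(c, s, n_permutations=n_permutations, rng=rng)
        for c, s in zip(cast_pool, s129_pool)
    ])
    out["pvalue"] = pvals
    finite = np.isfinite(pvals)
    padj = np.full(len(out), np.nan)
    if finite.any():
        padj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    out["padj"] = padj

    reads_ok = np.ones(len(out), dtype=bool)
    d_ok = np.ones(len(out), dtype=bool)
    for r in rep_ids:
        tot = counts[f"cast_rep{r}"].to_numpy() + counts[f"s129_rep{r}"].to_numpy()
        reads_ok &= tot >= min_reads
        d_r = out[f"d_rep{r}"].to_numpy()
        with np.errstate(invalid="ignore"):
            if literal_inside_range:
                d_ok &= np.abs(d_r) <= d_threshold
            else:
                d_ok &= np.abs(d_r) >= d_threshold
    with np.errstate(invalid="ignore"):
        significant = reads_ok & d_ok & np.isfinite(padj) & (padj < max_fdr)
    classes = np.array([PEAK_COMMON] * len(out), dtype=object)
    total_pool = cast_pool + s129_pool
    classes[total_pool == 0] = PEAK_UNPHASED
    d_pool = out["d_pooled"].to_numpy()
    classes[significant & (d_pool > 0)] = PEAK_CAST
    classes[significant & (d_pool < 0)] = PEAK_S129
    out["class"] = classes
    return out


# ---------------------------------------------------------------------------
# Promoter states and isoform selection

STATE_ACTIVE = "Active"
STATE_INACTIVE = "Inactive"
STATE_PRC = "PRC"
STATE_PRCA = "PRCa"

PROMOTER_MARKS = ("s5p", "s7p", "k27me3")


def promoter_state_classify(
    genes: pd.DataFrame, marks: tuple[str, ...] = PROMOTER_MARKS, percentile: float = 5.0
) -> pd.DataFrame:
    """Classify promoter states from mark overlap flags and TSS-window reads.

    ``genes`` needs, per mark M, columns ``M_overlap`` (bool: the 2-kb TSS
    window overlaps an enriched region) and ``M_reads`` (reads in the TSS
    window). Per mark, the read threshold is the 5th percentile of the reads
    of provisional positives (overlap only); final positives require overlap
    and reads >= threshold. States: Active = S5p+S7p+K27me3-;
    PRCa = S5p+S7p+K27me3+; PRC = K27me3+ & S7p-; all else Inactive.
    """
    out = genes.copy()
    flags = {}
    for mark in marks:
        overlap = genes[f"{mark}_overlap"].to_numpy(dtype=bool)
        reads = genes[f"{mark}_reads"].to_numpy(dtype=float)
        if overlap.sum() == 0:
            warnings.warn(f"no provisional positives for mark {mark!r}", stacklevel=2)
            flags[mark] = np.zeros(len(genes), dtype=bool)
            out[f"{mark}_threshold"] = np.nan
            continue
        threshold = np.percentile(reads[overlap], percentile)
        flags[mark] = overlap & (reads >= threshold)
        out[f"{mark}_threshold"] = threshold
        out[f"{mark}_positive"] = flags[mark]
    s5p, s7p, k27 = flags["s5p"], flags["s7p"], flags["k27me3"]
    state = np.array([STATE_INACTIVE] * len(genes), dtype=object)
    state[s5p & s7p & ~k27] = STATE_ACTIVE
    state[s5p & s7p & k27] = STATE_PRCA
    state[k27 & ~s7p] = STATE_PRC
    out["state"] = state
    return out


def select_isoform(isoforms: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """One isoform per gene: max TSS S5p reads, then S7p, then length, then
    a seeded random pick among exact ties."""
    rng = np.random.default_rng(seed)
    chosen = []
    for _, group in isoforms.groupby("gene", sort=False):
        for column in ("s5p", "s7p", "length"):
            best = group[column].max()
            group = group[group[column] == best]
            if len(group) == 1:
                break
        chosen.append(group.index[rng.integers(len(group))] if len(group) > 1 else group.index[0])
    return isoforms.loc[chosen].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Circular permutation test


def _merge_intervals(starts: np.ndarray, stops: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts)
    starts, stops = starts[order], stops[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, stops):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.array(merged_s), np.array(merged_e)


def _count_overlapping(
    f_starts: np.ndarray, f_stops: np.ndarray, t_starts: np.ndarray, t_stops: np.ndarray
) -> int:
    """Number of features overlapping any (merged, sorted) target interval."""
    if len(t_starts) == 0 or len(f_starts) == 0:
        return 0
    # feature [s, e) overlaps some target iff the first target with stop > s has start < e
    idx = np.searchsorted(t_stops, f_starts, side="right")
    ok = (idx < len(t_starts)) & (t_starts[np.minimum(idx, len(t_starts) - 1)] < f_stops)
    return int(ok.sum())


def _rotated_positions(starts, stops, offset, length):
    s = (starts + offset) % length
    e = s + (stops - starts)
    return s, e


def _overlap_statistic(features_by_chrom, targets_by_chrom, sizes, offsets) -> int:
    total = 0
    for chrom, (fs, fe) in features_by_chrom.items():
        length = sizes[chrom]
        ts, te = targets_by_chrom.get(chrom, (np.array([]), np.array([])))
        s, e = _rotated_positions(fs, fe, offsets.get(chrom, 0), length)
        wrap = e > length
        hit = np.zeros(len(s), dtype=bool)
        if len(ts):
            idx = np.searchsorted(te, s, side="right")
            hit |= (idx < len(ts)) & (ts[np.minimum(idx, len(ts) - 1)] < np.minimum(e, length))
            if wrap.any():
                s2 = np.zeros(int(wrap.sum()))
                e2 = e[wrap] - length
                idx2 = np.searchsorted(te, s2, side="right")
                hit2 = (idx2 < len(ts)) & (ts[np.minimum(idx2, len(ts) - 1)] < e2)
                hit[np.flatnonzero(wrap)] |= hit2
        total += int(hit.sum())
    return total


def circular_permutation_test(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n_permutations: int = 10_000,
    seed: int = 0,
    alternative: str = "enrichment",
    exhaustive_step: int | None = None,
) -> dict:
    """Circular-rotation null for feature/target interval overlap.

    Each permutation rotates all features of a chromosome by one uniform
    offset (wrapping at the chromosome end); the statistic is the number of
    features overlapping any target. ``exhaustive_step`` enumerates every
    offset in steps of that many bp instead of sampling (single-chromosome
    inputs only), giving an exact p-value without the add-one rule.
    """
    if len(features) == 0:
        raise DataIntegrityError("empty feature set")
    if n_permutations < 1:
        raise ConfigurationError("need at least one permutation")
    rng = np.random.default_rng(seed)

    def by_chrom(frame):
        out = {}
        for chrom, group in frame.groupby("chrom", sort=False):
            out[chrom] = (
                group["start"].to_numpy(dtype=float),
                group["stop"].to_numpy(dtype=float),
            )
        return out

    f_by = by_chrom(features)
    t_by = {c: _merge_intervals(s, e) for c, (s, e) in by_chrom(targets).items()}
    observed = _overlap_statistic(f_by, t_by, chrom_sizes, {})

    if exhaustive_step is not None:
        if len(f_by) != 1:
            raise ConfigurationError("exhaustive enumeration supports a single chromosome")
        chrom = next(iter(f_by))
        offsets = np.arange(0, chrom_sizes[chrom], exhaustive_step)
        null = np.array([
            _overlap_statistic(f_by, t_by, chrom_sizes, {chrom: off}) for off in offsets
        ])
        if alternative == "enrichment":
            p = float((null >= observed).mean())
        else:
            p = float((null <= observed).mean())
    else:
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            offsets = {c: rng.uniform(0, chrom_sizes[c]) for c in f_by}
            null[k] = _overlap_statistic(f_by, t_by, chrom_sizes, offsets)
        if alternative == "enrichment":
            p = (1 + int((null >= observed).sum())) / (1 + n_permutations)
        else:
            p = (1 + int((null <= observed).sum())) / (1 + n_permutations)
    return {
        "observed": observed,
        "pvalue": float(p),
        "null_mean": float(np.mean(null)),
        "null_sd": float(np.std(null)),
        "n_null": len(null),
    }


# ---------------------------------------------------------------------------
# Regulatory contact annotation

EP_MAX_DISTANCE = 2_000_000


def _window_has_feature(
    windows: pd.DataFrame, features: pd.DataFrame
) -> np.ndarray:
    """Per-window flag: does any feature interval overlap the window?"""
    flags = np.zeros(len(windows), dtype=bool)
    w = windows.reset_index(drop=True)
    for chrom, group in features.groupby("chrom", sort=False):
        sel = np.flatnonzero(w["chrom"].to_numpy() == chrom)
        if len(sel) == 0:
            continue
        ts, te = _merge_intervals(
            group["start"].to_numpy(dtype=float), group["stop"].to_numpy(dtype=float)
        )
        ws = w["start"].to_numpy(dtype=float)[sel]
        we = w["stop"].to_numpy(dtype=float)[sel]
        idx = np.searchsorted(te, ws, side="right")
        hit = (idx < len(ts)) & (ts[np.minimum(idx, len(ts) - 1)] < we)
        flags[sel] = hit
    return flags


def annotate_regulatory_contacts(
    contacts: pd.DataFrame,
    windows: pd.DataFrame,
    mode: str,
    genes: pd.DataFrame | None = None,
    peak_sets: dict[str, pd.DataFrame] | None = None,
    max_distance: int = EP_MAX_DISTANCE,
) -> pd.DataFrame:
    """Filter strong contacts down to putative regulatory pairs.

    EP mode: keep contacts <= 2 Mb where one anchor window holds an ASE gene
    TSS plus S5p and ATAC peaks and the other holds S5p, ATAC and H3K27ac
    peaks. CTCF-loop mode: both anchors hold CTCF and RAD21 peaks and carry
    convergent CTCF motifs (left anchor "+", right anchor "-"). Kept
    contacts are labelled by whether the contact's haplotype is the most- or
    least-expressed allele of the involved ASE gene (EP mode).

    Required ``peak_sets`` keys: EP -> ``s5p``, ``atac``, ``h3k27ac``;
    CTCF-loop -> ``ctcf`` (with a ``strand`` column), ``rad21``.
    """
    peak_sets = peak_sets or {}
    if mode == "EP":
        required = ("s5p", "atac", "h3k27ac")
    elif mode == "CTCF-loop":
        required = ("ctcf", "rad21")
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    missing = [k for k in required if k not in peak_sets]
    if missing:
        raise ConfigurationError(f"mode {mode}: missing peak sets {missing}")
    if mode == "EP" and genes is None:
        raise ConfigurationError("EP mode requires a gene table")

    out = contacts[contacts["distance"] <= max_distance].copy()
    i = out["window_i"].to_numpy(dtype=int)
    j = out["window_j"].to_numpy(dtype=int)

    if mode == "EP":
        ase = genes[genes["class"].isin([CLASS_CAST_ASE, CLASS_S129_ASE,
                                         CLASS_MONO_CAST, CLASS_MONO_S129])]
        tss = pd.DataFrame(
            {"chrom": ase["chrom"], "start": ase["tss"], "stop": ase["tss"] + 1}
        )
        has_tss = _window_has_feature(windows, tss)
        has_s5p = _window_has_feature(windows, peak_sets["s5p"])
        has_atac = _window_has_feature(windows, peak_sets["atac"])
        has_k27ac = _window_has_feature(windows, peak_sets["h3k27ac"])
        promoter = has_tss & has_s5p & has_atac
        enhancer = has_s5p & has_atac & has_k27ac
        keep = (promoter[i] & enhancer[j]) | (promoter[j] & enhancer[i])
        out = out[keep]
        i, j = i[keep], j[keep]
        # most-/least-expressed labelling per contact haplotype
        w = windows.reset_index(drop=True)
        gene_hap = {}
        for _, g in ase.iterrows():
            hit = (w["chrom"] == g["chrom"]) & (w["start"] <= g["tss"]) & (g["tss"] < w["stop"])
            for wi in np.flatnonzero(hit.to_numpy()):
                gene_hap[wi] = "cast" if "CAST" in g["class"] else "s129"
        labels = []
        for wi, wj, klass in zip(i, j, out["class"]):
            anchor = wi if wi in gene_hap else (wj if wj in gene_hap else None)
            if anchor is None:
                labels.append("")
                continue
            contact_hap = "cast" if "CAST" in str(klass) else "s129"
            labels.append(
                "most-expressed" if gene_hap[anchor] == contact_hap else "least-expressed"
            )
        out["allele_configuration"] = labels
        return out.reset_index(drop=True)

    # CTCF-loop mode
    ctcf = peak_sets["ctcf"]
    if "strand" not in ctcf.columns:
        raise ConfigurationError("CTCF peak set needs a strand column for motif orientation")
    has_ctcf = _window_has_feature(windows, ctcf)
    has_rad21 = _window_has_feature(windows, peak_sets["rad21"])
    plus = _window_has_feature(windows, ctcf[ctcf["strand"] == "+"])
    minus = _window_has_feature(windows, ctcf[ctcf["strand"] == "-"])
    anchors_ok = has_ctcf[i] & has_rad21[i] & has_ctcf[j] & has_rad21[j]
    convergent = plus[i] & minus[j]  # window_i is the left anchor (i < j)
    keep = anchors_ok & convergent
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Differential promoter methylation

METH_MIN_GENE_LENGTH = 2000
METH_PROMOTER_FLANK = 1000


def differential_methylation(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    percentile: float = 5.0,
    two_tailed: bool = True,
    min_gene_length: int = METH_MIN_GENE_LENGTH,
    flank: int = METH_PROMOTER_FLANK,
) -> pd.DataFrame:
    """Differentially methylated promoters from per-CpG per-allele tables.

    ``cpgs`` needs columns ``chrom``, ``pos``, ``cast_pct``, ``s129_pct``;
    ``genes`` needs ``gene``, ``chrom``, ``tss``, ``length``. Per allele a
    CpG is methylated iff its percentage exceeds 50. Per promoter
    (TSS +/- 1000 bp, genes > 2000 bp long) the methylated/unmethylated
    ratio is computed per allele; differential = S129 ratio - CAST ratio.
    Promoters in the extreme tail of |differential| (two-tailed default) are
    called, signed by direction.
    """
    rows = []
    for _, g in genes.iterrows():
        if g["length"] <= min_gene_length:
            rows.append((g["gene"], np.nan, np.nan, np.nan, "short-gene"))
            continue
        lo, hi = g["tss"] - flank, g["tss"] + flank
        local = cpgs[(cpgs["chrom"] == g["chrom"]) & (cpgs["pos"] >= lo) & (cpgs["pos"] < hi)]
        if len(local) == 0:
            rows.append((g["gene"], np.nan, np.nan, np.nan, "no-covered-cpgs"))
            continue
        ratios = {}
        for allele in ("cast", "s129"):
            meth = int((local[f"{allele}_pct"] > 50).sum())
            unmeth = len(local) - meth
            ratios[allele] = np.inf if unmeth == 0 else meth / unmeth
        diff = ratios["s129"] - ratios["cast"]
        if np.isinf(ratios["s129"]) and np.isinf(ratios["cast"]):
            diff = 0.0
        rows.append((g["gene"], ratios["cast"], ratios["s129"], diff, ""))
    out = pd.DataFrame(
        rows, columns=["gene", "cast_ratio", "s129_ratio", "differential", "exclude_reason"]
    )
    eligible = out["exclude_reason"] == ""
    diff = out.loc[eligible, "differential"].to_numpy(dtype=float)
    called = np.zeros(len(out), dtype=bool)
    if eligible.sum():
        if two_tailed:
            cutoff = np.percentile(np.abs(diff), 100 - percentile)
            hits = np.abs(diff) > cutoff
        else:
            cutoff = np.percentile(diff, 100 - percentile)
            hits = diff > cutoff
        called[np.flatnonzero(eligible.to_numpy())[hits]] = True
    out["called"] = called
    direction = np.array([""] * len(out), dtype=object)
    direction[called & (out["differential"] > 0).to_numpy()] = "S129-higher"
    direction[called & (out["differential"] < 0).to_numpy()] = "CAST-higher"
    out["direction"] = direction
    return out


# ---------------------------------------------------------------------------
# Cryosection allele quantification and feature co-occurrence


def cryofish_allele_fraction(section_counts) -> float:
    """Fraction of nuclear sections containing both alleles.

    ``section_counts`` holds, per section, the number of allele signals
    observed (1 or 2). Returns #(== 2) / #(>= 1).
    """
    counts = np.asarray(section_counts)
    if counts.size == 0:
        raise DataIntegrityError("empty section table")
    if not np.isin(counts, (1, 2)).all():
        raise DataIntegrityError("section allele counts must be 1 or 2")
    return float((counts == 2).sum()) / counts.size


def feature_cooccurrence(
    peak_sets: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    bin_size: int = 200_000,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-bin peak counts (200-kb bins)."""
    if len(peak_sets) < 2:
        raise DataIntegrityError("need at least 2 peak sets")
    edges = {}
    offset = 0
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_size))
        edges[chrom] = (offset, n_bins)
        offset += n_bins
    total_bins = offset
    vectors = {}
    for name, peaks in peak_sets.items():
        v = np.zeros(total_bins)
        for chrom, group in peaks.groupby("chrom", sort=False):
            if chrom not in edges:
                continue
            off, n_bins = edges[chrom]
            mids = (group["start"].to_numpy() + group["stop"].to_numpy()) // 2
            bins = np.clip(mids // bin_size, 0, n_bins - 1).astype(int)
            np.add.at(v, off + bins, 1)
        if v.sum() == 0:
            warnings.warn(f"peak set {name!r} has zero peaks", stacklevel=2)
        vectors[name] = v
    names = list(vectors)
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            va, vb = vectors[a], vectors[b]
            if va.sum() == 0 or vb.sum() == 0 or va.std() == 0 or vb.std() == 0:
                continue
            out.loc[a, b] = float(np.corrcoef(va, vb)[0, 1])
    return out
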