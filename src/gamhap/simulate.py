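"""Diploid nuclear-slicing simulator.

Generates GAM-like datasets from two haplotype genome models with planted
TAD, compartment, compaction and contact structure, by simulating thin-slab
sampling of spherical nuclei. Every simulated sample carries full ground
truth (per-haplotype capture flags), so downstream callers can be scored
against what was planted.

Geometry: the nucleus is a sphere of radius ``R``; each slice is a slab of
thickness ``h`` whose centre is drawn uniformly on ``[-R - h/2, R + h/2]``
along the sectioning axis. A locus (a sphere of radius ``r`` centred on the
window's 3D position) is captured iff it intersects the slab. For a locus
whose centre sits well inside the nucleus the capture probability over
random slabs is ``(2 r + h) / (2 R + h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError, CoverageTable, chromosome_codes, make_windows

HAPLOTYPES = ("cast", "s129")

#: Mean SNP density of the F123-like diploid model: one SNP per 124 bp.
DEFAULT_SNP_DENSITY = 1.0 / 124.0
DEFAULT_READ_LENGTH = 75


@dataclass
class HaplotypePlan:
    """Planted structure for one haplotype.

    ``tad_boundaries`` maps chromosome -> strictly increasing within-chromosome
    window indices (a boundary at index ``i`` starts a new TAD at window ``i``).
    ``compartment_labels`` maps chromosome -> per-100-kb-block labels ("A"/"B").
    ``radius_multipliers`` scales the per-window locus radius (compaction
    proxy; larger radius = more decondensed chromatin). ``None`` fields are
    drawn at random in :func:`build_genome_model`.
    """

    tad_boundaries: dict[str, np.ndarray] | None = None
    compartment_labels: dict[str, np.ndarray] | None = None
    radius_multipliers: np.ndarray | None = None


@dataclass
class SimConfig:
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    window_size: int = 50_000
    nucleus_radius: float = 1.0
    #: ~230 nm slab on a ~10 um diameter nucleus -> h/R = 0.23/5.
    slab_thickness: float = 0.046
    locus_radius: float = 0.04
    compartment_block_size: int = 100_000
    mean_tad_windows: int = 10
    snp_density: float = DEFAULT_SNP_DENSITY
    read_length: int = DEFAULT_READ_LENGTH
    tad_position_sigma: float = 0.18
    window_jitter_sigma: float = 0.05
    #: When set, place the A/B compartment anchors this far apart along the
    #: sectioning axis (strong, deterministic compartment contrast) instead of
    #: drawing both anchors at random.
    compartment_anchor_separation: float | None = None
    #: Planted long-range contacts: haplotype -> list of
    #: (chrom, (lo_a, hi_a), (lo_b, hi_b)) within-chromosome window ranges
    #: (half-open); block b is relocated next to block a for that haplotype.
    planted_contacts: dict[str, list[tuple]] = field(default_factory=dict)
    plans: dict[str, HaplotypePlan] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.window_size <= 0:
            raise ConfigurationError("window_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigurationError(f"chromosome {chrom!r} has non-positive length")
        if self.nucleus_radius <= 0 or self.locus_radius <= 0:
            raise ConfigurationError("nucleus and locus radii must be positive")
        if self.compartment_block_size % self.window_size not in (0,) and (
            self.window_size % self.compartment_block_size != 0
        ):
            raise ConfigurationError(
                "compartment block size must be commensurate with the window size"
            )


@dataclass
class SliceSpec:
    nucleus_radius: float = 1.0
    slab_thickness: float = 0.046
    slices_per_sample: int = 1

    def validate(self) -> None:
        if not 0 < self.slab_thickness < 2 * self.nucleus_radius:
            raise ConfigurationError(
                f"slab thickness {self.slab_thickness} must lie in (0, 2R)"
            )
        if self.slices_per_sample not in (1, 2, 3):
            raise ConfigurationError("slices per sample must be 1, 2 or 3 (NP multiplex mode)")


@dataclass
class GenomeModel:
    """Distributional diploid genome model.

    Chromatin conformation varies from cell to cell: the model stores the
    *plan* (TAD assignment, compartment labels, locus radii) and each sample
    draws a fresh 3D conformation via :func:`sample_conformation`. Windows in
    the same TAD share a per-cell random centre; TAD centres cluster around
    per-cell compartment anchors.
    """

    windows: pd.DataFrame
    window_size: int
    nucleus_radius: float
    tad_assignment: dict[str, np.ndarray]  # haplotype -> global TAD id per window
    tad_label: dict[str, np.ndarray]  # haplotype -> "A"/"B" per TAD id
    tad_chrom: dict[str, np.ndarray]  # haplotype -> chromosome code per TAD id
    radii: dict[str, np.ndarray]  # haplotype -> per-window locus radius
    tad_boundaries: dict[str, dict[str, np.ndarray]]
    compartment_labels: dict[str, np.ndarray]  # haplotype -> per-window "A"/"B"
    snp_counts: np.ndarray
    config: SimConfig

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def chrom_codes(self) -> np.ndarray:
        return chromosome_codes(self.windows)


@dataclass
class TruthBundle:
    """Ground truth emitted with every simulated dataset."""

    model: GenomeModel
    samples: list[str]
    captured: dict[str, np.ndarray]  # haplotype -> (n_samples, n_windows) bool
    seed: int

    @property
    def captured_any(self) -> np.ndarray:
        return self.captured["cast"] | self.captured["s129"]


def slab_capture_probability(r: float, R: float, h: float) -> float:
    """Closed-form capture probability for a well-centred locus sphere."""
    return (2.0 * r + h) / (2.0 * R + h)


def _random_boundaries(n_windows: int, mean_tad: int, rng: np.random.Generator) -> np.ndarray:
    sizes = []
    total = 0
    while total < n_windows:
        size = max(3, int(rng.poisson(mean_tad)))
        sizes.append(size)
        total += size
    bounds = np.cumsum(sizes)[:-1]
    return bounds[bounds < n_windows]

def _random_block_labels(n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    # Alternating A/B runs, geometric run lengths (mean 5 blocks = 500 kb).
    labels = np.empty(n_blocks, dtype="U1")
    label = "A" if rng.random() < 0.5 else "B"
    i = 0
    while i < n_blocks:
        run = 1 + rng.geometric(1.0 / 5.0)
        labels[i : i + run] = label
        label = "B" if label == "A" else "A"
        i += run
    return labels


def build_genome_model(config: SimConfig) -> GenomeModel:
    """Materialize a diploid genome model from per-haplotype structure plans.

    TAD assignments, compartment labels and locus radii are fixed here;
    3D positions are drawn per cell by :func:`sample_conformation`, so the
    two haplotypes differ in distribution exactly where their plans differ.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    windows = make_windows(config.chrom_sizes, config.window_size)
    n = len(windows)
    codes = chromosome_codes(windows)
    chroms = list(dict.fromkeys(windows["chrom"]))

    snp_counts = rng.poisson(config.window_size * config.snp_density, size=n)

    tad_assignment: dict[str, np.ndarray] = {}
    tad_label: dict[str, np.ndarray] = {}
    tad_chrom: dict[str, np.ndarray] = {}
    radii: dict[str, np.ndarray] = {}
    boundaries: dict[str, dict[str, np.ndarray]] = {}
    comp_labels: dict[str, np.ndarray] = {}

    block = config.compartment_block_size
    for hap in HAPLOTYPES:
        plan = config.plans.get(hap, HaplotypePlan())
        assignment = np.zeros(n, dtype=np.int64)
        hap_bounds: dict[str, np.ndarray] = {}
        labels = np.empty(n, dtype="U1")
        tad_labels: list[str] = []
        tad_chroms: list[int] = []
        next_tad = 0
        for ci, chrom in enumerate(chroms):
            idx = np.flatnonzero(codes == ci)
            n_chrom = len(idx)
            if plan.tad_boundaries is not None and chrom in plan.tad_boundaries:
                bounds = np.asarray(plan.tad_boundaries[chrom], dtype=np.int64)
                if len(bounds) and not (np.diff(bounds) > 0).all():
                    raise ConfigurationError("planted TAD boundaries must be strictly increasing")
            else:
                bounds = _random_boundaries(n_chrom, config.mean_tad_windows, rng)
            hap_bounds[chrom] = bounds

            starts = windows.loc[idx, "start"].to_numpy()
            block_ids = starts // block
            n_blocks = int(block_ids.max()) + 1
            if plan.compartment_labels is not None and chrom in plan.compartment_labels:
                block_labels = np.asarray(plan.compartment_labels[chrom], dtype="U1")
                if len(block_labels) < n_blocks:
                    raise ConfigurationError(
                        f"compartment plan for {chrom!r} covers {len(block_labels)} blocks, "
                        f"need {n_blocks}"
                    )
            else:
                block_labels = _random_block_labels(n_blocks, rng)
            labels[idx] = block_labels[block_ids]

            local_tad = np.searchsorted(bounds, np.arange(n_chrom), side="right")
            assignment[idx] = next_tad + local_tad
            for tid in range(int(local_tad.max()) + 1):
                members = idx[local_tad == tid]
                majority = "A" if (labels[members] == "A").sum() * 2 >= len(members) else "B"
                tad_labels.append(majority)
                tad_chroms.append(ci)
            next_tad += int(local_tad.max()) + 1

        # Planted long-range contacts: block b joins block a's TAD so the two
        # ranges share a centre in every cell of this haplotype.
        for chrom, (lo_a, hi_a), (lo_b, hi_b) in config.planted_contacts.get(hap, []):
            ci = chroms.index(chrom)
            idx = np.flatnonzero(codes == ci)
            assignment[idx[lo_b:hi_b]] = assignment[idx[lo_a]]

        tad_assignment[hap] = assignment
        tad_label[hap] = np.array(tad_labels, dtype="U1")
        tad_chrom[hap] = np.array(tad_chroms, dtype=np.int64)
        boundaries[hap] = hap_bounds
        comp_labels[hap] = labels

        mult = plan.radius_multipliers
        r = np.full(n, config.locus_radius)
        if mult is not None:
            mult = np.asarray(mult, dtype=float)
            if len(mult) != n:
                raise ConfigurationError("radius multiplier length must equal window count")
            r = r * mult
        if (r <= 0).any():
            raise ConfigurationError("locus radii must be positive")
        radii[hap] = r

    return GenomeModel(
        windows=windows,
        window_size=config.window_size,
        nucleus_radius=config.nucleus_radius,
        tad_assignment=tad_assignment,
        tad_label=tad_label,
        tad_chrom=tad_chrom,
        radii=radii,
        tad_boundaries=boundaries,
        compartment_labels=comp_labels,
        snp_counts=snp_counts,
        config=config,
    )


def sample_conformation(model: GenomeModel, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw one cell's 3D conformation per haplotype.

    Per chromosome and haplotype, A/B compartment anchors are drawn (or fixed
    along the sectioning axis when ``compartment_anchor_separation`` is set),
    TAD centres scatter around the anchor of their majority label, and
    windows jitter around their TAD centre. Points are pulled back inside
    0.85 R so the slab geometry stays valid.
    """
    config = model.config
    R = config.nucleus_radius
    out: dict[str, np.ndarray] = {}
    n_chroms = int(max(chrom.max() for chrom in model.tad_chrom.values())) + 1
    for hap in HAPLOTYPES:
        if config.compartment_anchor_separation is not None:
            sep = config.compartment_anchor_separation
            anchors = {
                "A": np.tile([0.0, 0.0, +sep / 2.0], (n_chroms, 1)),
                "B": np.tile([0.0, 0.0, -sep / 2.0], (n_chroms, 1)),
            }
        else:
            anchors = {
                "A": rng.normal(0.0, 0.3 * R, size=(n_chroms, 3)),
                "B": rng.normal(0.0, 0.3 * R, size=(n_chroms, 3)),
            }
        labels = model.tad_label[hap]
        chrom_of_tad = model.tad_chrom[hap]
        n_tads = len(labels)
        centres = np.where(
            (labels == "A")[:, None], anchors["A"][chrom_of_tad], anchors["B"][chrom_of_tad]
        ) + rng.normal(0.0, config.tad_position_sigma * R, size=(n_tads, 3))
        pos = centres[model.tad_assignment[hap]] + rng.normal(
            0.0, config.window_jitter_sigma * R, size=(model.n_windows, 3)
        )
        norms = np.linalg.norm(pos, axis=1)
        limit = 0.85 * R
        over = norms > limit
        pos[over] *= (limit / norms[over])[:, None]
        out[hap] = pos
    return out


@dataclass
class SliceCapture:
    """Capture state of one sample: boolean flags and graded intensity.

    ``intensity`` is the fraction of the locus sphere's diameter lying inside
    the slab (0 = missed, up to min(h, 2r)/2r for full inclusion), so loci
    grazed by the slab edge contribute proportionally less DNA.
    """

    captured: dict[str, np.ndarray]
    intensity: dict[str, np.ndarray]


def slice_nucleus(
    model: GenomeModel,
    spec: SliceSpec,
    rng: np.random.Generator,
    positions: dict[str, np.ndarray] | None = None,
) -> SliceCapture:
    """Capture flags/intensities for one sample (union over the sample's slices).

    A fresh per-cell conformation is drawn unless ``positions`` is given.
    """
    spec.validate()
    if positions is None:
        positions = sample_conformation(model, rng)
    R, h = spec.nucleus_radius, spec.slab_thickness
    intensity = {hap: np.zeros(model.n_windows) for hap in HAPLOTYPES}
    for _ in range(spec.slices_per_sample):
        z0 = rng.uniform(-R - h / 2.0, R + h / 2.0)
        for hap in HAPLOTYPES:
            z = positions[hap][:, 2]
            r = model.radii[hap]
            overlap = np.minimum(z + r, z0 + h / 2.0) - np.maximum(z - r, z0 - h / 2.0)
            frac = np.clip(overlap, 0.0, None) / (2.0 * r)
            intensity[hap] = np.maximum(intensity[hap], frac)
    captured = {hap: intensity[hap] > 0 for hap in HAPLOTYPES}
    return SliceCapture(captured=captured, intensity=intensity)


def simulate_sample_coverage(
    model: GenomeModel,
    capture: SliceCapture,
    depth: float,
    rng: np.random.Generator,
    background_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (total, cast, s129) nucleotide coverage for one sample.

    Each captured haplotype contributes Poisson(depth * capture intensity)
    coverage, so loci grazed by the slab edge yield shallow coverage. The
    SNP-informative share of a haplotype's coverage is binomially thinned
    with the per-window probability that a read overlaps at least one SNP
    (``1 - exp(-read_length * snp_count / window_size)``). Uncaptured windows
    receive only background coverage (unphased). ``cast + s129 <= total``
    holds by construction.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    n = model.n_windows
    density = model.snp_counts / model.window_size
    p_snp = 1.0 - np.exp(-model.config.read_length * density)

    per_hap = {}
    for hap in HAPLOTYPES:
        per_hap[hap] = rng.poisson(depth * capture.intensity[hap], size=n)
    background = rng.poisson(background_rate, size=n) if background_rate > 0 else np.zeros(n, dtype=np.int64)
    total = per_hap["cast"] + per_hap["s129"] + background
    cast = rng.binomial(per_hap["cast"], p_snp)
    s129 = rng.binomial(per_hap["s129"], p_snp)
    return total.astype(np.int64), cast.astype(np.int64), s129.astype(np.int64)


def emit_dataset(
    model: GenomeModel,
    spec: SliceSpec,
    n_samples: int,
    seed: int,
    depth: float = 80.0,
    background_rate: float = 0.0,
    out_dir: str | Path | None = None,
) -> tuple[CoverageTable, TruthBundle]:
    """Simulate ``n_samples`` exchangeable samples; deterministic given ``seed``."""
    if n_samples < 1:
        raise ConfigurationError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    table = CoverageTable(windows=model.windows)
    width = max(4, len(str(n_samples)))
    samples = [f"S{i + 1:0{width}d}" for i in range(n_samples)]
    captured = {hap: np.zeros((n_samples, model.n_windows), dtype=bool) for hap in HAPLOTYPES}
    for i, sample in enumerate(samples):
        capture = slice_nucleus(model, spec, rng)
        for hap in HAPLOTYPES:
            captured[hap][i] = capture.captured[hap]
        total, cast, s129 = simulate_sample_coverage(
            model, capture, depth, rng, background_rate=background_rate
        )
        table.add_sample(sample, total, cast, s129)
    truth = TruthBundle(model=model, samples=samples, captured=captured, seed=seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            table.to_tsv(out / "coverage.tsv")
            model.windows.to_csv(out / "windows.bed", sep="\t", index=False, header=False)
            for hap in HAPLOTYPES:
                truth_df = model.windows.copy()
                for i, sample in enumerate(samples):
                    truth_df[sample] = captured[hap][i].astype(int)
                truth_df.to_csv(out / f"truth_captured_{hap}.tsv", sep="\t", index=False)
            with open(out / "metadata.tsv", "w") as fh:
                fh.write("key\tvalue\n")
                fh.write(f"seed\t{seed}\n")
                fh.write(f"n_samples\t{n_samples}\n")
                fh.write(f"slices_per_sample\t{spec.slices_per_sample}\n")
                fh.write(f"depth\t{depth}\n")
                fh.write(f"background_rate\t{background_rate}\n")
        except OSError as exc:
            raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return table, truth
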