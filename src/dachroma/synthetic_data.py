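"""Ground-truth generators for every pipeline input.

The real study inputs — hybridized metaphase images, analyst score sheets,
RepeatMasker/CNV landscapes, ENCODE signal tracks, browser-assigned TADs —
are emulated here with known ground truth so that each pipeline stage has
a parameter-recovery test. Every generator is a pure function of its spec
and seed (byte-identical reruns).

Image regime presets: a "DA" batch draws true homolog intensity ratios
with median 0.8 and an "EA" batch with median 0.2, matching the scale of
quantified DA/EA medians reported for real metaphase cells (0.82 / 0.23)
without claiming to reproduce them from real images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval
from .gvf_quant import FishImage
from .probe_design import CnvRecord, RepeatElement
from .domain_tads import SignalTrack, TadSet, TAD_RESOLUTION

__all__ = [
    "ImageSpec",
    "ImageTruth",
    "ScoreTableSpec",
    "LandscapeSpec",
    "generate_fish_image",
    "generate_ratio_batch",
    "generate_cell_scores",
    "generate_repeat_landscape",
    "generate_signal_track",
    "generate_tads",
    "DA_PAIRS",
    "EA_PAIRS",
    "EXCLUDED_PAIRS_LIST",
]

# category pairs consistent with each call; the excluded list is exactly
# the scoring rule's exclusion set so generator and scorer agree by construction
DA_PAIRS = (("bright", "medium"), ("bright", "dim"), ("medium", "dim"), ("bright", "nil"))
EA_PAIRS = (("bright", "bright"), ("medium", "medium"))
EXCLUDED_PAIRS_LIST = (("dim", "dim"), ("nil", "nil"), ("dim", "nil"))


@dataclass
class ImageSpec:
    """A two-spot metaphase-FISH-like image.

    The spots carry exact integrated photon sums (S, rho*S) with an
    isotropic Gaussian profile of scale ``psf_sigma`` on a constant
    background; the true intensity ratio is (1-rho)/(1+rho).
    """

    shape: tuple[int, int] = (64, 64)
    spot_centers: tuple[tuple[float, float], tuple[float, float]] = ((22.0, 22.0), (42.0, 42.0))
    spot_sums: tuple[float, float] = (60_000.0, 30_000.0)
    psf_sigma: float = 2.0
    background_level: float = 100.0
    noise_model: str | tuple[str, float] = "poisson"
    seed: int = 0
    separation_floor: float = 5.0  # in units of psf_sigma

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if min(self.spot_sums) < 0:
            raise ValueError("spot sums must be >= 0")


@dataclass
class ImageTruth:
    centers: tuple[tuple[float, float], tuple[float, float]]
    sums: tuple[float, float]
    ratio: float


def generate_fish_image(spec: ImageSpec) -> tuple[FishImage, ImageTruth]:
    """Render the two-spot image described by ``spec``.

    Each spot's Gaussian profile is renormalized on the discrete grid so
    its pixel sum equals the specified photon sum exactly before noise.
    """
    (r1, c1), (r2, c2) = spec.spot_centers
    sep = np.hypot(r1 - r2, c1 - c2)
    if sep < spec.separation_floor * spec.psf_sigma:
        raise ValueError(
            f"spot centers {sep:.1f} px apart, below the separation floor "
            f"({spec.separation_floor} x psf_sigma)"
        )
    nrow, ncol = spec.shape
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    img = np.full(spec.shape, float(spec.background_level))
    for (r0, c0), total in zip(spec.spot_centers, spec.spot_sums):
        if total <= 0:
            continue
        prof = np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * spec.psf_sigma**2)))
        img += prof * (total / prof.sum())
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "poisson":
        img = rng.poisson(img).astype(float)
    elif spec.noise_model == "none":
        pass
    elif isinstance(spec.noise_model, tuple) and spec.noise_model[0] == "gaussian":
        img = np.clip(img + rng.normal(0.0, spec.noise_model[1], img.shape), 0, None)
    else:
        raise ValueError(f"unknown noise model: {spec.noise_model!r}")
    s1, s2 = spec.spot_sums
    true_ratio = abs(s1 - s2) / (s1 + s2) if (s1 + s2) > 0 else float("nan")
    return (
        FishImage(img, metadata={"seed": spec.seed}),
        ImageTruth(centers=spec.spot_centers, sums=spec.spot_sums, ratio=true_ratio),
    )


REGIME_MEDIANS = {"DA": 0.8, "EA": 0.2}
REGIME_SPREAD = {"DA": 0.2, "EA": 0.15}


def generate_ratio_batch(
    regime: str,
    n_cells: int,
    seed: int,
    total_photons: float = 60_000.0,
    shape: tuple[int, int] = (64, 64),
    margin: int = 14,
    min_separation: float = 18.0,
) -> list[tuple[FishImage, ImageTruth]]:
    """A batch of cells whose true ratios follow a DA- or EA-regime distribution.

    True ratios are drawn from a normal around the regime median (0.8 for
    DA, 0.2 for EA) clipped to [0, 0.98]; rho = (1-r)/(1+r) then splits the
    photon budget between the homolog spots. Spot centers are placed
    uniformly away from the border with a pairwise separation floor.
    """
    if regime not in REGIME_MEDIANS:
        raise ValueError(f"regime must be one of {sorted(REGIME_MEDIANS)}")
    rng = np.random.default_rng(seed)
    nrow, ncol = shape
    cells = []
    for i in range(n_cells):
        r = float(np.clip(rng.normal(REGIME_MEDIANS[regime], REGIME_SPREAD[regime]), 0.0, 0.98))
        rho = (1 - r) / (1 + r)
        s1 = total_photons / (1 + rho)
        s2 = s1 * rho
        while True:
            pts = rng.uniform([margin, margin], [nrow - margin, ncol - margin], size=(2, 2))
            if np.hypot(*(pts[0] - pts[1])) >= min_separation:
                break
        spec = ImageSpec(
            shape=shape,
            spot_centers=(tuple(pts[0]), tuple(pts[1])),
            spot_sums=(s1, s2),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cells.append(generate_fish_image(spec))
    return cells


@dataclass
class ScoreTableSpec:
    """Per-cell categorical score tables with a controllable DA probability."""

    probes: tuple[str, ...] = ("probe1",)
    samples_per_probe: int = 2
    cells_per_sample: int = 25
    p_da: float = 0.8
    p_excluded: float = 0.1
    tissue: str = "lymphocyte"
    category_mix: Optional[dict[tuple[str, str], float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_da, self.p_excluded):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.category_mix is not None:
            if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
                raise ValueError("category_mix must sum to 1")


def _draw_pair(rng, pairs, mix) -> tuple[str, str]:
    if mix:
        keys = [p for p in pairs if p in mix]
        w = np.array([mix[p] for p in keys], float)
        w = w / w.sum()
        pair = keys[rng.choice(len(keys), p=w)]
    else:
        pair = pairs[rng.integers(len(pairs))]
    return tuple(pair[::-1]) if rng.random() < 0.5 else pair  # homolog order is arbitrary


def generate_cell_scores(spec: ScoreTableSpec) -> pd.DataFrame:
    """Emit a cell-score table (probe, sample, tissue, cell, cat1, cat2, overlap).

    Per cell: EXCLUDED with probability ``p_excluded`` (drawing only from
    the excluded pair list), else DA-consistent with probability ``p_da``
    and EA-consistent otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for probe in spec.probes:
        for s in range(1, spec.samples_per_probe + 1):
            for c in range(1, spec.cells_per_sample + 1):
                u = rng.random()
                if u < spec.p_excluded:
                    pair = _draw_pair(rng, EXCLUDED_PAIRS_LIST, None)
                elif rng.random() < spec.p_da:
                    pair = _draw_pair(rng, DA_PAIRS, spec.category_mix)
                else:
                    pair = _draw_pair(rng, EA_PAIRS, spec.category_mix)
                rows.append(
                    {
                        "probe": probe,
                        "sample": f"{probe}_s{s}",
                        "tissue": spec.tissue,
                        "cell_id": f"{probe}_s{s}_c{c}",
                        "cat1": pair[0],
                        "cat2": pair[1],
                        "overlap_flag": False,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class LandscapeSpec:
    """A repeat/CNV landscape with planted single-copy runs.

    Outside the planted runs the region is tiled edge-to-edge with
    low-divergence repeats (divergence drawn below the 20% cutoff), so the
    planted runs are exactly the discoverable single-copy intervals.
    ``high_div_per_run`` sprinkles highly divergent (> 20%) repeats inside
    runs — they behave as unique sequence and must not break recovery.
    """

    chrom: str = "chrSim"
    length: int = 100_000
    planted_runs: tuple[tuple[int, int], ...] = ((20_001, 24_000), (60_001, 63_000))
    cnvs: tuple[tuple[int, int, float], ...] = ()
    tile_len: tuple[int, int] = (300, 2_000)
    divergence_low: tuple[float, float] = (1.0, 19.5)
    divergence_high: tuple[float, float] = (25.0, 40.0)
    high_div_per_run: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        runs = sorted(self.planted_runs)
        prev_end = 0
        for s, e in runs:
            if s <= prev_end or e < s or e > self.length:
                raise ValueError(f"bad planted run ({s}, {e})")
            prev_end = e


def generate_repeat_landscape(
    spec: LandscapeSpec,
) -> tuple[list[RepeatElement], list[CnvRecord], list[GenomicInterval]]:
    """(repeats, cnvs, true single-copy runs) for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    runs = [GenomicInterval(spec.chrom, s, e) for s, e in sorted(spec.planted_runs)]
    repeats: list[RepeatElement] = []
    families = ("Alu", "L1", "MIR", "LTR", "DNA")

    def tile(lo: int, hi: int) -> None:
        """Cover [lo, hi] inclusive with abutting low-divergence repeats."""
        pos = lo
        while pos <= hi:
            ln = int(rng.integers(spec.tile_len[0], spec.tile_len[1] + 1))
            end = min(pos + ln - 1, hi)
            repeats.append(
                RepeatElement(
                    GenomicInterval(spec.chrom, pos, end),
                    family=families[rng.integers(len(families))],
                    divergence=float(rng.uniform(*spec.divergence_low)),
                )
            )
            pos = end + 1

    cursor = 1
    for run in runs:
        if run.start > cursor:
            tile(cursor, run.start - 1)
        for _ in range(spec.high_div_per_run):
            span = run.end - run.start
            if span < 50:
                break
            ln = int(rng.integers(20, max(21, span // 4)))
            s = int(rng.integers(run.start, run.end - ln + 1))
            repeats.append(
                RepeatElement(
                    GenomicInterval(spec.chrom, s, s + ln),
                    family="L1_divergent",
                    divergence=float(rng.uniform(*spec.divergence_high)),
                )
            )
        cursor = run.end + 1
    if cursor <= spec.length:
        tile(cursor, spec.length)
    cnvs = [
        CnvRecord(GenomicInterval(spec.chrom, s, e), freq)
        for s, e, freq in spec.cnvs
    ]
    return repeats, cnvs, runs


def generate_signal_track(
    da_intervals: Sequence[GenomicInterval],
    ea_intervals: Sequence[GenomicInterval],
    mean_da: float = 1.0,
    mean_ea: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    da_outlier: Optional[tuple[int, float]] = None,
) -> SignalTrack:
    """Per-bp signal depleted over DA intervals relative to EA intervals.

    Each interval becomes one constant segment whose level is drawn around
    the group mean (clipped at 0). ``da_outlier=(index, factor)`` plants a
    promoter-like enrichment on one DA interval to exercise outlier
    flagging.
    """
    rng = np.random.default_rng(seed)
    segments = []
    for i, iv in enumerate(da_intervals):
        level = max(0.0, float(rng.normal(mean_da, noise_sd)))
        if da_outlier is not None and i == da_outlier[0]:
            level = mean_da * da_outlier[1]
        segments.append((iv, level))
    for iv in ea_intervals:
        segments.append((iv, max(0.0, float(rng.normal(mean_ea, noise_sd)))))
    return SignalTrack(segments=segments)


def reference_tad_topology() -> TadSet:
    """A synthetic TAD partition mimicking the reported interphase topology.

    Constructed (25 kb-aligned boundaries) so that the XDH, FGF6 and
    HMGB1P1 domain hulls sit mid-TAD, TPM1 and COX5A sit inside a TAD but
    approach one of its boundaries, and HMGB1P5 falls in an inter-TAD gap
    proximate to a boundary. This is a synthetic stand-in for
    browser-assigned Hi-C TAD calls, not measured data.
    """
    mk = GenomicInterval
    return TadSet(
        tads={
            "chr2": [mk("chr2", 31_400_000, 31_700_000)],
            "chr3": [mk("chr3", 22_000_000, 22_425_000), mk("chr3", 22_500_000, 22_900_000)],
            "chr12": [mk("chr12", 4_400_000, 4_700_000)],
            "chr15": [mk("chr15", 63_150_000, 63_375_000), mk("chr15", 75_125_000, 75_275_000)],
            "chr20": [mk("chr20", 55_900_000, 56_250_000)],
        },
        resolution=TAD_RESOLUTION,
    )


def generate_tads(
    chrom: str,
    length: int,
    boundaries: Optional[Sequence[int]] = None,
    gap_bp: int = 0,
    resolution: int = TAD_RESOLUTION,
    seed: int = 0,
) -> TadSet:
    """Disjoint TADs between successive boundaries.

    With ``boundaries=None`` a random partition is drawn at multiples of
    ``resolution``. ``gap_bp`` carves an inter-TAD gap centered on each
    internal boundary, so domains planted there classify as between TADs.
    """
    if boundaries is None:
        rng = np.random.default_rng(seed)
        n_bins = length // resolution
        k = max(2, int(rng.integers(2, max(3, n_bins // 8))))
        picks = sorted(rng.choice(np.arange(1, n_bins), size=min(k, n_bins - 1), replace=False))
        boundaries = [1] + [int(b) * resolution for b in picks] + [length]
    bounds = sorted(int(b) for b in boundaries)
    if bounds[0] < 1 or bounds[-1] > length or len(bounds) < 2:
        raise ValueError("boundaries must lie within [1, length] with >= 2 entries")
    half = gap_bp // 2
    tads = []
    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        s = lo if i == 0 else lo + half
        e = hi if i == len(bounds) - 2 else hi - half
        if e > s:
            tads.append(GenomicInterval(chrom, s, e))
    return TadSet(tads={chrom: tads}, resolution=resolution)
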