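"""DA domain aggregation, chromatin-mark integration and TAD overlap.

Adjacent single-copy probes that score concordantly DA constitute a
chromosomal DA domain, bounded by the smallest and largest coordinates of
the two maximally separated member probes and inferred contiguous between
them. Domains are compared with interphase structure two ways: cumulative
open-chromatin signal (DNase I HS, FAIRE, histone marks) integrated over
DA vs EA intervals, and overlap classification against precomputed
topologically associated domain (TAD) partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import da_stats
from .genomic_core import (
    GenomicInterval,
    IntervalContractError,
    ScProbe,
    gap_between,
    hull,
    kb_text,
    overlap_length,
    span_length,
)

__all__ = [
    "DaDomain",
    "DomainReport",
    "SignalTrack",
    "TadSet",
    "GeneModel",
    "MarkComparison",
    "build_domains",
    "domain_report",
    "name_probe",
    "integrate_track",
    "compare_marks",
    "classify_tad_overlap",
    "TAD_RESOLUTION",
]

TAD_RESOLUTION = 25_000  # bp; contact maps were binned at 25 kb


@dataclass
class DaDomain:
    """A maximal run of >= 2 adjacent concordant-DA probes at one locus."""

    name: str
    probes: list[ScProbe]
    hull: GenomicInterval
    gaps: list[int]
    combined_target_length: int

    def __post_init__(self) -> None:
        if len(self.probes) < 2:
            raise ValueError("a DA domain needs at least 2 probes")
        chroms = {p.interval.chrom for p in self.probes}
        if len(chroms) != 1:
            raise ValueError("domain probes must share a chromosome")


@dataclass
class SignalTrack:
    """Piecewise-constant genomic signal: (interval, value >= 0) segments."""

    segments: list[tuple[GenomicInterval, float]]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv, val in self.segments:
            if val < 0:
                raise ValueError("signal values must be >= 0")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                # segments may abut (a.end == b.start) under the end-start
                # length convention without double counting
                if b.start < a.end:
                    raise ValueError(f"overlapping track segments: {a} and {b}")


@dataclass
class TadSet:
    """Ordered disjoint TAD intervals per chromosome."""

    tads: dict[str, list[GenomicInterval]]
    resolution: int = TAD_RESOLUTION

    def __post_init__(self) -> None:
        for chrom, ivs in self.tads.items():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                # abutting TADs (b.start == a.end) are disjoint under the
                # end-start length convention
                if b.start < a.end:
                    raise ValueError(f"overlapping TADs on {chrom}: {a}, {b}")


@dataclass
class GeneModel:
    """Minimal gene annotation for probe naming.

    ``introns`` maps the intron number (IVS index) to its interval;
    ``centromere`` is the chromosome's centromere position, which decides
    whether an intergenic probe is centromeric or telomeric of the gene.
    """

    name: str
    interval: GenomicInterval
    introns: dict[int, GenomicInterval] = field(default_factory=dict)


def build_domains(
    probes: Sequence[ScProbe],
    max_gap_warn: Optional[int] = None,
) -> tuple[list[DaDomain], list[ScProbe]]:
    """Aggregate classified probes into DA domains.

    Probes are grouped per (chromosome, locus) — a locus is the analyzed
    probe neighborhood around one anchor — and sorted by coordinate.
    Maximal runs of consecutive DA probes with no interspersed EA probe
    and at least two members become domains, named after their locus.
    Singleton DA probes are returned separately, not as domains.
    ``max_gap_warn`` emits a warning (never a split) for intra-domain gaps
    above the given bp size.
    """
    for p in probes:
        if p.call not in ("DA", "EA"):
            raise ValueError(f"probe {p.name} has no DA/EA call")
    groups: dict[tuple[str, str], list[ScProbe]] = {}
    for p in probes:
        key = (p.interval.chrom, p.locus or "")
        groups.setdefault(key, []).append(p)
    domains: list[DaDomain] = []
    singletons: list[ScProbe] = []
    for (chrom, locus), members in sorted(groups.items()):
        members.sort(key=lambda p: (p.interval.start, p.interval.end))
        for a, b in zip(members, members[1:]):
            if b.interval.start <= a.interval.end:
                raise IntervalContractError(
                    f"overlapping probes {a.name} and {b.name}"
                )
        run: list[ScProbe] = []
        for p in members + [None]:  # sentinel flushes the last run
            if p is not None and p.call == "DA":
                run.append(p)
                continue
            if len(run) >= 2:
                ivs = [q.interval for q in run]
                gaps = [gap_between(x, y) for x, y in zip(ivs, ivs[1:])]
                if max_gap_warn is not None and any(g > max_gap_warn for g in gaps):
                    warnings.warn(
                        f"domain {locus or chrom}: intra-domain gap exceeds "
                        f"{max_gap_warn} bp",
                        stacklevel=2,
                    )
                domains.append(
                    DaDomain(
                        name=locus or f"{chrom}:{ivs[0].start}",
                        probes=list(run),
                        hull=hull(ivs),
                        gaps=gaps,
                        combined_target_length=sum(span_length(iv) for iv in ivs),
                    )
                )
            elif len(run) == 1:
                singletons.append(run[0])
            run = []
    return domains, singletons


@dataclass
class DomainReport:
    name: str
    n_probes: int
    span_bp: int
    gaps_bp: list[int]
    combined_target_length_bp: int
    span_kb: str
    gaps_kb: list[str]
    combined_target_length_kb: str


def domain_report(domain: DaDomain) -> DomainReport:
    """Span, gap and combined-target-length arithmetic with kb strings."""
    span = span_length(domain.hull)
    return DomainReport(
        name=domain.name,
        n_probes=len(domain.probes),
        span_bp=span,
        gaps_bp=list(domain.gaps),
        combined_target_length_bp=domain.combined_target_length,
        span_kb=kb_text(span, 3),
        gaps_kb=[kb_text(g, 1) for g in domain.gaps],
        combined_target_length_kb=kb_text(domain.combined_target_length, 1),
    )


def name_probe(
    interval: GenomicInterval,
    genes: Sequence[GeneModel],
    centromere: int,
) -> str:
    """Name a probe interval after its host or nearest gene.

    Genic probes (interval within a gene) are named GENE_IVSx[-IVSy] from
    the introns they overlap, listed in ascending genomic coordinate order
    (so minus-strand genes print descending intron numbers). Intergenic
    probes are named GENE_cen<d> or GENE_tel<d>: the nearest gene on the
    chromosome, "cen"/"tel" saying whether the probe lies on the
    centromeric or telomeric side of that gene, and d the bp distance
    between gene boundary and interval.
    """
    same_chrom = [g for g in genes if g.interval.chrom == interval.chrom]
    if not same_chrom:
        raise ValueError(f"no gene annotation on {interval.chrom}")
    host = next((g for g in same_chrom if g.interval.contains(interval)), None)
    if host is not None:
        hit = sorted(
            (iv.start, num)
            for num, iv in host.introns.items()
            if iv.overlaps(interval)
        )
        if not hit:
            raise ValueError(
                f"probe inside {host.name} overlaps no annotated intron"
            )
        first, last = hit[0][1], hit[-1][1]
        ivs = f"IVS{first}" if first == last else f"IVS{first}-IVS{last}"
        return f"{host.name}_{ivs}"

    def distance(g: GeneModel) -> int:
        if interval.end < g.interval.start:
            return g.interval.start - interval.end
        if g.interval.end < interval.start:
            return interval.start - g.interval.end
        return 0  # abutting/partial overlap without containment

    nearest = min(same_chrom, key=distance)
    d = distance(nearest)
    probe_mid = (interval.start + interval.end) / 2
    gene_mid = (nearest.interval.start + nearest.interval.end) / 2
    # "cen" when the probe sits on the same side of the gene as the centromere
    side_cen = (probe_mid - gene_mid) * (centromere - gene_mid) > 0
    tag = "cen" if side_cen else "tel"
    return f"{nearest.name}_{tag}{d}"


def integrate_track(
    track: SignalTrack, interval: GenomicInterval
) -> tuple[float, float]:
    """(cumulative signal, per-bp mean) of a track over an interval.

    Cumulative = sum over overlapping segments of value × overlap length
    (internal end−start convention); uncovered bases contribute 0. The
    per-bp mean divides by the interval span.
    """
    total = 0.0
    for seg_iv, val in track.segments:
        total += val * overlap_length(seg_iv, interval)
    span = span_length(interval)
    return total, (total / span if span > 0 else 0.0)


@dataclass
class MarkComparison:
    """Welch comparison of one open-chromatin mark between DA and EA intervals."""

    test: da_stats.TestResult
    da_mean: float
    ea_mean: float
    flagged: list[str]
    censored: list[str]


def compare_marks(
    da_values: Mapping[str, float],
    ea_values: Mapping[str, float],
    outlier_factor: float = 10.0,
    censor_outliers: bool = False,
    alpha: float = 0.05,
) -> MarkComparison:
    """Compare integrated-intensity values of a mark between DA and EA groups.

    Values larger than ``outlier_factor`` times their group median are
    flagged (a promoter-like interval swamping the group mean). Flagged DA
    or EA intervals are removed before testing only when
    ``censor_outliers`` is set, and the censored ids are reported — the
    exclusion is always explicit, never silent.
    """
    if len(da_values) < 2 or len(ea_values) < 2:
        raise ValueError("need >= 2 intervals per group")

    def flag(values: Mapping[str, float]) -> list[str]:
        med = float(np.median(list(values.values())))
        if med <= 0:
            return []
        return [k for k, v in values.items() if v > outlier_factor * med]

    flagged = flag(da_values) + flag(ea_values)
    censored: list[str] = []
    da_use, ea_use = dict(da_values), dict(ea_values)
    if censor_outliers:
        for k in flagged:
            da_use.pop(k, None)
            ea_use.pop(k, None)
        censored = list(flagged)
    test = da_stats.welch_t(list(da_use.values()), list(ea_use.values()), alpha=alpha)
    return MarkComparison(
        test=test,
        da_mean=float(np.mean(list(da_use.values()))),
        ea_mean=float(np.mean(list(ea_use.values()))),
        flagged=flagged,
        censored=censored,
    )


TAD_LABELS = ("within", "within_boundary_proximal", "spans_boundary", "between_tads")


def classify_tad_overlap(
    domain: DaDomain | GenomicInterval,
    tads: TadSet,
    boundary_window: Optional[int] = None,
) -> str:
    """Relation of a DA domain's hull to a TAD partition.

    within                    fully inside one TAD, > boundary_window from
                              both its edges
    within_boundary_proximal  fully inside one TAD but approaching an edge
    spans_boundary            crosses a TAD edge (overlaps >= 2 TADs, or
                              sticks out of its single TAD)
    between_tads              overlaps no TAD
    The window defaults to the TAD resolution (25 kb).
    """
    hull_iv = domain.hull if isinstance(domain, DaDomain) else domain
    window = boundary_window if boundary_window is not None else tads.resolution
    hits = [
        t
        for t in tads.tads.get(hull_iv.chrom, [])
        if overlap_length(t, hull_iv) > 0
    ]
    if not hits:
        return "between_tads"
    if len(hits) > 1:
        return "spans_boundary"
    tad = hits[0]
    if not tad.contains(hull_iv):
        return "spans_boundary"
    margin = min(hull_iv.start - tad.start, tad.end - hull_iv.end)
    return "within" if margin > window else "within_boundary_proximal"
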