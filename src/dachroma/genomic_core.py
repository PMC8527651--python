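"""Genomic interval model and tabular/BED I/O.

All coordinates are held internally as 1-based inclusive positions on a
named chromosome (the convention of the published probe tables this package
consumes). Interval length is computed as ``end - start``: that convention
reproduces every bracketed domain length in the source probe table, and is
applied uniformly to probe lengths, gaps and track overlaps. BED files on
disk keep their native 0-based half-open convention and are converted on
read/write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "ScProbe",
    "RegionParseError",
    "IntervalContractError",
    "BedFormatError",
    "parse_region",
    "span_length",
    "gap_between",
    "hull",
    "overlap_length",
    "kb_text",
    "read_probe_table",
    "write_probe_table",
    "read_bed",
    "write_bed",
    "load_scfish_probes",
]


class RegionParseError(ValueError):
    """A coordinate string could not be parsed; names the offending token."""


class IntervalContractError(ValueError):
    """An interval operation was called with arguments violating its contract."""


class BedFormatError(ValueError):
    """A BED file violated the expected column layout or coordinate ranges."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome segment, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalContractError("chrom must be non-empty")
        if self.start < 1:
            raise IntervalContractError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise IntervalContractError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ScProbe:
    """A named single-copy FISH probe interval.

    ``position_class`` is "genic" when the probe target lies within a gene
    (exons and introns) and "intergenic" otherwise. ``anchor`` marks the
    first probe at a locus confirmed to show differential accessibility,
    from which neighboring probes were designed. ``locus`` groups probes
    belonging to the same targeted chromosomal region (the anchor
    neighborhood); ``call`` optionally carries the probe-level DA/EA
    classification.
    """

    name: str
    interval: GenomicInterval
    position_class: str = "intergenic"
    anchor: bool = False
    locus: Optional[str] = None
    call: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position_class not in ("genic", "intergenic"):
            raise ValueError(
                f"position_class must be 'genic' or 'intergenic', "
                f"got {self.position_class!r}"
            )
        if self.call is not None and self.call not in ("DA", "EA"):
            raise ValueError(f"call must be 'DA', 'EA' or None, got {self.call!r}")


# coordinate strings in published tables mix hyphens, en/em dashes,
# thousands separators and stray whitespace
_DASHES = "‐‑‒–—−"
_REGION_RE = re.compile(
    rf"^\s*(?P<chrom>[^:\s]+)\s*:\s*(?P<start>[\d,]+)\s*[-{_DASHES}]\s*(?P<end>[\d,]+)\s*$"
)


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (hyphen or dash, optional thousands commas)."""
    m = _REGION_RE.match(text)
    if m is None:
        raise RegionParseError(f"cannot parse region string: {text!r}")
    chrom = m.group("chrom")
    try:
        start = int(m.group("start").replace(",", ""))
        end = int(m.group("end").replace(",", ""))
    except ValueError as exc:  # pragma: no cover - regex restricts to digits
        raise RegionParseError(f"bad coordinate in {text!r}") from exc
    if start > end:
        raise RegionParseError(
            f"start > end in {text!r} ({start} > {end})"
        )
    return GenomicInterval(chrom, start, end)


def span_length(a: GenomicInterval) -> int:
    """Interval length as ``end - start`` (the probe-table convention)."""
    return a.end - a.start


def gap_between(a: GenomicInterval, b: GenomicInterval) -> int:
    """Distance ``b.start - a.end`` between two ordered disjoint intervals."""
    if a.chrom != b.chrom:
        raise IntervalContractError(
            f"gap_between requires one chromosome, got {a.chrom} and {b.chrom}"
        )
    if a.end >= b.start:
        raise IntervalContractError(
            f"gap_between requires a.end < b.start, got a.end={a.end}, b.start={b.start}"
        )
    return b.start - a.end


def hull(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Smallest interval covering all inputs (one chromosome)."""
    ivs = list(intervals)
    if not ivs:
        raise IntervalContractError("hull of empty interval set")
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) != 1:
        raise IntervalContractError(f"hull across chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
    )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in the internal length convention (min end − max start, floored at 0)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def kb_text(bp: int, decimals: int = 1) -> str:
    """Format a bp count in kb, rounding half-up to the requested decimals.

    Half-up (not banker's) rounding is what reproduces printed figures such
    as 82,850 bp -> "82.9" and 12,195 bp -> "12.2".
    """
    q = Decimal(1).scaleb(-decimals)
    return str((Decimal(bp) / Decimal(1000)).quantize(q, rounding=ROUND_HALF_UP))


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}

_PROBE_COLUMNS = ("name", "region", "position_class", "anchor")
_OPTIONAL_COLUMNS = ("call", "locus")

_MAX_COORD = 2**40  # far beyond any chromosome; guards corrupt input


def read_probe_table(path) -> list[ScProbe]:
    """Read a tab-separated probe table.

    Required columns: name, region, position_class, anchor. Optional:
    call (DA/EA), locus. An empty file (header only or zero bytes) yields
    an empty list.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise BedFormatError(f"probe table missing columns: {missing}")
    unknown = [
        c for c in df.columns if c not in _PROBE_COLUMNS + _OPTIONAL_COLUMNS
    ]
    if unknown:
        raise BedFormatError(f"probe table has unknown columns: {unknown}")
    probes = []
    seen = set()
    for row in df.itertuples(index=False):
        name = row.name
        if name in seen:
            raise BedFormatError(f"duplicate probe name: {name}")
        seen.add(name)
        interval = parse_region(row.region)
        anchor = _BOOL_MAP.get(str(row.anchor).strip().lower())
        if anchor is None:
            raise BedFormatError(f"bad anchor flag for {name}: {row.anchor!r}")
        call = getattr(row, "call", None)
        if call is not None and (pd.isna(call) or call in (".", "")):
            call = None
        locus = getattr(row, "locus", None)
        if locus is not None and (pd.isna(locus) or locus in (".", "")):
            locus = None
        probes.append(
            ScProbe(
                name=name,
                interval=interval,
                position_class=row.position_class,
                anchor=anchor,
                locus=locus,
                call=call,
            )
        )
    return probes


def write_probe_table(probes: Sequence[ScProbe], path) -> None:
    rows = [
        {
            "name": p.name,
            "region": f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}",
            "position_class": p.position_class,
            "anchor": str(p.anchor).lower(),
            "call": p.call or ".",
            "locus": p.locus or ".",
        }
        for p in probes
    ]
    pd.DataFrame(rows, columns=list(_PROBE_COLUMNS) + list(_OPTIONAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


_BED_EXTRA_NAMES = ("name", "score", "strand")


def read_bed(path, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with internal 1-based inclusive coords.

    Columns beyond chrom/start/end are taken from ``extra_columns`` if
    given (e.g. ``("family", "divergence")`` for a RepeatMasker-style BED,
    ``("frequency",)`` for a CNV BED), else from the BED6 names
    name/score/strand. Surplus columns raise :class:`BedFormatError`.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", *extra_columns])
    if raw.shape[1] < 3:
        raise BedFormatError(f"BED needs >= 3 columns, got {raw.shape[1]}")
    n_extra = raw.shape[1] - 3
    extras = list(extra_columns) if extra_columns else list(_BED_EXTRA_NAMES[:n_extra])
    if n_extra > len(extras):
        raise BedFormatError(
            f"BED has {n_extra} extra columns but only {len(extras)} are named"
        )
    raw.columns = ["chrom", "start", "end", *extras][: raw.shape[1]]
    df = raw.copy()
    df["start"] = df["start"].astype("int64") + 1  # 0-based half-open -> 1-based incl.
    df["end"] = df["end"].astype("int64")
    if (df["start"] < 1).any() or (df["end"] > _MAX_COORD).any():
        raise BedFormatError("BED coordinates out of range")
    if (df["end"] < df["start"] - 1).any():
        raise BedFormatError("BED end < start")
    for col in extras:
        if col not in df.columns:
            df[col] = pd.NA
        else:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    return df


def bed_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    """Intervals from a frame produced by :func:`read_bed`."""
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED3 (converted back to 0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def load_scfish_probes() -> list[ScProbe]:
    """The packaged set of 19 curated scFISH probes (GRCh37).

    Eighteen probes across six differential-accessibility loci plus one
    singleton tissue-study probe, together with the 1p36 equivalent-
    accessibility control; coordinates, genic/intergenic annotation,
    anchor flags, DA/EA calls and locus grouping are included.
    """
    ref = resources.files("dachroma").joinpath("data/scfish_probes_grch37.tsv")
    with resources.as_file(ref) as path:
        return read_probe_table(path)
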