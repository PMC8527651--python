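"""Single-copy probe interval discovery and primer-pair evaluation.

Single-copy (sc) FISH probes must target sequence that hybridizes to one
genomic location. Candidate intervals are the maximal stretches of a region
free of repetitive elements whose divergence from their family consensus is
below 20% — highly divergent repeats (> 20%) behave as unique targets and
do not disqualify a stretch. Candidates overlapping common copy-number
variants (population frequency >= 1%) are excluded, and probes inside genes
are restricted to transcriptionally inert genes (<= 5 TPM in every tissue
under study). Primer pairs amplifying a candidate are screened against
melting-temperature, Tm-difference and product-size windows (hard rules)
and GC-content / primer-length preferences (soft rank terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .genomic_core import GenomicInterval, IntervalContractError, overlap_length

__all__ = [
    "RepeatElement",
    "CnvRecord",
    "PrimerPair",
    "ExpressionRecord",
    "ScCandidate",
    "PrimerReport",
    "find_sc_intervals",
    "filter_cnv",
    "filter_expression",
    "gc_content",
    "melting_temperature",
    "self_complementarity",
    "evaluate_primer_pair",
    "DIVERGENCE_CUTOFF",
    "CNV_FREQUENCY_CUTOFF",
    "MAX_TPM",
]

DIVERGENCE_CUTOFF = 20.0   # % divergence below which a repeat masks sequence
CNV_FREQUENCY_CUTOFF = 0.01
MAX_TPM = 5.0
MIN_PROBE_LEN = 1400       # bp, probes run ~1.4-4 kb
MAX_PROBE_LEN = 4000


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    family: str
    divergence: float  # percent divergence from the family consensus

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 100.0:
            raise ValueError(f"divergence must be in [0, 100], got {self.divergence}")


@dataclass(frozen=True)
class CnvRecord:
    interval: GenomicInterval
    population_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError(
                f"population_frequency must be in [0, 1], got {self.population_frequency}"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    tissue: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"tpm must be >= 0, got {self.tpm}")


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_length: int
    self_complementarity: float = 0.0

    def __post_init__(self) -> None:
        for seq in (self.forward_seq, self.reverse_seq):
            _validate_dna(seq)
        if self.product_length <= 0:
            raise ValueError("product_length must be > 0")


@dataclass(frozen=True)
class ScCandidate:
    """A repeat-free run; ``exceeds_max`` flags runs longer than the probe cap."""

    interval: GenomicInterval
    exceeds_max: bool = False

    @property
    def length(self) -> int:
        return self.interval.end - self.interval.start


def find_sc_intervals(
    repeats: Sequence[RepeatElement],
    region: GenomicInterval,
    min_len: int = MIN_PROBE_LEN,
    max_len: int = MAX_PROBE_LEN,
    divergence_cutoff: float = DIVERGENCE_CUTOFF,
) -> list[ScCandidate]:
    """Maximal sub-intervals of ``region`` free of low-divergence repeats.

    Repeats with divergence >= ``divergence_cutoff`` are ignored (they act
    as unique sequence). Runs shorter than ``min_len`` (in the internal
    end−start convention) are dropped; runs longer than ``max_len`` are
    returned whole with ``exceeds_max=True`` — trimming to probe size is a
    reporting concern.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    masking = []
    for rep in repeats:
        if rep.interval.chrom != region.chrom:
            raise IntervalContractError(
                f"repeat on {rep.interval.chrom} but region on {region.chrom}"
            )
        if rep.divergence < divergence_cutoff and rep.interval.overlaps(region):
            masking.append(
                (max(rep.interval.start, region.start), min(rep.interval.end, region.end))
            )
    masking.sort()
    # merge masked intervals, then take the complementary runs
    merged: list[list[int]] = []
    for s, e in masking:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    runs: list[GenomicInterval] = []
    cursor = region.start
    for s, e in merged:
        if s > cursor:
            runs.append(GenomicInterval(region.chrom, cursor, s - 1))
        cursor = e + 1
    if cursor <= region.end:
        runs.append(GenomicInterval(region.chrom, cursor, region.end))
    return [
        ScCandidate(run, exceeds_max=(run.end - run.start) > max_len)
        for run in runs
        if (run.end - run.start) >= min_len
    ]


def filter_cnv(
    candidates: Iterable[GenomicInterval],
    cnvs: Sequence[CnvRecord],
    freq_threshold: float = CNV_FREQUENCY_CUTOFF,
) -> list[GenomicInterval]:
    """Drop candidates overlapping any CNV at or above the frequency threshold."""
    hot = [c.interval for c in cnvs if c.population_frequency >= freq_threshold]
    return [
        cand
        for cand in candidates
        if not any(cand.overlaps(h) for h in hot)
    ]


def filter_expression(
    probes: Sequence,
    expression: Sequence[ExpressionRecord] | pd.DataFrame,
    max_tpm: float = MAX_TPM,
    gene_of: Optional[Mapping[str, str]] = None,
) -> list:
    """Keep probes whose gene is inert (tpm <= max_tpm in every tissue).

    Intergenic probes pass unconditionally. Genic probes map to a gene via
    ``gene_of`` (probe name -> gene) or, by default, the token before the
    first underscore of the probe name. A genic probe whose gene has no
    expression rows is an error rather than a silent keep.
    """
    if isinstance(expression, pd.DataFrame):
        records = [
            ExpressionRecord(r.gene, r.tissue, float(r.tpm))
            for r in expression.itertuples(index=False)
        ]
    else:
        records = list(expression)
    by_gene: dict[str, list[float]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec.tpm)
    kept = []
    for probe in probes:
        if probe.position_class == "intergenic":
            kept.append(probe)
            continue
        gene = gene_of[probe.name] if gene_of else probe.name.split("_")[0]
        if gene not in by_gene:
            raise KeyError(f"no expression rows for gene {gene!r} (probe {probe.name})")
        if max(by_gene[gene]) <= max_tpm:
            kept.append(probe)
    return kept


_DNA = set("ACGT")


def _validate_dna(seq: str) -> None:
    if not seq:
        raise ValueError("empty DNA sequence")
    bad = set(seq.upper()) - _DNA
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


def gc_content(seq: str) -> float:
    """Fraction of G or C bases."""
    _validate_dna(seq)
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def melting_temperature(
    seq: str,
    method: str = "nearest-neighbor",
    na_mM: float = 50.0,
    primer_nM: float = 500.0,
) -> float:
    """Primer melting temperature in degrees Celsius.

    The default is unified nearest-neighbor thermodynamics (SantaLucia 1998
    parameter set) at 50 mM monovalent salt and 500 nM total primer,
    computed through Biopython. ``method="wallace"`` gives the 2+4 rule for
    quick sanity checks.
    """
    _validate_dna(seq)
    s = seq.upper()
    if method == "nearest-neighbor":
        return float(
            _mt.Tm_NN(
                s,
                nn_table=_mt.DNA_NN3,  # SantaLucia 1998 unified parameters
                Na=na_mM,
                dnac1=primer_nM / 2,
                dnac2=primer_nM / 2,
                saltcorr=5,
            )
        )
    if method == "wallace":
        return float(_mt.Tm_Wallace(s))
    raise ValueError(f"unknown Tm method: {method!r}")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def self_complementarity(seq: str) -> int:
    """Max Watson–Crick matches over ungapped self-alignments.

    The sequence is slid against its own reverse complement at every
    offset; the score is the largest number of positions at which the two
    agree (i.e. at which the original base pairs with the base it faces).
    """
    _validate_dna(seq)
    s = seq.upper()
    rc = s.translate(_COMPLEMENT)[::-1]
    n = len(s)
    best = 0
    for offset in range(-(n - 1), n):
        matches = sum(
            1
            for i in range(max(0, offset), min(n, n + offset))
            if s[i] == rc[i - offset]
        )
        best = max(best, matches)
    return best


@dataclass(frozen=True)
class PrimerReport:
    """Per-rule outcome for one primer pair against one sc interval.

    Hard rules disqualify; soft rules and the self-complementarity score
    only order surviving pairs (smaller rank key is better).
    """

    tm_in_window: bool          # both Tm in [58, 65] C
    tm_delta_ok: bool           # |Tm_f - Tm_r| <= 2 C
    product_max_ok: bool        # product <= sc interval length
    product_min_ok: bool        # product >= sc interval length - slack
    gc_in_window: bool          # soft: both GC in [0.40, 0.60]
    long_primers: bool          # soft: both primers > 25 bp
    passes: bool
    rank_key: tuple

    TM_WINDOW = (58.0, 65.0)
    TM_OPTIMUM = 62.0
    MAX_TM_DELTA = 2.0
    GC_WINDOW = (0.40, 0.60)
    MIN_PREFERRED_LEN = 25


def evaluate_primer_pair(
    pair: PrimerPair,
    sc_interval_length: int,
    product_min_slack: int = 500,
) -> PrimerReport:
    """Score a primer pair against the probe-production constraints.

    The PCR product may be at most the sc interval length and at least
    ``product_min_slack`` bp shorter than that maximum (slack 200–500 bp;
    the permissive 500 is the default).
    """
    lo, hi = PrimerReport.TM_WINDOW
    tm_in_window = lo <= pair.tm_forward <= hi and lo <= pair.tm_reverse <= hi
    tm_delta = abs(pair.tm_forward - pair.tm_reverse)
    tm_delta_ok = tm_delta <= PrimerReport.MAX_TM_DELTA
    product_max_ok = pair.product_length <= sc_interval_length
    product_min_ok = pair.product_length >= sc_interval_length - product_min_slack
    g0, g1 = PrimerReport.GC_WINDOW
    gc_in_window = g0 <= pair.gc_forward <= g1 and g0 <= pair.gc_reverse <= g1
    long_primers = (
        len(pair.forward_seq) > PrimerReport.MIN_PREFERRED_LEN
        and len(pair.reverse_seq) > PrimerReport.MIN_PREFERRED_LEN
    )
    passes = tm_in_window and tm_delta_ok and product_max_ok and product_min_ok
    # order survivors: soft-rule misses first, then self-complementarity,
    # then distance from the optimal Tm, then Tm imbalance
    rank_key = (
        (not gc_in_window) + (not long_primers),
        float(pair.self_complementarity),
        abs(pair.tm_forward - PrimerReport.TM_OPTIMUM)
        + abs(pair.tm_reverse - PrimerReport.TM_OPTIMUM),
        tm_delta,
    )
    return PrimerReport(
        tm_in_window=tm_in_window,
        tm_delta_ok=tm_delta_ok,
        product_max_ok=product_max_ok,
        product_min_ok=product_min_ok,
        gc_in_window=gc_in_window,
        long_primers=long_primers,
        passes=passes,
        rank_key=rank_key,
    )
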