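# Methods

`dachroma` implements a desk-reproducible version of a metaphase-FISH
differential-accessibility (DA) workflow: quantifying the asymmetry of
single-copy probe hybridization between homologous chromosomes, deciding
DA vs equivalent accessibility (EA) per locus, designing the single-copy
probe intervals themselves, aggregating concordant DA probes into
chromosomal domains, and relating those domains to interphase chromatin
(open-chromatin marks, TAD partitions). This note records the models,
conventions, parameters and deliberate design choices.

## Coordinate and length conventions

All intervals are 1-based inclusive internally; BED input/output converts
from/to the on-disk 0-based half-open convention. Interval length is
`end − start` throughout. Published probe tables in this domain mix two
dialects — domain totals computed as `end − start` and probe lengths as
`end − start + 1` — and the package adopts the former uniformly because
every machine-checkable domain quantity (the six domain spans, gap sizes,
combined target lengths) is reproduced exactly under it. The `+1` dialect
would shift each probe length by one base; users comparing against
per-probe lengths quoted elsewhere should expect that off-by-one.

Reported kb figures round half-up at the printed precision
(`kb_text`): 82,850 bp → "82.9", 12,195 bp → "12.2". Banker's rounding
would print "12.1" and fail to reproduce published strings.

## Single-copy interval discovery and primer screening

A stretch is single-copy-eligible when it overlaps no repetitive element
whose divergence from its family consensus is below 20%; more divergent
repeats behave as unique hybridization targets and do not mask. Maximal
repeat-free runs are returned whole: runs shorter than 1.4 kb (the
practical probe minimum) are dropped, runs longer than 4 kb are flagged
rather than trimmed, since trimming is a reporting decision. Candidates
overlapping a copy-number variant of population frequency ≥ 1% are
excluded — any overlap (≥ 1 bp) disqualifies; probe-count minima used by
the source CNV arrays belong to those datasets, not to this filter. Genic
probes additionally require the host gene to be transcriptionally inert
(≤ 5 TPM in every tissue of interest); a genic probe with no expression
rows is an error, never a silent keep.

Primer pairs are screened with hard rules — both melting temperatures in
58–65 °C, |ΔTm| ≤ 2 °C, PCR product no longer than the single-copy
interval and no more than 500 bp (configurable 200–500) shorter than that
maximum — and soft preferences (GC in 40–60%, primers > 25 bp) that only
order survivors together with the self-complementarity score. Melting
temperatures use unified nearest-neighbor thermodynamics (the 1998
SantaLucia unified parameter set via Biopython) at 50 mM monovalent salt
and 500 nM total primer; the model is pluggable because the original
designs came from a web service whose exact settings are not restated
anywhere, and any fixed, documented thermodynamic model serves the
screening role. Self-complementarity is the maximum count of Watson–Crick
matches over all ungapped alignments of a primer against its own reverse
complement — the criterion is named but not defined in the source
protocols, and the ungapped scan is the simplest faithful reading.

## GVF signal quantification

Each homolog signal is delineated by an active contour whose external
force field is gradient vector flow (GVF): the gradient of an edge map
(squared gradient magnitude of the Gaussian-smoothed image, rescaled to
[0, 1]) diffused by iterating

    u ← u + μ ∇²u − (u − f_r)(f_r² + f_c²)

(and likewise v with f_c), which converges to the field's Euler–Lagrange
fixed point; a dense linear solve of the same equations on a 32×32 grid
is the test oracle. Diffusion lets the contour feel the boundary from a
distance, so a small initial circle placed at a seed converges onto the
signal perimeter even when initialized well inside it.

The snake itself is the standard semi-implicit discretization: internal
tension α and rigidity β enter through a cyclic pentadiagonal system
solved implicitly each step, the external force is the GVF vector
sampled at the contour points. Each signal is contoured on a locally
min–max-normalized crop around its seed; this makes contour forces
invariant to the (possibly 20-fold) brightness difference between the
two homolog spots, which is the entire phenomenon under study. An early
implementation normalized the external force vectors to unit length; that
made weak noise edges exactly as attractive as the true boundary and the
contour could wander off dim signals, so the field is used at its native
magnitude.

Defaults (all surfaced in `GvfConfig`): edge-map σ = 4 px (about twice
the expected point-spread σ, which keeps ≈ 90% of a spot's flux inside
the converged contour), μ = 0.2, 80 diffusion iterations, tolerance 1e−3,
α = 0.1, β = 0.5, initial radius 3 px, 48 contour points, 400 step cap.
These are conventional stable values; the acceptance properties hold
without tuning them per image.

Integrated intensity is the sum of background-corrected pixels inside
the contour mask, floored at zero. Background is the median of the
annulus obtained by dilating the mask 2 px (falling back to a global
percentile if the annulus is empty), because the source protocols never
describe background handling and a local annulus is the default choice
in spot quantification. Annulus contamination by the spot's own tail
biases each homolog's integral by the same *relative* amount, so the
intensity ratio

    ratio = |I1 − I2| / (I1 + I2)

is unbiased even where the absolute integrals are a few percent low.
Homologs are ordered by descending intensity (I1 ≥ I2); the ratio is
invariant under the ordering and under common rescaling. Cells are
excluded (never silently skipped) when signals cannot be quantified:
fewer than two separated maxima, a contour that converges without ever
feeling an external force (flat background — the practical signature of
contour collapse, since the semi-implicit internal forces reach the
displacement tolerance before the area shrinks below the literal 4 px
floor, which is also checked), overlapping contours, or both integrals
zero.

Seed detection takes the brightest smoothed local maxima above a robust
prominence threshold (median + 5 MAD-σ), pairwise separated by at least
`min_separation`; user-supplied expected target locations override
detection, mirroring the real protocol in which the analyst knows where
the probe should hybridize.

## Scoring and statistics

The qualitative rule: homologs scored on {bright, medium, dim, nil};
different categories → DA; bright/bright or medium/medium → EA; dim/dim,
nil/nil, dim/nil, and any chromosome-overlap cell → EXCLUDED. The rule is
total and symmetric over the 4×4 category grid, with exactly those three
unordered pairs excluded.

Probe-level classification pools DA/EA counts across a probe's samples
and applies a two-tailed binomial test with normal approximation against
p₀ = 0.5 — the natural null for "no accessibility bias" since DA and EA
calls are the two scored outcomes. The approximation uses a half-unit
continuity correction by default: exhaustive enumeration at n = 25 (the
protocol's minimum scored-cell count) shows the corrected approximation
within 0.0022 of the exact two-sided binomial p, against a worst case of
0.159 uncorrected, so the correction is what makes "normal approximation"
interchangeable with the exact test at protocol sample sizes. The
uncorrected textbook z is available via `continuity=False`. A probe is DA
(EA) when its DA (EA) fraction exceeds 1/2 and the test is significant at
α = 0.05; otherwise indeterminate. The "> 2/3 of cells" figure quoted in
qualitative descriptions is reported as a flag, not used as a gate.
Pools below 25 scored cells carry a warning rather than failing.

Between-sample contrasts use the pooled-variance two-proportion Z test
without continuity correction (the generic named test; published
decisions are matched at the significance level, not digit-for-digit).
Ratio distributions are compared with a two-sided Mann–Whitney U: exact
enumeration when both samples have ≤ 8 untied observations, otherwise the
tie-corrected normal approximation *without* continuity correction —
that choice keeps p = 1 exactly for identical samples and preserves the
identity H = z² between the two-group Kruskal–Wallis statistic and the
Mann–Whitney z; the cost, established by full enumeration of the 7-vs-7
null, is a worst-case gap of 0.056 from the exact p at those sizes.
Tissue-level comparisons use tie-corrected Kruskal–Wallis (χ² reference,
k−1 df; all-identical data returns H = 0, p = 1 rather than erroring),
and chromatin-mark means use Welch's unequal-variance t test. No
multiple-testing correction is applied across probes, matching the
source workflow; a Bonferroni-style correction can be applied by callers
but is deliberately not silent default behavior.

## Domains, marks and TADs

Probes carry a `locus` label — the targeted chromosomal neighborhood
around one anchor probe. Domains are maximal runs of ≥ 2 consecutive DA
probes within a (chromosome, locus) group with no interspersed EA probe;
singleton DA probes are reported but are not domains. Grouping by locus
rather than by bare chromosome matters: chromosome 15 carries three
separately targeted regions with no interspersed EA probe, which a bare
per-chromosome scan would fuse into one 30 Mb pseudo-domain. No maximum
intra-domain gap is imposed (the largest genuine gap is 87,287 bp), but
`max_gap_warn` emits a warning for unusually sparse runs. The domain
hull runs from the smallest to the largest member-probe coordinate, and
the domain is inferred contiguous between probes — an inference, not an
observation, as only the probe targets are measured.

Signal tracks are piecewise-constant (bedGraph-like); integration over an
interval is Σ value × overlap (end−start convention), additive over
partitions and equal to a per-base scan by construction. DA-vs-EA mark
comparison runs Welch's t per mark; intervals exceeding 10× their group
median are flagged as outliers (the signature of a probe landing in an
active promoter), and censoring them is opt-in with the censored ids
always reported — never silent.

TAD overlap classification of a domain hull against a precomputed TAD
partition (Hi-C matrices are not parsed; TADs enter as BED intervals):
`within` (inside one TAD, more than one boundary window from both
edges), `within_boundary_proximal` (inside but approaching an edge),
`spans_boundary` (crossing a TAD edge — including the case of a hull
overlapping one TAD but protruding into an inter-TAD gap, which the
four-label scheme does not otherwise cover), `between_tads` (overlapping
none). The boundary window defaults to the 25 kb map resolution, since
"approaching a boundary" is a qualitative call at that resolution.

## Synthetic data: what it emulates and what it does not

Every pipeline input has a seeded generator with exact ground truth, and
generators are pure functions of (spec, seed).

* **Images**: two isotropic-Gaussian spots (σ = 2 px) with exact
  integrated photon sums (S, ρS) on a constant background (100 counts)
  with Poisson noise, in 64×64 frames; the true ratio is (1−ρ)/(1+ρ).
  The DA regime draws true ratios around median 0.8 and the EA regime
  around 0.2 — the scale of quantified medians reported for real DA and
  EA loci — with spreads 0.2/0.15. Not modeled: chromosome morphology
  and DAPI counterstain, anisotropic optics, uneven illumination,
  hybridization artifacts. Passing recovery tests therefore shows the
  quantification chain is correct and unbiased for well-formed two-spot
  signals, not that it is robust to every microscopy pathology. Cells
  whose dim homolog approaches zero photons can be unscorable; they are
  excluded exactly as unscorable real cells are, which trims the extreme
  top of the recovered DA-regime ratio distribution.
* **Score tables**: per cell, EXCLUDED with probability `p_excluded`
  (drawn only from the excluded pair list, so generator and scoring rule
  agree by construction), else a DA-consistent pair with probability
  `p_da`. Inter-analyst disagreement is not modeled.
* **Repeat landscapes**: low-divergence repeats tile everything outside
  planted single-copy runs edge-to-edge, so the planted runs are exactly
  the discoverable intervals (the closure property the recovery test
  asserts); highly divergent repeats are sprinkled inside runs to confirm
  they do not mask. Real repeat landscapes leave sub-threshold runs too.
* **Signal tracks**: one constant segment per interval, DA mean 1.0 vs
  EA mean 3.0 per bp (a three-fold depletion, the order observed for
  open-chromatin marks over DA loci) with optional noise and an optional
  20× promoter-like outlier.
* **TADs**: disjoint intervals between 25 kb-aligned boundaries with
  optional inter-TAD gaps. `reference_tad_topology()` is a synthetic
  stand-in partition constructed so the six packaged domains reproduce
  the reported qualitative placement (three mid-TAD, two
  boundary-proximal, one between TADs); it is not measured Hi-C data.

## Problem sizes and numerics

The test suite and the acceptance script use 25 cells per condition for
image batches (100 cells across the four asymmetry levels ρ ∈ {1, 0.5,
0.2, 0.05}), 500 replicates for score-table parameter recovery at n = 50
scored cells, 1,000 simulations for the Kruskal–Wallis type-I rate
(three tissues × 10 samples of continuous DA fractions), and ≥ 100
random cases for each brute-force oracle comparison — sizes chosen to
make the Monte-Carlo acceptance margins comfortable at desk scale.
GVF iterations stop at a 1e−3 max-update tolerance; the direct-solve
comparison uses 32×32 grids where the dense system is well conditioned.
Degenerate inputs error loudly by policy: zero scored cells, both-zero
intensities, zero variance in both Welch samples, pooled proportions of
0 or 1.

## Known limitations

* The contour energy of the original GVF implementation is not published;
  equivalence is claimed to the recovery properties, not to that code.
* Quantification assumes exactly two signals per cell; polyploid or
  overlapping-chromosome cells must be excluded upstream.
* The intensity ratio implements only the displayed normalization;
  exposure or gain correction across images is out of scope.
* Genome-wide primer uniqueness (BLAST/BLAT) is out of scope; the primer
  report screens thermodynamic and product-size constraints only.
* A figure caption in the source material quotes one domain span as
  25.455 kb where the coordinate arithmetic (and the table) give
  25,454 bp; the arithmetic value is used.
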