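"""Domain aggregation, probe naming, track integration and TAD overlap."""

import numpy as np
import pytest

from dachroma.genomic_core import GenomicInterval, IntervalContractError, ScProbe
from dachroma.domain_tads import (
    GeneModel,
    SignalTrack,
    TadSet,
    build_domains,
    classify_tad_overlap,
    compare_marks,
    domain_report,
    integrate_track,
    name_probe,
)

EXPECTED_DOMAINS = {
    # name: (n_probes, span_bp, combined target length bp)
    "XDH": (3, 25454, 7594),
    "HMGB1P5": (2, 39731, 5232),
    "FGF6": (2, 16048, 5088),
    "TPM1": (3, 16034, 7999),
    "COX5A": (3, 109970, 6250),
    "HMGB1P1": (4, 12_9583, 12195),
}


class TestBuildDomains:
    def test_packaged_probe_set_reconstructs_all_six_domains(
        self, domains_and_singletons
    ):
        domains, singletons = domains_and_singletons
        assert {d.name for d in domains} == set(EXPECTED_DOMAINS)
        for dom in domains:
            n, span, target = EXPECTED_DOMAINS[dom.name]
            rep = domain_report(dom)
            assert rep.n_probes == n
            assert rep.span_bp == span
            assert rep.combined_target_length_bp == target
        assert [p.name for p in singletons] == ["DUOX1_IVS1-IVS3"]

    def test_published_gap_and_target_strings(self, domains_and_singletons):
        domains, _ = domains_and_singletons
        reports = {d.name: domain_report(d) for d in domains}
        assert "82.9" in reports["HMGB1P1"].gaps_kb
        assert "87.3" in reports["COX5A"].gaps_kb
        assert reports["XDH"].combined_target_length_kb == "7.6"
        assert reports["TPM1"].combined_target_length_kb == "8.0"
        assert reports["HMGB1P1"].combined_target_length_kb == "12.2"
        all_gaps = [g for r in reports.values() for g in r.gaps_bp]
        assert min(all_gaps) == 1366 and max(all_gaps) == 87287

    def test_interspersed_ea_breaks_run(self):
        probes = [
            ScProbe(f"p{i}", GenomicInterval("chr1", 1000 * i, 1000 * i + 500), call=c)
            for i, c in enumerate(["DA", "EA", "DA"], start=1)
        ]
        domains, singletons = build_domains(probes)
        assert domains == []
        assert len(singletons) == 2

    def test_matches_brute_force_run_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            calls = rng.choice(["DA", "EA"], size=12)
            probes = [
                ScProbe(
                    f"p{i}",
                    GenomicInterval("chr1", 1 + 2000 * i, 1000 + 2000 * i),
                    call=c,
                )
                for i, c in enumerate(calls)
            ]
            domains, singletons = build_domains(probes)
            # oracle: run-length scan over the call vector
            runs, run = [], []
            for i, c in enumerate(calls):
                if c == "DA":
                    run.append(i)
                else:
                    runs.append(run)
                    run = []
            runs.append(run)
            expected_domains = [r for r in runs if len(r) >= 2]
            expected_singletons = [r[0] for r in runs if len(r) == 1]
            assert [len(d.probes) for d in domains] == [
                len(r) for r in expected_domains
            ]
            assert [p.name for p in singletons] == [
                f"p{i}" for i in expected_singletons
            ]
            for dom in domains:  # every member DA; no EA inside the hull
                assert all(p.call == "DA" for p in dom.probes)
                for p in probes:
                    if p.call == "EA":
                        assert not dom.hull.contains(p.interval)

    def test_overlapping_probes_rejected(self):
        probes = [
            ScProbe("a", GenomicInterval("chr1", 100, 500), call="DA"),
            ScProbe("b", GenomicInterval("chr1", 400, 900), call="DA"),
        ]
        with pytest.raises(IntervalContractError):
            build_domains(probes)

    def test_unclassified_probe_rejected(self):
        with pytest.raises(ValueError):
            build_domains([ScProbe("a", GenomicInterval("chr1", 1, 10))])

    def test_max_gap_warning(self):
        probes = [
            ScProbe("a", GenomicInterval("chr1", 1, 1000), call="DA"),
            ScProbe("b", GenomicInterval("chr1", 500_000, 501_000), call="DA"),
        ]
        with pytest.warns(UserWarning):
            domains, _ = build_domains(probes, max_gap_warn=100_000)
        assert len(domains) == 1  # warned, never split


class TestNameProbe:
    GENES = [
        GeneModel("FGF6", GenomicInterval("chr12", 4543308, 4554558)),
        GeneModel("CTCFL", GenomicInterval("chr20", 56071021, 56100163)),
    ]

    def test_telomeric_intergenic_probe(self):
        # 12p: centromere is on the high-coordinate side, probe below the gene
        name = name_probe(
            GenomicInterval("chr12", 4537157, 4538816), self.GENES, centromere=34_800_000
        )
        assert name == "FGF6_tel4492"

    def test_centromeric_intergenic_probe(self):
        # 20q: centromere on the low-coordinate side, probe below the gene
        name = name_probe(
            GenomicInterval("chr20", 56033167, 56036719), self.GENES, centromere=28_000_000
        )
        assert name == "CTCFL_cen34302"

    def test_abutting_gene_distance_zero(self):
        gene = GeneModel("GENE", GenomicInterval("chr1", 10_000, 20_000))
        name = name_probe(
            GenomicInterval("chr1", 5_000, 9_000), [gene], centromere=1
        )
        assert name == "GENE_cen1000"
        abutting = name_probe(
            GenomicInterval("chr1", 5_000, 10_000), [gene], centromere=1
        )
        assert abutting == "GENE_cen0"

    def test_genic_probe_named_by_intron_span(self):
        gene = GeneModel(
            "XDH",
            GenomicInterval("chr2", 31_540_000, 31_620_000),
            introns={
                27: GenomicInterval("chr2", 31_570_500, 31_572_000),
                30: GenomicInterval("chr2", 31_567_000, 31_569_500),
            },
        )
        # minus-strand gene: ascending coordinates print descending IVS numbers
        name = name_probe(
            GenomicInterval("chr2", 31_568_769, 31_571_269), [gene], centromere=93_300_000
        )
        assert name == "XDH_IVS30-IVS27"

    def test_single_intron(self):
        gene = GeneModel(
            "TPM1",
            GenomicInterval("chr15", 63_334_830, 63_364_111),
            introns={8: GenomicInterval("chr15", 63_356_000, 63_361_000)},
        )
        name = name_probe(
            GenomicInterval("chr15", 63_357_346, 63_360_645), [gene], centromere=39_000_000
        )
        assert name == "TPM1_IVS8"

    def test_no_gene_on_chromosome(self):
        with pytest.raises(ValueError):
            name_probe(GenomicInterval("chrX", 1, 10), self.GENES, centromere=1)


def _track(segs):
    return SignalTrack(
        segments=[(GenomicInterval("chrT", s, e), v) for s, e, v in segs]
    )


class TestIntegrateTrack:
    def test_constant_track(self):
        track = _track([(1, 10_001, 2.5)])
        iv = GenomicInterval("chrT", 1, 10_001)
        total, per_bp = integrate_track(track, iv)
        assert total == pytest.approx(2.5 * 10_000)
        assert per_bp == pytest.approx(2.5)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(8)
        segs = []
        pos = 1
        while pos < 50_000:
            end = pos + int(rng.integers(100, 3000))
            segs.append((pos, end, float(rng.uniform(0, 5))))
            pos = end
        track = _track(segs)
        iv = GenomicInterval("chrT", 5_000, 42_000)
        mid = 17_345
        whole, _ = integrate_track(track, iv)
        left, _ = integrate_track(track, GenomicInterval("chrT", 5_000, mid))
        right, _ = integrate_track(track, GenomicInterval("chrT", mid, 42_000))
        assert whole == pytest.approx(left + right)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            segs = []
            pos = int(rng.integers(1, 50))
            for _ in range(rng.integers(1, 8)):
                end = pos + int(rng.integers(1, 300))
                segs.append((pos, end, float(rng.uniform(0, 4))))
                pos = end + int(rng.integers(0, 100))
            track = _track(segs)
            s = int(rng.integers(1, 1500))
            iv = GenomicInterval("chrT", s, s + int(rng.integers(1, 800)))
            total, _ = integrate_track(track, iv)
            # per-base scan: base p in [start, end) carries each segment's value
            oracle = 0.0
            for seg_s, seg_e, v in segs:
                for p in range(max(s, seg_s), min(iv.end, seg_e)):
                    oracle += v
            assert total == pytest.approx(oracle)

    def test_uncovered_interval_is_zero(self):
        total, per_bp = integrate_track(
            _track([(1, 100, 3.0)]), GenomicInterval("chrT", 5_000, 6_000)
        )
        assert total == 0.0 and per_bp == 0.0


class TestCompareMarks:
    def test_identical_groups_no_flags(self):
        vals = {f"i{k}": 2.0 + 0.1 * k for k in range(6)}
        res = compare_marks(vals, dict(vals))
        assert res.test.p_value == pytest.approx(1.0)
        assert res.flagged == [] and res.censored == []

    def test_depleted_da_detected(self):
        rng = np.random.default_rng(4)
        da = {f"da{k}": max(0.0, rng.normal(1.0, 0.3)) for k in range(18)}
        ea = {f"ea{k}": max(0.0, rng.normal(3.0, 0.9)) for k in range(59)}
        res = compare_marks(da, ea)
        assert res.da_mean < res.ea_mean
        assert res.test.significant

    def test_planted_outlier_flagged_and_censoring_explicit(self):
        da = {f"da{k}": 1.0 + 0.02 * k for k in range(5)}
        da["da_promoter"] = 20.0
        ea = {f"ea{k}": 3.0 + 0.01 * k for k in range(5)}
        res = compare_marks(da, ea)
        assert res.flagged == ["da_promoter"] and res.censored == []
        res_c = compare_marks(da, ea, censor_outliers=True)
        assert res_c.censored == ["da_promoter"]
        assert res_c.da_mean < res.da_mean  # censoring removes the enrichment


class TestClassifyTadOverlap:
    TADS = TadSet(
        tads={
            "chr1": [
                GenomicInterval("chr1", 1, 1_000_000),
                GenomicInterval("chr1", 1_100_000, 2_000_000),
            ]
        },
        resolution=25_000,
    )

    def test_within(self):
        iv = GenomicInterval("chr1", 400_000, 500_000)
        assert classify_tad_overlap(iv, self.TADS) == "within"

    def test_boundary_proximal(self):
        iv = GenomicInterval("chr1", 960_000, 990_000)  # 10 kb from TAD edge
        assert classify_tad_overlap(iv, self.TADS) == "within_boundary_proximal"

    def test_spans_boundary(self):
        iv = GenomicInterval("chr1", 900_000, 1_200_000)
        assert classify_tad_overlap(iv, self.TADS) == "spans_boundary"

    def test_between_tads(self):
        iv = GenomicInterval("chr1", 1_010_000, 1_090_000)
        assert classify_tad_overlap(iv, self.TADS) == "between_tads"

    def test_partition_property(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            s = int(rng.integers(1, 1_900_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 400_000)))
            labels = [
                classify_tad_overlap(iv, self.TADS, boundary_window=w)
                for w in (25_000,)
            ]
            assert len(labels) == 1 and labels[0] in (
                "within",
                "within_boundary_proximal",
                "spans_boundary",
                "between_tads",
            )
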