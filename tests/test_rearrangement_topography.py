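"""Kataegis, clustered rearrangements, chromothripsis filters, event merging
and complex-SV statistics, each checked against brute-force oracles."""

import numpy as np
import pytest

from mutscenarios.cna_topography import classify_segment
from mutscenarios.rearrangement_topography import (ComplexEvent,
                                                   annotate_gene_overlap,
                                                   chromothripsis_filters,
                                                   complex_sv_fraction,
                                                   detect_clustered_rearrangements,
                                                   detect_kataegis,
                                                   genome_density,
                                                   longest_oscillating_run,
                                                   merge_complex_calls,
                                                   read_complex_events,
                                                   write_complex_events, sv_id)
from mutscenarios.variant_io import CnaSegment, GeneAnnotation, SnvRecord, SvRecord


def snvs_at(positions, sample="s", chrom="chr1"):
    return [SnvRecord(sample, chrom, p, "C", "A") for p in positions]


class TestKataegis:
    def test_six_snvs_500bp_apart_form_one_cluster(self):
        clusters = detect_kataegis(snvs_at([1000 + 500 * i for i in range(6)]))
        assert len(clusters) == 1
        assert clusters[0].n_snvs == 6
        assert (clusters[0].start, clusters[0].end) == (1000, 3500)

    def test_five_snvs_insufficient(self):
        assert detect_kataegis(snvs_at([1000 + 500 * i for i in range(5)])) == []

    def test_exact_1kb_gap_splits_run(self):
        # 7 SNVs with one exactly-1000 bp gap: strict < 1 kb splits into 4+3
        pos = [1000, 1500, 2000, 2500, 3500, 4000, 4500]
        assert detect_kataegis(snvs_at(pos)) == []

    def test_clusters_are_maximal_and_disjoint(self, rng):
        for _ in range(20):
            pos = sorted(int(p) for p in
                         rng.choice(200_000, size=int(rng.integers(5, 60)),
                                    replace=False))
            clusters = detect_kataegis(snvs_at(pos), min_run=6, max_imd=1000)
            for c in clusters:
                inside = [p for p in pos if c.start <= p <= c.end]
                assert len(inside) == c.n_snvs
                assert all(b - a < 1000 for a, b in zip(inside, inside[1:]))
                # not extendable on either side
                before = [p for p in pos if p < c.start]
                after = [p for p in pos if p > c.end]
                if before:
                    assert c.start - before[-1] >= 1000
                if after:
                    assert after[0] - c.end >= 1000

    def test_matches_brute_force_run_oracle(self, rng):
        """Detected clusters equal exhaustive run scanning on instances with
        up to 200 variants."""
        for _ in range(20):
            pos = sorted(set(int(p) for p in
                             rng.integers(1, 100_000, size=int(rng.integers(1, 200)))))
            got = [(c.start, c.end, c.n_snvs) for c in detect_kataegis(snvs_at(pos))]
            runs, run = [], [pos[0]]
            for a, b in zip(pos, pos[1:]):
                if b - a < 1000:
                    run.append(b)
                else:
                    runs.append(run)
                    run = [b]
            runs.append(run)
            expected = [(r[0], r[-1], len(r)) for r in runs if len(r) >= 6]
            assert got == expected


class TestClusteredRearrangements:
    def _dels(self, start, n, spacing, sample="s", chrom="chr1"):
        return [SvRecord(sample, chrom, start + i * spacing, chrom,
                         start + i * spacing + 200, "DEL") for i in range(n)]

    def test_twelve_breakpoints_in_8mb_detected(self):
        svs = self._dels(1_000_000, 6, 1_500_000)  # 12 breakpoints over ~7.5 Mb
        events = detect_clustered_rearrangements(svs)
        assert len(events) == 1
        assert events[0].event_class == "clustered"

    def test_nine_breakpoints_not_detected(self):
        svs = self._dels(1_000_000, 4, 100_000)
        svs.append(SvRecord("s", "chr1", 1_500_000, "chr2", 1_000, "TRA"))
        assert detect_clustered_rearrangements(svs) == []

    def test_region_overlapping_known_event_filtered(self):
        svs = self._dels(1_000_000, 6, 1_000_000)
        known = [ComplexEvent("s", "chromothripsis",
                              intervals=(("chr1", 900_000, 8_000_000),))]
        assert detect_clustered_rearrangements(svs, known_events=known) == []
        other = [ComplexEvent("other_sample", "chromothripsis",
                              intervals=(("chr1", 900_000, 8_000_000),))]
        assert len(detect_clustered_rearrangements(svs, known_events=other)) == 1

    def test_adding_breakpoints_never_removes_regions(self, rng):
        svs = self._dels(1_000_000, 6, 1_000_000)
        base = detect_clustered_rearrangements(svs)
        extra = svs + self._dels(2_000_000, 3, 50_000)
        grown = detect_clustered_rearrangements(extra)
        for ev in base:
            (chrom, s, e), = ev.intervals
            assert any(iv[0] == chrom and iv[1] <= s and iv[2] >= e
                       for g in grown for iv in g.intervals)

    def test_matches_brute_force_window_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(3, 40))
            svs = []
            for _ in range(n):
                p1 = int(rng.integers(1, 30_000_000))
                svs.append(SvRecord("s", "chr1", p1, "chr1",
                                    p1 + int(rng.integers(500, 5_000_000)), "DEL"))
            got = detect_clustered_rearrangements(svs, window=10_000_000,
                                                  min_breakpoints=10)
            bps = sorted(p for sv in svs for _, p in sv.breakpoints())
            member = set()
            for i, a in enumerate(bps):
                inside = [p for p in bps if a <= p <= a + 10_000_000]
                if len(inside) >= 10:
                    member.update(inside)
            if not member:
                assert got == []
            else:
                covered = set()
                for ev in got:
                    for _, s, e in ev.intervals:
                        covered.update(p for p in bps if s < p <= e)
                assert covered == member


class TestChromothripsis:
    def test_oscillating_run_counter_against_brute_force(self, rng):
        def oracle(seq):
            best = min(len(seq), 1)
            for i in range(len(seq)):
                for j in range(i + 1, len(seq)):
                    vals = seq[i:j + 1]
                    if len(set(vals)) == 2 and all(a != b for a, b in zip(vals, vals[1:])):
                        best = max(best, len(vals))
            return best

        for _ in range(30):
            seq = [int(x) for x in rng.integers(1, 4, size=int(rng.integers(1, 40)))]
            assert longest_oscillating_run(seq) == oracle(seq)

    def _interleaved_svs(self, n, sample="s", chrom="chr1"):
        # staggered intervals: i-th [i*10k, i*10k + 15k] partially overlaps next
        return [SvRecord(sample, chrom, 1_000_000 + i * 10_000, chrom,
                         1_000_000 + i * 10_000 + 15_000,
                         ["DEL", "DUP", "INV"][i % 3]) for i in range(n)]

    def _oscillating_states(self, n_segments, sample="s", chrom="chr1"):
        segs = []
        for i in range(n_segments):
            total = 2 if i % 2 == 0 else 3
            segs.append(CnaSegment(sample, chrom, i * 100_000, (i + 1) * 100_000,
                                   total - 1, 1))
        return [classify_segment(s, 2.0) for s in segs]

    def test_three_interleaved_svs_is_none(self):
        cands = chromothripsis_filters(self._interleaved_svs(3),
                                       self._oscillating_states(10), "s")
        assert cands[0].confidence == "none"

    def test_six_interleaved_eight_oscillating_at_least_low(self):
        cands = chromothripsis_filters(self._interleaved_svs(6),
                                       self._oscillating_states(8), "s")
        assert cands[0].n_interleaved_svs >= 6
        assert cands[0].n_oscillating_segments >= 7
        assert cands[0].confidence in ("low", "high")

    def test_missing_cna_skips_chromosome(self):
        cands = chromothripsis_filters(self._interleaved_svs(6), [], "s")
        assert cands == []


class TestMergeComplexCalls:
    def _ev(self, cls, chrom="chr1", start=0, end=1_000_000, sample="s", source="x"):
        return ComplexEvent(sample, cls, intervals=((chrom, start, end),),
                            source=source)

    def test_most_informative_class_survives(self):
        merged = merge_complex_calls([self._ev("clustered"), self._ev("ecDNA")])
        assert len(merged) == 1
        assert merged[0].event_class == "ecDNA"
        assert set(merged[0].source.split(";")) == {"x"}

    def test_disjoint_events_both_retained(self):
        merged = merge_complex_calls([self._ev("ecDNA"), self._ev("BFB", chrom="chr2")])
        assert len(merged) == 2

    def test_transitive_chain_collapses_like_union_find_oracle(self):
        a = self._ev("clustered", start=0, end=1_000_000)
        b = self._ev("chromothripsis", start=400_000, end=1_400_000)
        c = self._ev("BFB", start=900_000, end=1_900_000)
        merged = merge_complex_calls([a, b, c], min_reciprocal_overlap=0.5)
        assert len(merged) == 1 and merged[0].event_class == "BFB"

    def test_idempotent_and_order_invariant(self):
        events = [self._ev("clustered"), self._ev("ecDNA"),
                  self._ev("TIC", chrom="chr2"), self._ev("rigma", sample="t")]
        once = merge_complex_calls(events)
        assert merge_complex_calls(once) == once
        assert merge_complex_calls(list(reversed(events))) == once

    def test_tsv_round_trip(self, tmp_path):
        events = [ComplexEvent("s1", "ecDNA", (("chr1", 100, 2000), ("chr2", 5, 50)),
                               source="adapter", sv_ids=("a", "b"))]
        path = tmp_path / "events.tsv"
        write_complex_events(events, path)
        assert read_complex_events(path) == events


class TestGeneOverlapAndStats:
    GENES = [GeneAnnotation("BRCA2", "chr1", 1_000_000, 1_050_000, "hrr_profound")]

    def test_breakpoint_10kb_upstream_is_close(self):
        sv = SvRecord("s", "chr1", 990_000, "chr1", 2_000_000, "DEL")
        hits = annotate_gene_overlap([sv], [], [], self.GENES)
        assert ("s", "BRCA2", "sv_close") in hits.itertuples(index=False, name=None)

    def test_breakpoint_inside_gene_is_within(self):
        sv = SvRecord("s", "chr1", 1_010_000, "chr1", 2_000_000, "DEL")
        hits = annotate_gene_overlap([sv], [], [], self.GENES)
        assert ("s", "BRCA2", "sv_within") in hits.itertuples(index=False, name=None)

    def test_breakpoint_20001_bp_away_is_no_hit(self):
        # both breakpoints outside the 20 kb pad: no hit at all
        sv = SvRecord("s", "chr1", 1_000_000 - 20_001, "chr1", 3_000_000, "DEL")
        assert annotate_gene_overlap([sv], [], [], self.GENES).empty

    def test_exact_20kb_is_still_close(self):
        sv = SvRecord("s", "chr1", 1_000_000 - 19_999, "chr1", 3_000_000, "DEL")
        hits = annotate_gene_overlap([sv], [], [], self.GENES)
        assert ("s", "BRCA2", "sv_close") in hits.itertuples(index=False, name=None)

    def test_coding_and_cna_hits(self):
        snv = SnvRecord("s", "chr1", 1_000_500, "C", "A", consequence="missense")
        seg = CnaSegment("s", "chr1", 990_000, 1_060_000, 9, 1)
        state = classify_segment(seg, 2.0)
        hits = annotate_gene_overlap([], [state], [snv], self.GENES)
        got = set(hits.itertuples(index=False, name=None))
        assert ("s", "BRCA2", "coding_snv_indel") in got
        assert ("s", "BRCA2", "amp") in got

    def test_complex_fraction_toy_recount(self):
        svs = [SvRecord("s", "chr1", 100_000 + i * 10_000, "chr1",
                        100_000 + i * 10_000 + 500, "DEL") for i in range(7)]
        svs += [SvRecord("s", "chr1", 5_000_000 + i * 10_000, "chr1",
                         5_000_000 + i * 10_000 + 500, "DEL") for i in range(3)]
        ev = [ComplexEvent("s", "chromothripsis", (("chr1", 50_000, 400_000),))]
        per_sample, cohort = complex_sv_fraction(svs, ev)
        assert per_sample["s"] == pytest.approx(0.7)
        assert cohort == pytest.approx(0.7)

    def test_complex_fraction_bounds_and_empty(self):
        svs = [SvRecord("s", "chr1", 1000, "chr1", 2000, "DEL")]
        ev = [ComplexEvent("s", "ecDNA", (("chr1", 0, 10_000),))]
        assert complex_sv_fraction(svs, ev)[0]["s"] == 1.0
        assert complex_sv_fraction(svs, [])[0]["s"] == 0.0
        assert complex_sv_fraction([], ev)[1] is None

    def test_genome_density_tiling(self):
        ev = [ComplexEvent("s", "ecDNA", (("chr1", 500_000, 3_000_000),))]
        dens = genome_density(ev, {"chr1": 10_000_000})
        rows = dens[dens.event_class == "ecDNA"]
        assert sorted(rows.bin_start) == [0, 1_000_000, 2_000_000]
        assert genome_density([], {"chr1": 10_000_000}).empty

    def test_genome_density_matches_brute_force(self, rng):
        lengths = {"chr1": 10_000_000, "chr2": 5_000_000}
        events = []
        for i in range(25):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, lengths[chrom] - 10_000))
            e = s + int(rng.integers(1_000, 4_000_000))
            events.append(ComplexEvent(f"s{i}", "rigma",
                                       ((chrom, s, min(e, lengths[chrom])),)))
        dens = genome_density(events, lengths)
        for chrom, clen in lengths.items():
            for b in range(0, clen, 1_000_000):
                expected = sum(1 for ev in events for c, s, e in ev.intervals
                               if c == chrom and s < b + 1_000_000 and e > b)
                row = dens[(dens.chrom == chrom) & (dens.bin_start == b)]
                got = int(row["count"].iloc[0]) if len(row) else 0
                assert got == expected
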