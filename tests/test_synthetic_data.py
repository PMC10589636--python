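"""Generator correctness: determinism, round-trips, planted-feature recovery
and validity of every emitted format."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mutscenarios import variant_io as vio
from mutscenarios.catalogs import build_catalog, classify_indel, classify_sbs
from mutscenarios.cna_topography import classify_segment
from mutscenarios.consensus_sv import consensus_merge
from mutscenarios.rearrangement_topography import (detect_clustered_rearrangements,
                                                   detect_kataegis)
from mutscenarios.synthetic_data import (DEFAULT_CALLERS, GenomeSequence,
                                         SvSimConfig,
                                         bundled_reference_signatures,
                                         build_indel_pools, make_reference,
                                         simulate_cna, simulate_cohort,
                                         simulate_indels, simulate_kataegis,
                                         simulate_snvs, simulate_svs)

CHROMS = {"chr1": 150_000, "chr2": 100_000}
COHORT_CHROMS = {"chr1": 400_000, "chr2": 300_000, "chr3": 200_000}


class TestMakeReference:
    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        g1, _ = make_reference(CHROMS, seed=5)
        g2, _ = make_reference(CHROMS, seed=5)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        g1.write_fasta(p1)
        g2.write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()
        g3, _ = make_reference(CHROMS, seed=6)
        assert g3.sequences != g1.sequences

    def test_zero_density_pure_iid(self):
        g, report = make_reference(CHROMS, homopolymer_density=0.0,
                                   repeat_density=0.0, seed=1)
        assert report["homopolymers"] == 0 and report["tandem_repeats"] == 0

    def test_planted_counts_match_report(self):
        _, report = make_reference({"chr1": 1_000_000}, homopolymer_density=0.5,
                                   repeat_density=0.2, seed=2)
        assert report["homopolymers"] == 500
        assert report["tandem_repeats"] == 200

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            make_reference({"chr1": 5_000}, seed=0)

    def test_fasta_round_trip_via_pyfaidx(self, tmp_path):
        g, _ = make_reference(CHROMS, seed=7)
        path = tmp_path / "ref.fa"
        g.write_fasta(path)
        back = GenomeSequence.from_fasta(path)
        assert back.sequences == g.sequences


class TestSimulateSnvs:
    def test_round_trip_classification_exact(self, small_genome):
        sigs = bundled_reference_signatures("SBS96")
        expo = pd.DataFrame([[120, 90, 60, 30]] * 2, index=["a", "b"],
                            columns=sigs.names)
        recs, truth = simulate_snvs(small_genome, sigs, expo, seed=1)
        cat = build_catalog(recs, "SBS96", small_genome)
        assert (cat.counts.loc[truth.index].to_numpy() == truth.to_numpy()).all()

    def test_expected_total_matches_exposure_sum(self, small_genome):
        sigs = bundled_reference_signatures("SBS96")
        expo = pd.DataFrame([[200, 100, 50, 50]], index=["a"], columns=sigs.names)
        recs, _ = simulate_snvs(small_genome, sigs, expo, seed=2)
        assert len(recs) == 400

    def test_positions_unique_per_sample(self, small_genome):
        sigs = bundled_reference_signatures("SBS96")
        expo = pd.DataFrame([[300, 200, 100, 100]], index=["a"], columns=sigs.names)
        recs, _ = simulate_snvs(small_genome, sigs, expo, seed=3)
        keys = [(r.chrom, r.pos) for r in recs]
        assert len(keys) == len(set(keys))


class TestSimulateIndels:
    def test_round_trip_classification(self, small_genome):
        sigs = bundled_reference_signatures("ID83")
        expo = pd.DataFrame((sigs.W.to_numpy() @ np.array([[60, 40, 30]]).T).T,
                            index=["a"], columns=list(sigs.W.index))
        recs, truth = simulate_indels(small_genome, expo, seed=4)
        assert len(recs) == int(truth.loc["a"].sum())
        mismatches = sum(
            classify_indel(r, small_genome) is None for r in recs)
        cat = build_catalog(recs, "ID83", small_genome)
        agree = (cat.counts.loc["a"].to_numpy() == truth.loc["a"].to_numpy()).all()
        assert agree and mismatches == 0

    def test_empty_pool_channel_is_parameter_error(self):
        g, _ = make_reference({"chr1": 20_000}, homopolymer_density=0.0,
                              repeat_density=0.0, seed=9)
        pools = build_indel_pools(g, n_proposals=50, seed=0)
        missing = next(c for c in
                       ["1:Del:C:5", "5:Del:M:5", "1:Ins:T:5"] if c not in pools)
        expo = pd.DataFrame(0.0, index=["a"],
                            columns=[missing])
        with pytest.raises(ValueError, match="eligible"):
            simulate_indels(g, expo.assign(**{missing: 10.0}), seed=0, pools=pools)


class TestSimulateSvs:
    def test_caller_dropout_bookkeeping(self):
        cfg = SvSimConfig(n_background=30, caller_dropout={
            "delly": 0.3, "novobreak": 0.3, "svaba": 0.3})
        callsets, truth = simulate_svs(CHROMS, ["s"], cfg=cfg, seed=5)
        n_true = len(truth["true_svs"]["s"])
        consensus = consensus_merge(callsets, insertion_exception="svaba")
        # every consensus record arises from >=2 callers (or the INS caller)
        for c in consensus:
            assert len(c.callers) >= 2 or c.record.svclass == "INS"
        assert len(consensus) <= n_true

    def test_planted_cluster_recovered(self):
        chroms = {"chr1": 30_000_000, "chr2": 5_000_000}
        clusters = {"s": [("chr1", 10_000_000, 15_000_000, 12)]}
        callsets, _ = simulate_svs(chroms, ["s"], cfg=SvSimConfig(n_background=5),
                                   planted_clusters=clusters, seed=6)
        consensus = consensus_merge(callsets, insertion_exception="svaba")
        events = detect_clustered_rearrangements(consensus)
        covering = [ev for ev in events for c, s, e in ev.intervals
                    if c == "chr1" and s < 15_000_000 and e > 10_000_000]
        assert covering

    def test_jitter_within_consensus_window(self):
        callsets, truth = simulate_svs(CHROMS, ["s"],
                                       cfg=SvSimConfig(n_background=20), seed=7)
        true_set = truth["true_svs"]["s"]
        for caller, recs in callsets.items():
            for r in recs:
                assert any(abs(r.pos1 - t[1]) <= 150 and abs(r.pos2 - t[3]) <= 151
                           for t in true_set
                           if (t[0], t[2], t[4]) == (r.chrom1, r.chrom2, r.svclass))


class TestSimulateCna:
    def test_planted_states_classified_by_construction(self):
        planted = {"s": [("chr1", 10_000, 30_000, "gain"),
                         ("chr1", 50_000, 80_000, "amplification"),
                         ("chr2", 0, 40_000, "loss"),
                         ("chr2", 60_000, 80_000, "homozygous_deletion")]}
        segs, _truth = simulate_cna(CHROMS, planted, ploidy=2.0)
        by_span = {(s.chrom, s.start, s.end): s for s in segs}
        for chrom, start, end, state in planted["s"]:
            st = classify_segment(by_span[(chrom, start, end)], 2.0)
            assert st.state == state
        # all records valid and non-overlapping per chromosome
        for s in segs:
            assert s.end > s.start

    def test_loh_plant_sets_flag(self):
        segs, _ = simulate_cna(CHROMS, {"s": [("chr1", 0, 50_000, "loh")]})
        st = classify_segment(next(x for x in segs if x.start == 0 and x.chrom == "chr1"),
                              2.0)
        assert st.loh


class TestKataegisPlant:
    def test_planted_cluster_detected(self, small_genome):
        rng = np.random.default_rng(8)
        recs, (chrom, start, end) = simulate_kataegis(small_genome, "s", rng)
        clusters = detect_kataegis(recs)
        assert len(clusters) == 1
        assert clusters[0].start == start and clusters[0].end == end


class TestCohort:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        return simulate_cohort(n_per_group=4, seed=21, chrom_lengths=COHORT_CHROMS,
                               indel_pool_proposals=12_000)

    def test_group_labels_and_metadata(self, cohort):
        assert len(cohort.samples) == 12
        groups = {s.risk_group for s in cohort.samples}
        assert groups == {"HR_MNA", "HR_nonMNA", "nonHR"}

    def test_written_cohort_passes_validation_round_trip(self, cohort, tmp_path):
        from mutscenarios.pipeline import load_cohort

        out = tmp_path / "cohort"
        cohort.write(out)
        back = load_cohort(out)
        assert len(back.samples) == len(cohort.samples)
        assert len(back.snvs) == len(cohort.snvs)
        assert len(back.indels) == len(cohort.indels)
        assert {c: len(v) for c, v in back.sv_callsets.items()} == \
            {c: len(v) for c, v in cohort.sv_callsets.items()}
        assert len(back.external_events) == len(cohort.external_events)

    def test_same_seed_byte_identical_cohort_directory(self, tmp_path):
        a = simulate_cohort(n_per_group=2, seed=33, chrom_lengths=CHROMS,
                            indel_pool_proposals=6_000)
        b = simulate_cohort(n_per_group=2, seed=33, chrom_lengths=CHROMS,
                            indel_pool_proposals=6_000)
        da, db = tmp_path / "a", tmp_path / "b"
        a.write(da)
        b.write(db)
        files_a = sorted(p.relative_to(da) for p in da.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(db) for p in db.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (da / rel).read_bytes() == (db / rel).read_bytes(), rel

    def test_truth_supports_recovery_scoring(self, cohort):
        t = cohort.truth
        assert set(t.labels) == {s.sample_id for s in cohort.samples}
        assert t.sbs_exposures.shape[1] == 4
        # channel-count truth equals the reclassified catalog once the
        # kataegis SNVs (recorded by exact position) are removed
        kat = {(s, lo["chrom"], p) for s, loci in t.kataegis_loci.items()
               for lo in loci for p in lo["positions"]}
        cat = build_catalog(
            [s for s in cohort.snvs
             if (s.sample_id, s.chrom, s.pos) not in kat],
            "SBS96", cohort.genome, samples=list(t.sbs_channel_counts.index))
        assert (cat.counts.to_numpy() == t.sbs_channel_counts.to_numpy()).all()
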