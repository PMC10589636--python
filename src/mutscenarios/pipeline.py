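"""End-to-end orchestration: cohort -> consensus -> catalogs -> exposures ->
topography -> scenario clustering, programmatically or from an on-disk
cohort directory.

Stage defaults carry the analysis thresholds: 500 bp consensus window with
2-of-3 callers, 10 breakpoints / 1 Mb clustered-SV flag, 10 / 10 Mb
clustered rearrangements, kataegis 6 SNVs under 1 kb, gain/loss log2
thresholds +/-0.3, amplification 1.25, cohort exposure filter 5%, scenario
k = 3 with defining-feature threshold 0.3.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, variant_io
from .catalogs import MutationCatalog, build_catalog
from .cna_topography import classify_segment
from .consensus_sv import consensus_merge, qc_exclude_hypermutated
from .rearrangement_topography import (ComplexEvent, chromothripsis_filters,
                                       complex_sv_fraction,
                                       detect_clustered_rearrangements,
                                       detect_kataegis, merge_complex_calls,
                                       read_complex_events)
from .scenarios import (assemble_features, concordance, defining_features,
                        hkmeans, select_k)
from .signature_inference import fit_exposures
from .subclonal_trajectories import bin_by_ccf, trajectory
from .synthetic_data import (Cohort, CohortTruth, GenomeSequence,
                             bundled_reference_signatures, simulate_cohort)

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "consensus": {"min_callers": 2, "window": 500, "insertion_exception": "svaba",
                  "qc_fold": 5.0},
    "catalogs": {"clustered_window": 1_000_000, "clustered_min_breakpoints": 10},
    "signatures": {"cohort_min_fraction": 0.05, "cosine_threshold": 0.85,
                   "n_iterations": 500, "k_candidates": [4, 5, 6]},
    "cna": {"gain_thresh": 0.3, "amp_thresh": 1.25},
    "topography": {"kataegis_min_run": 6, "kataegis_max_imd": 1000,
                   "clustered_window": 10_000_000, "clustered_min_breakpoints": 10,
                   "merge_overlap": 0.5, "alpha": 0.05},
    "trajectories": {"enabled": True, "n_bins": 5, "min_per_bin": 30},
    "scenarios": {"k": 3, "define_threshold": 0.3, "select_k": False,
                  "k_range": [1, 2, 3, 4, 5, 6], "gap_B": 25},
}


def _merged_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, vals in (overrides or {}).items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(vals, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        cfg[section].update(vals)
    return cfg


@dataclass
class AnalysisResult:
    consensus: list
    excluded_samples: list[str]
    catalogs: dict[str, MutationCatalog]
    exposures: dict[str, pd.DataFrame]  # relative exposures per scheme
    cna_states: list
    kataegis: list
    events: list[ComplexEvent]
    chromothripsis: list
    complex_fraction: tuple
    features: object
    scenario: object
    suggested_k: int | None = None
    gap_report: pd.DataFrame | None = None
    trajectories: pd.DataFrame | None = None


def analyze_cohort(cohort: Cohort, seed: int = 0,
                   config: dict | None = None,
                   compute_select_k: bool = False) -> AnalysisResult:
    """Run every pipeline stage on an in-memory cohort."""
    cfg = _merged_config(config)

    # --- consensus SV calling and cohort QC -------------------------------
    ccfg = cfg["consensus"]
    consensus = consensus_merge(cohort.sv_callsets,
                                min_callers=ccfg["min_callers"],
                                window=ccfg["window"],
                                insertion_exception=ccfg["insertion_exception"])
    counts = {s.sample_id: 0 for s in cohort.samples}
    for c in consensus:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    excluded, _median = qc_exclude_hypermutated(counts, fold=ccfg["qc_fold"])
    if excluded:
        log.info("QC excluded hypermutated samples: %s", excluded)
    keep = [s.sample_id for s in cohort.samples if s.sample_id not in excluded]
    consensus = [c for c in consensus if c.sample_id in set(keep)]
    snvs = [r for r in cohort.snvs if r.sample_id not in set(excluded)]
    indels = [r for r in cohort.indels if r.sample_id not in set(excluded)]

    # --- catalogs ---------------------------------------------------------
    kcfg = cfg["catalogs"]
    cat_sbs = build_catalog(snvs, "SBS96", cohort.genome, samples=keep)
    cat_id = build_catalog(indels, "ID83", cohort.genome, samples=keep)
    cat_sv = build_catalog(consensus, "SV38", samples=keep,
                           clustered_window=kcfg["clustered_window"],
                           clustered_min_breakpoints=kcfg["clustered_min_breakpoints"])

    # --- supervised exposures on the bundled reference sets ---------------
    exposures: dict[str, pd.DataFrame] = {}
    for scheme, cat in (("SBS96", cat_sbs), ("ID83", cat_id), ("SV38", cat_sv)):
        sigs = bundled_reference_signatures(scheme)
        expo = fit_exposures(cat, sigs)
        exposures[scheme] = expo.relative

    # --- CNA states -------------------------------------------------------
    ncfg = cfg["cna"]
    ploidy = {s.sample_id: s.ploidy for s in cohort.samples}
    cna_states = [classify_segment(seg, ploidy.get(seg.sample_id, 2.0),
                                   gain_thresh=ncfg["gain_thresh"],
                                   amp_thresh=ncfg["amp_thresh"])
                  for seg in cohort.cna_segments if seg.sample_id in set(keep)]

    # --- topography -------------------------------------------------------
    tcfg = cfg["topography"]
    kataegis = detect_kataegis(snvs, min_run=tcfg["kataegis_min_run"],
                               max_imd=tcfg["kataegis_max_imd"])
    chromo = []
    for sample in keep:
        chromo.extend(chromothripsis_filters(consensus, cna_states, sample,
                                             alpha=tcfg["alpha"]))
    chromo_events = [
        ComplexEvent(sample_id=c.sample_id, event_class="chromothripsis",
                     intervals=((c.chrom, max(0, c.region[0] - 1), c.region[1]),),
                     source="chromothripsis-filter")
        for c in chromo if c.confidence in ("high", "low")]
    known = list(cohort.external_events) + chromo_events
    clustered = detect_clustered_rearrangements(
        consensus, window=tcfg["clustered_window"],
        min_breakpoints=tcfg["clustered_min_breakpoints"], known_events=known)
    events = merge_complex_calls(known + clustered,
                                 min_reciprocal_overlap=tcfg["merge_overlap"])
    frac = complex_sv_fraction(consensus, events)

    # --- subclonal trajectories ------------------------------------------
    traj_df = None
    jcfg = cfg["trajectories"]
    if jcfg["enabled"]:
        sbs_sigs = bundled_reference_signatures("SBS96")
        frames = []
        by_sample: dict[str, list] = {}
        for r in snvs:
            if r.ccf is not None:
                by_sample.setdefault(r.sample_id, []).append(r)
        for sample in keep:
            recs = by_sample.get(sample, [])
            if len(recs) < 2 * jcfg["min_per_bin"]:
                continue
            bins = bin_by_ccf(recs, n_bins=jcfg["n_bins"],
                              min_per_bin=jcfg["min_per_bin"])
            t, _end = trajectory(bins, sbs_sigs, cohort.genome)
            t.insert(0, "sample_id", sample)
            frames.append(t)
        traj_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    # --- scenarios --------------------------------------------------------
    scfg = cfg["scenarios"]
    features = assemble_features(exposures, events)
    suggested_k = None
    gap_report = None
    if compute_select_k or scfg["select_k"]:
        gap_report, suggested_k = select_k(features.scaled,
                                          k_range=scfg["k_range"],
                                          B=scfg["gap_B"], seed=seed)
    scenario = hkmeans(features.scaled, k=scfg["k"], seed=seed)
    scenario.defining_features = defining_features(scenario.centroids,
                                                   threshold=scfg["define_threshold"])
    labels = pd.Series({s.sample_id: s.risk_group for s in cohort.samples
                        if s.sample_id in set(keep)})
    conc, crosstab = concordance(scenario.assignment, labels)
    scenario.concordance = conc
    scenario.label_crosstab = crosstab

    return AnalysisResult(
        consensus=consensus, excluded_samples=excluded,
        catalogs={"SBS96": cat_sbs, "ID83": cat_id, "SV38": cat_sv},
        exposures=exposures, cna_states=cna_states, kataegis=kataegis,
        events=events, chromothripsis=chromo, complex_fraction=frac,
        features=features, scenario=scenario,
        suggested_k=suggested_k, gap_report=gap_report, trajectories=traj_df)


# ---------------------------------------------------------------------------
# disk-based orchestration
# ---------------------------------------------------------------------------

def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a cohort directory written by ``Cohort.write`` (or assembled by
    hand in the same layout)."""
    d = Path(cohort_dir)
    genome = GenomeSequence.from_fasta(d / "reference.fa")
    samples = variant_io.read_sample_table(d / "samples.tsv")
    known = list(genome.lengths)
    snvs, indels = [], []
    for vcf in sorted((d / "vcf").glob("*.vcf")):
        sample = vcf.stem
        snvs.extend(variant_io.read_snv_vcf(vcf, sample, known_chroms=known))
        indels.extend(variant_io.read_indel_vcf(vcf, sample, known_chroms=known))
    callsets = {}
    for bedpe in sorted((d / "sv").glob("*.bedpe")):
        callsets[bedpe.stem] = variant_io.read_sv_table(bedpe, "bedpe",
                                                        caller=bedpe.stem,
                                                        known_chroms=known)
    cna = variant_io.read_cna_segments(d / "cna.tsv", known_chroms=known)
    events = read_complex_events(d / "events.tsv") if (d / "events.tsv").exists() else []
    truth_path = d / "truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth = CohortTruth(
            seed=raw.get("seed", 0), labels=raw.get("labels", {}),
            sbs_exposures=pd.DataFrame.from_dict(raw.get("sbs_exposures", {}), orient="index"),
            sbs_channel_counts=pd.DataFrame.from_dict(raw.get("sbs_channel_counts", {}),
                                                      orient="index").fillna(0),
            id_channel_counts=pd.DataFrame.from_dict(raw.get("id_channel_counts", {}),
                                                     orient="index").fillna(0),
            sv_truth=raw.get("sv_truth", {}), planted_events=raw.get("planted_events", []),
            kataegis_loci=raw.get("kataegis_loci", {}), cna_truth=raw.get("cna_truth", {}),
            subclonal_switch_groups=raw.get("subclonal_switch_groups", {}))
    else:
        truth = CohortTruth(seed=0, labels={}, sbs_exposures=pd.DataFrame(),
                            sbs_channel_counts=pd.DataFrame(),
                            id_channel_counts=pd.DataFrame(), sv_truth={},
                            planted_events=[], kataegis_loci={}, cna_truth={},
                            subclonal_switch_groups={})
    return Cohort(genome=genome, chrom_lengths=dict(genome.lengths),
                  samples=samples, snvs=snvs, indels=indels,
                  sv_callsets=callsets, cna_segments=cna,
                  external_events=events, truth=truth)


def run_pipeline(cohort_dir: str | Path, out_dir: str | Path, seed: int = 0,
                 config: dict | None = None) -> AnalysisResult:
    """Run all stages from a cohort directory and write TSV/JSON artifacts
    plus a manifest (versions, seed, parameter hash; no timestamps, so
    reruns with the same inputs are byte-identical)."""
    cfg = _merged_config(config)
    cohort = load_cohort(cohort_dir)
    result = analyze_cohort(cohort, seed=seed, config=config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    variant_io.write_sv_bedpe(
        [c.record for c in result.consensus], out / "consensus.bedpe",
        extra={"supporting_callers": [";".join(c.callers) for c in result.consensus],
               "n_callers": [len(c.callers) for c in result.consensus],
               "pass_any": [c.pass_any for c in result.consensus]})
    for scheme, cat in result.catalogs.items():
        cat.to_tsv(out / f"catalog_{scheme.lower()}.tsv")
    for scheme, rel in result.exposures.items():
        rel.rename_axis("sample").to_csv(out / f"exposures_{scheme.lower()}.tsv", sep="\t")
    pd.DataFrame([{
        "sample_id": st.segment.sample_id, "chrom": st.segment.chrom,
        "start": st.segment.start, "end": st.segment.end,
        "cn_major": st.segment.cn_major, "cn_minor": st.segment.cn_minor,
        "state": st.state, "loh": st.loh,
        "log2_ratio": round(st.log2_ratio, 4)} for st in result.cna_states
    ]).to_csv(out / "cna_states.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "sample_id": k.sample_id, "chrom": k.chrom, "start": k.start,
        "end": k.end, "n_snvs": k.n_snvs, "max_imd": k.max_imd}
        for k in result.kataegis],
        columns=["sample_id", "chrom", "start", "end", "n_snvs", "max_imd"],
    ).to_csv(out / "kataegis.tsv", sep="\t", index=False)
    from .rearrangement_topography import write_complex_events
    write_complex_events(result.events, out / "complex_events.tsv")
    if result.trajectories is not None:
        result.trajectories.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    result.features.raw.rename_axis("sample").to_csv(out / "features.tsv", sep="\t")
    result.scenario.assignment.rename_axis("sample").to_csv(out / "assignment.tsv", sep="\t")
    result.scenario.centroids.rename_axis("cluster").to_csv(out / "centroids.tsv", sep="\t")
    (out / "defining_features.json").write_text(json.dumps(
        {str(k): v for k, v in result.scenario.defining_features.items()},
        indent=1, sort_keys=True))
    result.scenario.label_crosstab.to_csv(out / "crosstab.tsv", sep="\t")

    per_sample_frac, cohort_frac = result.complex_fraction
    summary = {
        "n_samples": len(cohort.samples),
        "excluded_samples": result.excluded_samples,
        "n_consensus_svs": len(result.consensus),
        "n_kataegis": len(result.kataegis),
        "n_complex_events": len(result.events),
        "complex_sv_fraction_cohort": cohort_frac,
        "scenario_concordance": result.scenario.concordance,
        "suggested_k": result.suggested_k,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "package": "mutscenarios",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "stages": ["consensus", "catalogs", "signatures", "cna", "topography",
                   "trajectories" if cfg["trajectories"]["enabled"] else None,
                   "scenarios"],
    }
    manifest["stages"] = [s for s in manifest["stages"] if s]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
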