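"""End-to-end orchestration on simulated or user-supplied inputs.

Runs the full chain: region universe -> taxonomy -> flanks ->
fragment filtering -> coverage -> normalization -> PCA -> SVM ->
enrichment thresholds -> element calls -> directional-transcription
filter, and scores the calls against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify, coverage, regions as reg_mod, simulate, txfilter


@dataclass
class PipelineResult:
    regions: pd.DataFrame
    taxonomy: pd.Series
    pca: classify.PcaModel
    svm: classify.ReferenceClassifier
    calls: pd.DataFrame          # pre-filter element calls
    filtered_calls: pd.DataFrame
    removal_report: pd.DataFrame
    enrichment: pd.DataFrame
    truth: pd.DataFrame | None = None


def _flank_sums(fragments_by_sample: dict, regions: pd.DataFrame
                ) -> pd.DataFrame:
    """Raw coverage summed over all non-control samples on the genomic
    left and right flanks (used to orient them)."""
    live = regions.loc[~regions["taxonomy"].str.startswith("discarded")]
    chroms = live["chrom"].to_numpy()
    left = np.zeros(len(live))
    right = np.zeros(len(live))
    for (mark, _rep), frag in fragments_by_sample.items():
        if mark == simulate.CONTROL_MARK:
            continue
        left += coverage._count_overlaps(
            frag, chroms, live["left_flank_start"].to_numpy(),
            live["left_flank_end"].to_numpy())
        right += coverage._count_overlaps(
            frag, chroms, live["right_flank_start"].to_numpy(),
            live["right_flank_end"].to_numpy())
    return pd.DataFrame({"left": left, "right": right},
                        index=pd.Index(live["region_id"], name="region_id"))


def run_classification(region_table: pd.DataFrame,
                       fragments_by_sample: dict,
                       selected_tss: pd.DataFrame,
                       isoform_tss: pd.DataFrame,
                       genes_per_chrom: dict[str, int],
                       chromosome_lengths: dict[str, int]
                       ) -> tuple[pd.DataFrame, dict]:
    """Shared front half: taxonomy, flanks, orientation, coverage,
    PCA + SVM + enrichment + calls. Returns (regions, artifacts)."""
    regions = reg_mod.classify_taxonomy(region_table, selected_tss,
                                        isoform_tss, genes_per_chrom)
    regions = reg_mod.build_flanks(regions, chromosome_lengths)

    filtered = {key: coverage.filter_fragments(frame)
                for key, frame in fragments_by_sample.items()}
    sums = _flank_sums(filtered, regions)
    regions = reg_mod.orient_flanks(regions, sums)

    raw = coverage.count_coverage(filtered, regions,
                                  known_chroms=set(chromosome_lengths))
    pooled = coverage.pool_replicates(raw)
    norm_pooled = coverage.normalize_log2_rpk500(pooled)

    taxonomy = regions.set_index("region_id")["taxonomy"] \
        .reindex(norm_pooled.counts.index)
    pca = classify.fit_pca(norm_pooled)
    svm = classify.fit_reference_classifier(pca, taxonomy)
    svm_labels = classify.predict_all(svm, pca)
    enrichment = coverage.enrichment_over_control(pooled)
    calls = classify.call_elements(svm_labels, enrichment, taxonomy, pooled)
    artifacts = {"pca": pca, "svm": svm, "svm_labels": svm_labels,
                 "enrichment": enrichment, "calls": calls,
                 "pooled": pooled, "taxonomy": taxonomy, "raw": raw}
    return regions, artifacts


def run_synthetic(config: simulate.SimulationConfig | None = None,
                  spec: simulate.SyntheticGenomeSpec | None = None,
                  profiles: dict | None = None,
                  stage: str = "dome") -> PipelineResult:
    """Generate a synthetic study and run the full pipeline on it."""
    config = config or simulate.SimulationConfig()
    profiles = profiles or simulate.default_profiles()
    if spec is None:
        n_prom = sum(n for c, n in config.class_counts().items()
                     if c.endswith("promoter"))
        spec = simulate.default_genome_spec(
            n_genes=max(int(n_prom / 0.8) + 40, 60), seed=config.seed)
    chrom_lengths = dict(spec.chromosomes)

    tss_table, exons, _expr = simulate.generate_annotation(spec, config.seed)
    candidates = tss_table.rename(columns={"source": "source"})
    selected = reg_mod.select_promoter_tss(candidates)
    truth = simulate.generate_regions(spec, config)

    cov_config = config if stage in config.stages else \
        simulate.SimulationConfig(**{**config.__dict__, "stages": (stage,)})
    fragments, _spikes = simulate.simulate_coverage(
        truth, profiles, cov_config, chrom_lengths)
    stage_frags = {(mark, rep): frame
                   for (st, mark, rep), frame in fragments.items()
                   if st == stage}

    region_table = truth[["region_id", "chrom", "start", "end", "source"]]
    regions, art = run_classification(
        region_table, stage_frags, selected, tss_table[["chrom", "pos"]],
        spec.genes_per_chrom(), chrom_lengths)

    rna_reads, rna_libs = simulate.simulate_rna_flanks(truth, config)
    flank_cov = txfilter.compute_flank_coverage(rna_reads, regions, rna_libs)
    flagged = txfilter.detect_directional_tss(flank_cov)
    exempt = txfilter.exonic_flank_mask(regions, exons)
    calls = art["calls"].set_index(art["calls"].index)
    filtered_calls, report = txfilter.apply_filter(calls, flagged, exempt)

    return PipelineResult(
        regions=regions, taxonomy=art["taxonomy"], pca=art["pca"],
        svm=art["svm"], calls=calls, filtered_calls=filtered_calls,
        removal_report=report, enrichment=art["enrichment"], truth=truth)


def score_recovery(result: PipelineResult) -> dict:
    """Sensitivity and precision of the planted enhancer classes, and
    the recall of cryptic-TSS contaminant removal.

    Sensitivity/precision are computed on non-contaminant regions
    against the planted chromatin class; a contaminant counts as
    removed if it is absent from the final enhancer calls (whether
    dropped by the transcription filter or never called).
    """
    truth = result.truth.set_index("region_id")
    final = result.filtered_calls["call"]
    out = {}
    for cls in ("H3K4me1-enhancer", "H3K4me2-enhancer"):
        planted = truth.index[(truth["true_class"] == cls) &
                              ~truth["is_cryptic_tss"]]
        called = final.index[final == cls]
        tp = len(set(planted) & set(called))
        out[f"{cls}:sensitivity"] = tp / len(planted) if len(planted) else \
            float("nan")
        out[f"{cls}:precision"] = (
            sum(truth.loc[c, "true_class"] == cls for c in called) /
            len(called)) if len(called) else float("nan")
    cryptic = truth.index[truth["is_cryptic_tss"]]
    if len(cryptic):
        enh_final = set(final.index[final.isin(
            ["H3K4me1-enhancer", "H3K4me2-enhancer"])])
        removed = sum(c not in enh_final for c in cryptic)
        out["cryptic:removal_recall"] = removed / len(cryptic)
    else:
        out["cryptic:removal_recall"] = float("nan")
    return out
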