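"""Directional-transcription filter for putative enhancers.

Some accessible regions called as enhancers are in fact unannotated
gene TSSs. These betray themselves by stable, strand-biased RNA-seq
coverage immediately flanking the open interval: a (+)-strand gene TSS
shows downstream (+)-strand coverage of at least 1 RPKM that is at
least twice the upstream (+)-strand coverage, in at least two
developmental stages (and symmetrically for the (-) strand). Regions
whose 100-bp flanks lie entirely within an annotated exon are exempt
(their RNA signal is attributable to the surrounding gene). Flagged,
non-exempt regions are removed from both enhancer classes.

Upstream/downstream here are in genomic coordinates (left/right), not
the coverage-oriented flanks used for chromatin features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RNA_FLANK_BP = 100
MIN_RPKM = 1.0
MIN_RATIO = 2.0
MIN_STAGES = 2


def compute_flank_coverage(stranded_counts: dict[tuple[str, str], pd.DataFrame],
                           regions: pd.DataFrame,
                           library_sizes: dict[tuple[str, str], float],
                           flank_bp: int = RNA_FLANK_BP) -> pd.DataFrame:
    """Strand-specific RPKM in the 100-bp windows flanking each region.

    ``stranded_counts`` maps (stage, strand) to a DataFrame of read
    intervals (chrom, start, end); ``library_sizes`` maps the same keys
    to total mapped reads. Returns a long table with columns region_id,
    stage, plus_up, plus_down, minus_up, minus_down (RPKM).
    """
    from .coverage import _count_overlaps

    reg = regions.loc[~regions["taxonomy"].str.startswith("discarded")] \
        if "taxonomy" in regions.columns else regions
    chroms = reg["chrom"].to_numpy()
    up_s = reg["start"].to_numpy() - flank_bp
    up_e = reg["start"].to_numpy()
    dn_s = reg["end"].to_numpy()
    dn_e = reg["end"].to_numpy() + flank_bp

    stages = sorted({stage for stage, _ in stranded_counts})
    rows = []
    for stage in stages:
        vals = {}
        for strand, key in (("plus", "+"), ("minus", "-")):
            frame = stranded_counts[(stage, key)]
            lib = library_sizes[(stage, key)]
            scale = 1.0 / (flank_bp / 1000.0) / (lib / 1e6)
            vals[f"{strand}_up"] = _count_overlaps(frame, chroms, up_s, up_e) * scale
            vals[f"{strand}_down"] = _count_overlaps(frame, chroms, dn_s, dn_e) * scale
        rows.append(pd.DataFrame(
            {"region_id": reg["region_id"].to_numpy(), "stage": stage, **vals}))
    return pd.concat(rows, ignore_index=True)


def detect_directional_tss(flank_coverage: pd.DataFrame,
                           min_rpkm: float = MIN_RPKM,
                           min_ratio: float = MIN_RATIO,
                           min_stages: int = MIN_STAGES) -> set[str]:
    """Regions with directional RNA-seq signal in >= 2 stages.

    (+)-strand: downstream (+) coverage >= 1 RPKM and >= 2x the
    upstream (+) coverage. (-)-strand: upstream (-) coverage >= 1 RPKM
    and >= 2x the downstream (-) coverage. Zero opposite-flank coverage
    qualifies (the ratio is +inf). A region is flagged if either strand
    qualifies in at least two stages.
    """
    fc = flank_coverage
    n_stages = fc["stage"].nunique()
    if n_stages < min_stages:
        raise ValueError(f"need >= {min_stages} stages, got {n_stages}")
    plus = (fc["plus_down"] >= min_rpkm) & \
        (fc["plus_down"] >= min_ratio * fc["plus_up"])
    minus = (fc["minus_up"] >= min_rpkm) & \
        (fc["minus_up"] >= min_ratio * fc["minus_down"])
    flagged = set()
    for name, hit in (("plus", plus), ("minus", minus)):
        per_region = fc.loc[hit.to_numpy(), "region_id"].value_counts()
        flagged.update(per_region[per_region >= min_stages].index)
    return flagged


def exonic_flank_mask(regions: pd.DataFrame,
                      exons: pd.DataFrame,
                      flank_bp: int = RNA_FLANK_BP) -> set[str]:
    """Regions exempt from TSS flagging because a 100-bp flank lies
    entirely within a single annotated exon.

    ``exons`` needs columns chrom, start, end. Containment is strict:
    partial overlap does not exempt.
    """
    exempt = set()
    ex_by_chrom = {c: g for c, g in exons.groupby("chrom")}
    for _, r in regions.iterrows():
        ex = ex_by_chrom.get(r["chrom"])
        if ex is None:
            continue
        for fs, fe in ((r["start"] - flank_bp, r["start"]),
                       (r["end"], r["end"] + flank_bp)):
            if ((ex["start"] <= fs) & (ex["end"] >= fe)).any():
                exempt.add(r["region_id"])
                break
    return exempt


def apply_filter(calls: pd.DataFrame,
                 flagged: set[str],
                 exempt: set[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove flagged, non-exempt regions from both enhancer classes.

    Returns (filtered calls, removal report). The report lists the
    removed ids and the per-class removed fraction. Pure set
    subtraction: retained and removed partition the input.
    """
    removable = (flagged - exempt)
    enhancer = calls["call"].isin(["H3K4me1-enhancer", "H3K4me2-enhancer"])
    remove = enhancer & calls.index.isin(removable)
    report_rows = []
    for cls in ("H3K4me1-enhancer", "H3K4me2-enhancer"):
        in_class = calls["call"] == cls
        n = int(in_class.sum())
        n_removed = int((in_class & remove).sum())
        report_rows.append({
            "call": cls, "n_input": n, "n_removed": n_removed,
            "fraction_removed": n_removed / n if n else 0.0,
            "removed_ids": ",".join(sorted(calls.index[in_class & remove]))})
    filtered = calls.loc[~remove].copy()
    return filtered, pd.DataFrame(report_rows)
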