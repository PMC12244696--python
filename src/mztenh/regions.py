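"""Region universe construction.

Merges open-chromatin interval sets from two sources, selects one
promoter TSS per gene from CAGE-supported candidates, assigns the
promoter / TSS-proximal / distal taxonomy, and builds the 500-bp flanks
used for coverage quantification.

Coordinates are 0-based half-open (BED convention) throughout. The
distance between a region and a TSS is 0 if the TSS position falls
inside [start, end), else the base-pair distance to the nearer of the
two terminal bases, min(|start - tss|, |tss - (end - 1)|).
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FLANK_BP = 500
DISTAL_MIN_BP = 2_000
MIN_CAGE_TAGS = 20  # strict: a promoter TSS needs > 20 supporting tags

TAXONOMIES = ("promoter", "proximal", "distal",
              "discarded-scaffold", "discarded-no-flank")


def _dedup_source(df: pd.DataFrame, source: str) -> pd.DataFrame:
    dups = df.duplicated(subset=["chrom", "start", "end"])
    if dups.any():
        log.warning("%d duplicate identical intervals in %s source dropped",
                    int(dups.sum()), source)
    return df.loc[~dups].reset_index(drop=True)


def merge_region_sources(primary: pd.DataFrame,
                         secondary: pd.DataFrame) -> pd.DataFrame:
    """Merge two open-chromatin region sources into one named universe.

    All primary regions are kept, in input order, with ids atac_L00001...;
    secondary regions are appended (atac_P00001...) only if they overlap
    no primary region by >= 1 bp.

    Parameters
    ----------
    primary, secondary : DataFrames with columns chrom, start, end.
    """
    for df, name in ((primary, "primary"), (secondary, "secondary")):
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"invalid interval in {name} source")
    primary = _dedup_source(primary[["chrom", "start", "end"]].copy(), "primary")
    secondary = _dedup_source(secondary[["chrom", "start", "end"]].copy(),
                              "secondary")

    keep = np.ones(len(secondary), dtype=bool)
    for chrom, grp in secondary.groupby("chrom", sort=False):
        prim = primary[primary["chrom"] == chrom]
        if prim.empty:
            continue
        starts = prim["start"].to_numpy()
        ends = prim["end"].to_numpy()
        for i, (s, e) in enumerate(zip(grp["start"], grp["end"])):
            if ((starts < e) & (ends > s)).any():
                keep[grp.index[i]] = False
    secondary = secondary.loc[keep].reset_index(drop=True)

    primary = primary.assign(
        region_id=[f"atac_L{i + 1:05d}" for i in range(len(primary))],
        source="L")
    secondary = secondary.assign(
        region_id=[f"atac_P{i + 1:05d}" for i in range(len(secondary))],
        source="P")
    merged = pd.concat([primary, secondary], ignore_index=True)
    return merged[["region_id", "chrom", "start", "end", "source"]]


def select_promoter_tss(candidates: pd.DataFrame,
                        min_tags: int = MIN_CAGE_TAGS) -> pd.DataFrame:
    """Select one promoter TSS per gene.

    For genes in the primary annotation: the candidate with the maximal
    CAGE tag count, kept only if tag_count > ``min_tags`` (strict). Ties
    in tag count are broken toward the most 5' position on the gene
    strand. Genes present only in the secondary annotation contribute
    their TSS regardless of tag support.

    Parameters
    ----------
    candidates : DataFrame with columns gene_id, chrom, pos, strand,
        tag_count, source (``primary-annotation``/``secondary-annotation``).
    """
    rows = []
    for gene, grp in candidates.groupby("gene_id", sort=False):
        prim = grp[grp["source"] == "primary-annotation"]
        if prim.empty:
            # secondary-only gene: retain its TSS (most 5' if several)
            rows.append(_most_5prime(grp))
            continue
        best_tags = prim["tag_count"].max()
        if best_tags <= min_tags:
            continue
        rows.append(_most_5prime(prim[prim["tag_count"] == best_tags]))
    if not rows:
        return candidates.iloc[0:0].copy()
    return pd.DataFrame(rows).reset_index(drop=True)


def _most_5prime(grp: pd.DataFrame) -> pd.Series:
    strand = grp["strand"].iloc[0]
    idx = grp["pos"].idxmax() if strand == "-" else grp["pos"].idxmin()
    return grp.loc[idx]


def _nearest_tss_distance(start: int, end: int, positions: np.ndarray) -> int:
    """Distance from [start, end) to the nearest TSS position."""
    inside = (positions >= start) & (positions < end)
    if inside.any():
        return 0
    d = np.minimum(np.abs(start - positions), np.abs(positions - (end - 1)))
    return int(d.min())


def classify_taxonomy(regions: pd.DataFrame,
                      selected_tss: pd.DataFrame,
                      all_isoform_tss: pd.DataFrame,
                      genes_per_chrom: dict[str, int]) -> pd.DataFrame:
    """Assign the promoter / proximal / distal taxonomy.

    A region overlapping a selected promoter TSS is a promoter; else, if
    its distance to the nearest annotated TSS of any transcript isoform
    is < 2 kb it is TSS-proximal; regions >= 2 kb from every TSS are
    distal. Regions on chromosomes or scaffolds with zero annotated
    genes are discarded.

    ``all_isoform_tss`` needs columns chrom, pos.
    """
    regions = regions.copy()
    taxonomy = []
    sel_by_chrom = {c: g["pos"].to_numpy(dtype=np.int64)
                    for c, g in selected_tss.groupby("chrom")}
    iso_by_chrom = {c: np.sort(g["pos"].to_numpy(dtype=np.int64))
                    for c, g in all_isoform_tss.groupby("chrom")}
    for chrom, start, end in zip(regions["chrom"], regions["start"],
                                 regions["end"]):
        if genes_per_chrom.get(chrom, 0) == 0:
            taxonomy.append("discarded-scaffold")
            continue
        sel = sel_by_chrom.get(chrom)
        if sel is not None and ((sel >= start) & (sel < end)).any():
            taxonomy.append("promoter")
            continue
        iso = iso_by_chrom.get(chrom)
        if iso is None or iso.size == 0:
            taxonomy.append("distal")
            continue
        d = _nearest_tss_distance(int(start), int(end), iso)
        taxonomy.append("proximal" if d < DISTAL_MIN_BP else "distal")
    regions["taxonomy"] = taxonomy
    return regions


def build_flanks(regions: pd.DataFrame,
                 chromosome_lengths: dict[str, int],
                 flank_bp: int = FLANK_BP) -> pd.DataFrame:
    """Attach the two abutting 500-bp flanks to each surviving region.

    Regions where either flank would extend past a chromosome boundary
    are re-labelled ``discarded-no-flank``.
    """
    regions = regions.copy()
    left_start = regions["start"] - flank_bp
    right_end = regions["end"] + flank_bp
    lengths = regions["chrom"].map(chromosome_lengths)
    ok = (left_start >= 0) & (right_end <= lengths) & \
        ~regions["taxonomy"].str.startswith("discarded")
    no_flank = ((left_start < 0) | (right_end > lengths)) & \
        ~regions["taxonomy"].str.startswith("discarded")
    regions.loc[no_flank, "taxonomy"] = "discarded-no-flank"
    regions["left_flank_start"] = np.where(ok, left_start, -1)
    regions["left_flank_end"] = np.where(ok, regions["start"], -1)
    regions["right_flank_start"] = np.where(ok, regions["end"], -1)
    regions["right_flank_end"] = np.where(ok, right_end, -1)
    return regions


def orient_flanks(regions: pd.DataFrame,
                  flank_coverage_sums: pd.DataFrame) -> pd.DataFrame:
    """Label each region's higher-coverage flank as ``downstream``.

    ``flank_coverage_sums`` has index region_id and columns ``left`` /
    ``right`` holding total raw coverage summed over all marks and
    replicates. The flank with the larger sum becomes downstream; on a
    tie the genomic-right flank is downstream.

    Adds a ``downstream_is_right`` boolean column.
    """
    regions = regions.copy()
    sums = flank_coverage_sums.reindex(regions["region_id"])
    regions["downstream_is_right"] = (
        sums["right"].to_numpy() >= sums["left"].to_numpy())
    return regions


def region_ledger(regions: pd.DataFrame) -> pd.DataFrame:
    """Per-taxonomy bookkeeping of every region and discard reason."""
    counts = regions["taxonomy"].value_counts().reindex(
        TAXONOMIES, fill_value=0)
    return counts.rename_axis("taxonomy").to_frame("n_regions").reset_index()
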