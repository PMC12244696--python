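"""Fragment filtering and coverage quantification.

Consumes paired-end-derived fragment intervals (chrom, start, end per
sample), keeps mononucleosome-sized spans (140-250 bp), trims each to a
73-bp tag-centered window, removes exact duplicates, counts coverage on
each region's three subintervals (upstream flank, open-interval center,
downstream flank), and normalizes as log2 RPKM/2 -- i.e. reads per
500 bp per million filtered fragments ("RPK500"), with a pseudocount of
1. Replicates are pooled by summing raw counts and library sizes before
renormalization, and per-region fold enrichment of each mark over the
IgG control is computed on the combined center + downstream interval
with a ratio pseudocount of 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MONONUC_MIN = 140
MONONUC_MAX = 250
TRIM_BP = 73
RATIO_PSEUDOCOUNT = 0.1
SUBINTERVALS = ("upstream", "center", "downstream")


@dataclass
class CoverageMatrix:
    """Per-region x (mark, replicate, subinterval) coverage values.

    ``counts`` is indexed by region id with a 3-level column MultiIndex
    (mark, replicate, subinterval). ``library_sizes`` is indexed by
    (mark, replicate) and holds the total filtered fragment count per
    sample. ``lengths`` holds per-region subinterval lengths in bp.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    lengths: pd.DataFrame
    normalized: bool = False

    @property
    def marks(self) -> list[str]:
        return list(self.counts.columns.get_level_values(0).unique())

    def drop_marks(self, marks) -> "CoverageMatrix":
        keep = [m for m in self.marks if m not in set(marks)]
        return CoverageMatrix(
            self.counts.loc[:, keep],
            self.library_sizes.loc[self.library_sizes.index.get_level_values(0)
                                   .isin(keep)],
            self.lengths, self.normalized)


def filter_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    """Mononucleosome filter, tag-centered trim, duplicate removal.

    Keeps fragments whose span is 140-250 bp inclusive, replaces each by
    the 73-bp window centered on its midpoint ([mid - 36, mid + 37) for
    even midpoint splits, so every window is exactly 73 bp), and drops
    exact duplicates (same chrom/start/end), keeping the first in input
    order. Spans of exactly 73 bp are treated as already tag-centered
    and passed through unchanged, which makes the filter idempotent.
    """
    frag = fragments[["chrom", "start", "end"]].copy()
    span = frag["end"] - frag["start"]
    frag = frag.loc[((span >= MONONUC_MIN) & (span <= MONONUC_MAX)) |
                    (span == TRIM_BP)]
    mid = (frag["start"] + frag["end"]) // 2
    frag = frag.assign(start=mid - TRIM_BP // 2, end=mid + TRIM_BP // 2 + 1)
    frag = frag.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    return frag.reset_index(drop=True)


def _count_overlaps(frag: pd.DataFrame, chroms: np.ndarray,
                    starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Count fragments overlapping (>= 1 bp) each query interval."""
    out = np.zeros(len(starts), dtype=np.int64)
    by_chrom = {c: g for c, g in frag.groupby("chrom", sort=False,
                                              observed=True)}
    for chrom in np.unique(chroms):
        g = by_chrom.get(chrom)
        idx = np.flatnonzero(chroms == chrom)
        if g is None or not len(g):
            continue
        fs = np.sort(g["start"].to_numpy())
        fe = np.sort(g["end"].to_numpy())
        n = len(fs)
        # overlap iff frag.start < q.end and frag.end > q.start
        n_start_right = n - np.searchsorted(fs, ends[idx], side="left")
        n_end_left = np.searchsorted(fe, starts[idx], side="right")
        out[idx] = n - n_start_right - n_end_left
    return out


def count_coverage(fragments_by_sample: dict[tuple[str, str], pd.DataFrame],
                   regions: pd.DataFrame,
                   known_chroms: set[str] | None = None) -> CoverageMatrix:
    """Raw fragment counts on each region's three oriented subintervals.

    ``fragments_by_sample`` maps (mark, replicate) to a filtered
    fragment DataFrame. ``regions`` must carry flank coordinates and the
    ``downstream_is_right`` orientation flag; only non-discarded regions
    are counted. Library size per sample is its total filtered fragment
    count.
    """
    import warnings

    reg = regions.loc[~regions["taxonomy"].str.startswith("discarded")]
    rid = reg["region_id"].to_numpy()
    chroms = reg["chrom"].to_numpy()
    right_is_down = reg["downstream_is_right"].to_numpy() if \
        "downstream_is_right" in reg.columns else np.ones(len(reg), bool)

    left = (reg["left_flank_start"].to_numpy(), reg["left_flank_end"].to_numpy())
    center = (reg["start"].to_numpy(), reg["end"].to_numpy())
    right = (reg["right_flank_start"].to_numpy(), reg["right_flank_end"].to_numpy())
    up = (np.where(right_is_down, left[0], right[0]),
          np.where(right_is_down, left[1], right[1]))
    down = (np.where(right_is_down, right[0], left[0]),
            np.where(right_is_down, right[1], left[1]))
    windows = {"upstream": up, "center": center, "downstream": down}

    cols, data, libsizes = [], [], {}
    for (mark, rep), frag in fragments_by_sample.items():
        if known_chroms is not None:
            bad = ~frag["chrom"].isin(known_chroms)
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} fragments on unknown chromosomes "
                    f"skipped in sample ({mark}, {rep})", stacklevel=2)
                frag = frag.loc[~bad]
        libsizes[(mark, rep)] = len(frag)
        for sub in SUBINTERVALS:
            s, e = windows[sub]
            cols.append((mark, rep, sub))
            data.append(_count_overlaps(frag, chroms, s, e))

    counts = pd.DataFrame(
        np.column_stack(data) if data else np.zeros((len(rid), 0)),
        index=pd.Index(rid, name="region_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["mark", "replicate",
                                                       "subinterval"]))
    lengths = pd.DataFrame(
        {"upstream": up[1] - up[0], "center": center[1] - center[0],
         "downstream": down[1] - down[0]},
        index=counts.index)
    libs = pd.Series(libsizes)
    libs.index.names = ["mark", "replicate"]
    return CoverageMatrix(counts, libs, lengths)


def rpk500(count, length_bp, library_size):
    """Reads per 500 bp per million filtered fragments (= RPKM / 2)."""
    return count / (length_bp / 500.0) / (library_size / 1e6)


def normalize_log2_rpk500(matrix: CoverageMatrix) -> CoverageMatrix:
    """log2(RPK500 + 1) normalization of a raw count matrix."""
    if (matrix.library_sizes <= 0).any():
        raise ValueError("zero library size")
    values = {}
    for col in matrix.counts.columns:
        mark, rep, sub = col
        lib = matrix.library_sizes[(mark, rep)]
        lengths = matrix.lengths[sub]
        values[col] = np.log2(rpk500(matrix.counts[col], lengths, lib) + 1.0)
    norm = pd.DataFrame(values, index=matrix.counts.index)
    norm.columns = matrix.counts.columns
    return CoverageMatrix(norm, matrix.library_sizes.copy(), matrix.lengths,
                          normalized=True)


def spike_in_scale(values, spike_pairs: int):
    """Scale track values by 1e6 / spike-in pair count."""
    if spike_pairs <= 0:
        raise ValueError("spike-in pair count must be positive")
    return np.asarray(values, dtype=float) * (1e6 / spike_pairs)


def pool_replicates(matrix: CoverageMatrix) -> CoverageMatrix:
    """Sum raw counts and library sizes across replicates per mark.

    Pooling precedes normalization: the pooled RPK500 uses the summed
    library size, which differs from averaging per-replicate RPK500
    whenever replicate depths differ.
    """
    if matrix.normalized:
        raise ValueError("pool raw counts, then normalize")
    pooled = matrix.counts.T.groupby(level=["mark", "subinterval"]).sum().T
    pooled.columns = pd.MultiIndex.from_tuples(
        [(m, "pooled", s) for m, s in pooled.columns],
        names=["mark", "replicate", "subinterval"])
    # preserve mark order of the input
    marks = list(dict.fromkeys(matrix.counts.columns.get_level_values(0)))
    pooled = pooled.loc[:, [(m, "pooled", s) for m in marks
                            for s in SUBINTERVALS]]
    libs = matrix.library_sizes.groupby(level="mark").sum()
    libs.index = pd.MultiIndex.from_product([libs.index, ["pooled"]],
                                            names=["mark", "replicate"])
    return CoverageMatrix(pooled, libs, matrix.lengths)


def center_downstream_rpk500(matrix: CoverageMatrix,
                             mark: str, replicate: str = "pooled") -> pd.Series:
    """Linear RPK500 on the combined center + downstream interval."""
    count = (matrix.counts[(mark, replicate, "center")] +
             matrix.counts[(mark, replicate, "downstream")])
    length = matrix.lengths["center"] + matrix.lengths["downstream"]
    lib = matrix.library_sizes[(mark, replicate)]
    return rpk500(count, length, lib)


def enrichment_over_control(pooled: CoverageMatrix,
                            control_mark: str = "IgG",
                            eps: float = RATIO_PSEUDOCOUNT,
                            subintervals=("center", "downstream")) -> pd.DataFrame:
    """Per-region fold enrichment of each mark over the IgG control.

    fold = (RPK500_mark + eps) / (RPK500_IgG + eps), computed on the
    combined center + downstream interval by default (configurable).
    """
    if pooled.normalized:
        raise ValueError("enrichment is computed from raw pooled counts")
    marks = pooled.marks
    if control_mark not in marks:
        raise ValueError(f"control mark {control_mark!r} missing")

    def _rpk(mark):
        count = sum(pooled.counts[(mark, "pooled", s)] for s in subintervals)
        length = sum(pooled.lengths[s] for s in subintervals)
        return rpk500(count, length, pooled.library_sizes[(mark, "pooled")])

    ctrl = _rpk(control_mark)
    folds = {m: (_rpk(m) + eps) / (ctrl + eps)
             for m in marks if m != control_mark}
    return pd.DataFrame(folds, index=pooled.counts.index)
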