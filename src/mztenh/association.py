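"""Association of enhancer classes with sequence and epigenome features.

Covers PWM motif-density scanning in a +/-100 bp window around region
centers, chi-squared motif presence tests between enhancer classes,
DNA-methylation stratification (<20% / 20-80% / >80%) and gamete-shared
hypomethylation, base composition (CpG count and C+G fraction in the
center 500 bp), nearest-gene distances with Wilcoxon rank-sum
comparisons, gene-proximity fractions, and GO enrichment by Fisher's
exact test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, chi2_contingency_test, fisher_exact_test, \
    rank_sum_test

MOTIF_WINDOW_BP = 100
PWM_SCORE_FRACTION = 0.8
HYPO_METHYLATION_MAX = 0.20
HYPER_METHYLATION_MIN = 0.80

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pwm:
    """Position weight matrix with a relative log-odds threshold.

    ``matrix`` is 4 x L (rows A, C, G, T) of base probabilities; columns
    must sum to 1. The detection threshold is ``score_fraction`` times
    the maximal achievable log-odds score under a uniform background.
    """

    motif_id: str
    matrix: np.ndarray
    score_fraction: float = PWM_SCORE_FRACTION

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L (A, C, G, T rows)")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM probability columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / background)

    @property
    def threshold(self) -> float:
        lo = self.log_odds()
        return self.score_fraction * float(lo.max(axis=0).sum())

    @classmethod
    def from_counts(cls, motif_id: str, counts, pseudo: float = 0.0,
                    score_fraction: float = PWM_SCORE_FRACTION) -> "Pwm":
        """Build from a JASPAR-style count matrix (rows A, C, G, T)."""
        counts = np.asarray(counts, dtype=float) + pseudo
        return cls(motif_id, counts / counts.sum(axis=0, keepdims=True),
                   score_fraction)


def _scan_strand(seq: str, pwm: Pwm) -> int:
    """Number of positions scoring >= threshold on one strand."""
    L = pwm.length
    n = len(seq) - L + 1
    if n <= 0:
        return 0
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(codes.shape, -1, dtype=np.int64)
    for base, j in _BASE_INDEX.items():
        idx[codes == ord(base)] = j
    lo = pwm.log_odds()
    lo = np.vstack([lo, np.full((1, L), -np.inf)])  # row 4: N / unknown
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = lo[windows, np.arange(L)].sum(axis=1)
    return int((scores >= pwm.threshold - 1e-9).sum())


def scan_motif_density(window_sequences: pd.Series, pwm: Pwm) -> pd.Series:
    """Per-region motif hit count in the +/-100 bp center window.

    ``window_sequences`` maps region id to the DNA sequence of the
    window (typically 200 bp centered on the open-interval midpoint).
    Hits are counted on both strands; a palindromic motif matching
    forward and reverse at the same position counts once per strand.
    Sequences shorter than the motif yield 0 hits; N bases never match.
    """
    out = {}
    for rid, seq in window_sequences.items():
        rc = seq.translate(_COMPLEMENT)[::-1]
        out[rid] = _scan_strand(seq, pwm) + _scan_strand(rc, pwm)
    return pd.Series(out, name=pwm.motif_id)


def motif_presence_test(counts_a, counts_b,
                        levels: int = 2) -> tuple[float, int, float]:
    """Chi-squared comparison of motif presence between two classes.

    ``levels=2`` categorizes regions as {0 hits, >= 1 hit} (1 d.o.f.);
    ``levels=3`` uses {0, 1, >= 2 hits} (2 d.o.f.). Returns
    (chi2, dof, pvalue).
    """
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if levels == 2:
        table = [[(a == 0).sum(), (a >= 1).sum()],
                 [(b == 0).sum(), (b >= 1).sum()]]
    elif levels == 3:
        table = [[(a == 0).sum(), (a == 1).sum(), (a >= 2).sum()],
                 [(b == 0).sum(), (b == 1).sum(), (b >= 2).sum()]]
    else:
        raise ValueError("levels must be 2 or 3")
    return chi2_contingency_test(table)


def methylation_stratify(records: pd.DataFrame,
                         column: str = "embryo") -> pd.Series:
    """Low (<20%) / medium (20-80%) / high (>80%) methylation strata.

    Boundaries at exactly 0.20 and 0.80 fall in the medium stratum (the
    printed low/high cutoffs are strict inequalities).
    """
    p = records[column]
    strata = np.where(p < HYPO_METHYLATION_MAX, "low",
                      np.where(p > HYPER_METHYLATION_MIN, "high", "medium"))
    return pd.Series(strata, index=records.index, name="methylation_stratum")


def shared_hypomethylation(records: pd.DataFrame,
                           cutoff: float = HYPO_METHYLATION_MAX
                           ) -> tuple[float | None, dict[str, list]]:
    """Fraction of embryo-hypomethylated regions hypomethylated (<20%)
    in both egg and sperm.

    Returns (fraction, partition). The fraction is None (undefined) if
    no region is embryo-hypomethylated.
    """
    hypo = records["embryo"] < cutoff
    if not hypo.any():
        return None, {"shared": [], "not_shared": []}
    sub = records.loc[hypo]
    shared = (sub["egg"] < cutoff) & (sub["sperm"] < cutoff)
    partition = {"shared": sub.index[shared].tolist(),
                 "not_shared": sub.index[~shared].tolist()}
    return float(shared.mean()), partition


def base_composition(center_sequences: pd.Series,
                     window_bp: int = 500) -> pd.DataFrame:
    """CpG dinucleotide count and C+G fraction in the center window.

    CpG counts are forward-strand "CG" occurrences; both quantities are
    strand-symmetric. Sequences shorter than the window (off-chromosome
    windows) are skipped with a warning.
    """
    import warnings

    rows = {}
    for rid, seq in center_sequences.items():
        if len(seq) < window_bp:
            warnings.warn(f"center window for {rid} shorter than "
                          f"{window_bp} bp; skipped", stacklevel=2)
            continue
        s = seq.upper()
        rows[rid] = {"cpg_count": s.count("CG"),
                     "cg_fraction": (s.count("C") + s.count("G")) / window_bp}
    return pd.DataFrame.from_dict(rows, orient="index")


def _nearest_distance(starts: np.ndarray, ends: np.ndarray,
                      positions: np.ndarray) -> np.ndarray:
    """Vectorized edge distance from intervals to nearest position
    (0 when a position falls inside the interval)."""
    pos = np.sort(positions)
    out = np.empty(len(starts), dtype=np.int64)
    for i, (s, e) in enumerate(zip(starts, ends)):
        j = np.searchsorted(pos, s)
        cands = pos[max(0, j - 1):j + 2]
        inside = (cands >= s) & (cands < e)
        if inside.any():
            out[i] = 0
        else:
            out[i] = np.min(np.minimum(np.abs(s - cands),
                                       np.abs(cands - (e - 1))))
    return out


def nearest_gene_distances(calls: pd.DataFrame,
                           regions: pd.DataFrame,
                           gene_tss: pd.DataFrame,
                           gene_group_col: str = "expression_group"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance from each called enhancer to the nearest gene of each
    group, plus rank-sum comparisons of the two enhancer classes.

    ``gene_tss`` needs columns chrom, pos and a gene-group column.
    Returns (per-enhancer distance table, per-group test table with the
    two-sided Wilcoxon rank-sum p comparing H3K4me2- versus
    H3K4me1-enhancer distance distributions).
    """
    enh = calls[calls["call"].isin(["H3K4me1-enhancer", "H3K4me2-enhancer"])]
    reg = regions.set_index("region_id").loc[enh.index]
    dist_rows = {"call": enh["call"]}
    for group, tss in gene_tss.groupby(gene_group_col):
        d = np.full(len(reg), np.iinfo(np.int64).max, dtype=np.int64)
        for chrom, sub in tss.groupby("chrom"):
            mask = (reg["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            d[mask] = _nearest_distance(
                reg["start"].to_numpy()[mask], reg["end"].to_numpy()[mask],
                sub["pos"].to_numpy())
        dist_rows[f"dist_{group}"] = pd.Series(d, index=enh.index)
    distances = pd.DataFrame(dist_rows)

    tests = []
    for group in gene_tss[gene_group_col].unique():
        col = f"dist_{group}"
        me2 = distances.loc[distances["call"] == "H3K4me2-enhancer", col]
        me1 = distances.loc[distances["call"] == "H3K4me1-enhancer", col]
        if len(me1) and len(me2):
            stat, p = rank_sum_test(me2, me1)
        else:
            stat, p = float("nan"), float("nan")
        tests.append({"gene_group": group, "statistic": stat, "pvalue": p,
                      "n_H3K4me2": len(me2), "n_H3K4me1": len(me1)})
    return distances, pd.DataFrame(tests)


def proximity_fraction(gene_tss: pd.DataFrame,
                       calls: pd.DataFrame,
                       regions: pd.DataFrame,
                       enhancer_class: str,
                       radius_bp: int) -> float:
    """Fraction of genes with >= 1 enhancer of the class within the
    radius (TSS-to-enhancer-edge distance)."""
    enh_ids = calls.index[calls["call"] == enhancer_class]
    reg = regions.set_index("region_id").loc[enh_ids]
    n_near = 0
    for _, g in gene_tss.iterrows():
        sub = reg[reg["chrom"] == g["chrom"]]
        if sub.empty:
            continue
        d = np.where((g["pos"] >= sub["start"]) & (g["pos"] < sub["end"]), 0,
                     np.minimum(np.abs(sub["start"] - g["pos"]),
                                np.abs(g["pos"] - (sub["end"] - 1))))
        if (d <= radius_bp).any():
            n_near += 1
    return n_near / len(gene_tss) if len(gene_tss) else float("nan")


def go_enrichment(annotation: pd.DataFrame,
                  genes_near_a: set[str],
                  genes_near_b: set[str]) -> pd.DataFrame:
    """Per-term Fisher's exact test comparing two gene sets.

    ``annotation`` has columns gene_id, term. For each term, the 2x2
    table is (annotated, not annotated) x (near class A, near class B);
    two-sided Fisher p-values are Benjamini-Hochberg corrected across
    terms. Terms annotating zero genes in the union are skipped.
    """
    rows = []
    a, b = set(genes_near_a), set(genes_near_b)
    for term, genes in annotation.groupby("term")["gene_id"]:
        gs = set(genes)
        a_annot = len(a & gs)
        b_annot = len(b & gs)
        if a_annot + b_annot == 0:
            continue
        table = [[a_annot, b_annot],
                 [len(a) - a_annot, len(b) - b_annot]]
        odds, p = fisher_exact_test(table)
        rows.append({"term": term, "odds_ratio": odds, "pvalue": p,
                     "n_annotated_a": a_annot, "n_annotated_b": b_annot})
    result = pd.DataFrame(rows)
    if len(result):
        result["qvalue"] = bh_fdr(result["pvalue"])
    return result
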