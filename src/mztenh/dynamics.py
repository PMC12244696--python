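"""Stage-wise dynamics: H3K4-methylation PCA trajectories and RNA-seq
activation trajectories.

The time-course PCA represents each region by one row per stage (the
nine features are H3K4me1/2/3 coverage on the upstream, center and
downstream subintervals), so per-group mean paths through PC space can
be drawn. Activation trajectories are per-gene log2 fold increases over
the first stage (pseudocount 0.1), summarized per gene group with a
t-based 95% confidence interval: mean +/- qt(0.975, n-1) * sd / sqrt(n)
with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import PcaModel, fit_pca
from .coverage import CoverageMatrix

EXPRESSION_PSEUDOCOUNT = 0.1
MATERNAL_RPKM_CUTOFF = 0.5
K4_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3")


def timecourse_pca(matrices_by_stage: dict[str, CoverageMatrix],
                   marks=K4_MARKS) -> tuple[PcaModel, pd.DataFrame]:
    """Stacked-stage PCA of H3K4 methylation coverage.

    ``matrices_by_stage`` maps stage name to a normalized,
    replicate-pooled coverage matrix. Rows are (region, stage) pairs;
    regions missing any stage are excluded with a warning. Returns the
    fitted model and a long score table with columns region_id, stage,
    PC1..PCk.
    """
    stages = list(matrices_by_stage)
    common = None
    for stage, m in matrices_by_stage.items():
        if not m.normalized:
            raise ValueError("timecourse_pca expects normalized matrices")
        idx = set(m.counts.index)
        common = idx if common is None else common & idx
    all_ids = set().union(*(set(m.counts.index)
                            for m in matrices_by_stage.values()))
    dropped = all_ids - common
    if dropped:
        warnings.warn(f"{len(dropped)} regions missing a stage excluded",
                      stacklevel=2)
    common = sorted(common)

    blocks, row_regions, row_stages = [], [], []
    cols = [(m, "pooled", s) for m in marks
            for s in ("upstream", "center", "downstream")]
    for stage in stages:
        mat = matrices_by_stage[stage].counts.loc[common, cols]
        blocks.append(mat.to_numpy(dtype=float))
        row_regions.extend(common)
        row_stages.extend([stage] * len(common))
    X = np.vstack(blocks)

    stacked = pd.DataFrame(
        X, columns=pd.MultiIndex.from_tuples(
            cols, names=["mark", "replicate", "subinterval"]),
        index=pd.MultiIndex.from_arrays([row_regions, row_stages],
                                        names=["region_id", "stage"]))
    lengths = matrices_by_stage[stages[0]].lengths.loc[common]
    lengths = pd.concat([lengths] * len(stages))
    lengths.index = stacked.index
    libs = pd.Series(1.0, index=pd.MultiIndex.from_tuples(
        [(m, "pooled") for m in marks], names=["mark", "replicate"]))
    cm = CoverageMatrix(stacked, libs, lengths, normalized=True)
    pca = fit_pca(cm, control_mark="IgG")

    scores = pca.scores.reset_index()
    return pca, scores


def rna_activation_trajectory(expression: pd.DataFrame,
                              gene_groups: pd.Series,
                              t0_stage: str,
                              pseudocount: float = EXPRESSION_PSEUDOCOUNT
                              ) -> pd.DataFrame:
    """Mean log2 fold-increase trajectories per gene group with 95% CI.

    ``expression`` is gene x stage (values >= 0); ``gene_groups`` maps
    gene id to group label. Genes missing any stage are dropped
    listwise. For groups of n < 2, bounds are NaN.
    """
    expr = expression.dropna(axis=0)
    if t0_stage not in expr.columns:
        raise ValueError(f"t0 stage {t0_stage!r} absent from table")
    logx = np.log2(expr + pseudocount)
    fc = logx.sub(logx[t0_stage], axis=0)
    groups = gene_groups.reindex(fc.index)

    rows = []
    for group, sub in fc.groupby(groups):
        n = len(sub)
        for stage in expr.columns:
            vals = sub[stage].to_numpy()
            mean = float(vals.mean())
            if n >= 2:
                sd = float(vals.std(ddof=1))
                qt = float(sps.t.ppf(0.975, n - 1))
                half = qt * sd / np.sqrt(n)
                lower, upper = mean - half, mean + half
            else:
                lower = upper = float("nan")
            rows.append({"group": group, "stage": stage, "mean_log2_fc": mean,
                         "lower": lower, "upper": upper, "n": n})
    return pd.DataFrame(rows)


def stratify_maternal_zygotic(expression: pd.DataFrame,
                              two_cell_stage: str,
                              cutoff: float = MATERNAL_RPKM_CUTOFF
                              ) -> pd.Series:
    """Maternal-zygotic (2-cell expression > 0.5 RPKM, strict) versus
    strictly-zygotic genes."""
    if two_cell_stage not in expression.columns:
        raise ValueError(f"stage {two_cell_stage!r} absent from table")
    mz = expression[two_cell_stage] > cutoff
    return pd.Series(np.where(mz, "maternal-zygotic", "strictly-zygotic"),
                     index=expression.index, name="contribution")
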