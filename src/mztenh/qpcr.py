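"""Crispant qRT-PCR analysis.

Quantifies enhancer loss-of-function effects from per-embryo Ct tables:
technical replicates are averaged, per-embryo delta-Ct (target minus
reference) is converted to 2^-dCt, values are normalized so the
control-group average is exactly 1, and the knockdown is summarized as
the fold decrease (control mean / crispant mean) with a two-sided
Wilcoxon rank-sum p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import rank_sum_test

TARGET_PRIMER = "target"
REFERENCE_PRIMER = "reference"


def collapse_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (embryo, primer).

    ``table`` has columns embryo_id, group, primer, rep, ct. Returns one
    row per embryo with columns group, ct_target, ct_reference.
    """
    means = table.groupby(["embryo_id", "primer"])["ct"].mean().unstack()
    for primer in (TARGET_PRIMER, REFERENCE_PRIMER):
        missing = means.index[means.get(primer, pd.Series(dtype=float)
                                        ).isna()] if primer in means else \
            means.index
        if len(missing):
            raise ValueError(
                f"embryo {missing[0]!r} is missing primer {primer!r}")
    groups = table.groupby("embryo_id")["group"].first()
    out = pd.DataFrame({"group": groups,
                        "ct_target": means[TARGET_PRIMER],
                        "ct_reference": means[REFERENCE_PRIMER]})
    return out


def relative_expression(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Per-embryo 2^-dCt normalized to a control-group mean of 1."""
    out = collapsed.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    out["rel_expr"] = 2.0 ** (-out["delta_ct"])
    control = out.loc[out["group"] == "control", "rel_expr"]
    if control.empty:
        raise ValueError("control group is empty")
    out["normalized"] = out["rel_expr"] / control.mean()
    return out


def knockdown_test(normalized: pd.DataFrame,
                   fold_method: str = "ratio-of-means") -> dict:
    """Fold decrease and rank-sum test between crispant and control.

    ``fold_method`` "ratio-of-means" (default) is the control mean over
    the crispant mean of normalized values (the control mean is 1 by
    construction); "mean-of-reciprocals" averages per-embryo reciprocal
    values instead.
    """
    ctrl = normalized.loc[normalized["group"] == "control", "normalized"]
    cris = normalized.loc[normalized["group"] == "crispant", "normalized"]
    if len(ctrl) < 2 or len(cris) < 2:
        raise ValueError("need >= 2 embryos per group")
    if cris.mean() == 0:
        warnings.warn("crispant mean is zero; fold reported as +inf",
                      stacklevel=2)
        fold = float("inf")
    elif fold_method == "ratio-of-means":
        fold = float(ctrl.mean() / cris.mean())
    elif fold_method == "mean-of-reciprocals":
        fold = float((1.0 / cris).mean() / (1.0 / ctrl).mean())
    else:
        raise ValueError(f"unknown fold_method {fold_method!r}")
    stat, p = rank_sum_test(ctrl, cris)
    return {"fold_decrease": fold, "pvalue": p, "statistic": stat,
            "n_control": int(len(ctrl)), "n_crispant": int(len(cris)),
            "fold_method": fold_method}


def analyze_ct_table(table: pd.DataFrame,
                     fold_method: str = "ratio-of-means") -> dict:
    """Full pipeline: collapse, normalize, test."""
    return knockdown_test(relative_expression(collapse_technical(table)),
                          fold_method=fold_method)
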