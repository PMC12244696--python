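"""Element classification: PCA, SVM reference classifier, final calls.

The two enhancer classes are defined by discordance between genomic
annotation and chromatin state. A PCA (centered, not variance-scaled)
summarizes the normalized coverage features; an RBF support-vector
machine (gamma = 1, C = 1) trained on the first three principal
components with promoter-taxonomy regions labelled "promoter" and
distal regions labelled "enhancer" provides a reference chromatin-state
label for every region. Distal regions whose chromatin looks
promoter-like (SVM "promoter") and that pass H3K4me2 and H3K27ac
enrichment thresholds are H3K4me2 enhancers; distal regions with
concordant SVM labels, H3K4me1 enrichment, and background-level
H3K4me2 are H3K4me1 enhancers. A rescue step re-admits SVM-"enhancer"
regions with top-quartile H3K4me2 coverage, and mark-bearing regions
lacking H3K27ac are annotated as poised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .coverage import CoverageMatrix, center_downstream_rpk500

SVM_GAMMA = 1.0
SVM_COST = 1.0
N_PCS_FOR_SVM = 3

# enrichment thresholds for the refined element calls
K27AC_ACTIVE_MIN = 1.5
K4ME2_ENHANCER_MIN = 2.0
K4ME1_ENHANCER_MIN = 2.0
K4ME2_BACKGROUND_MAX = 1.25
K4ME3_BACKGROUND_MAX = 1.25
RESCUE_QUANTILE = 0.75

CALLS = ("H3K4me1-enhancer", "H3K4me2-enhancer", "poised-enhancer",
         "proximal-potential-H3K4me2", "proximal-potential-H3K4me1",
         "high-K4me23-promoter", "low-K4me23-promoter", "unclassified")


@dataclass
class PcaModel:
    """Centered PCA with a deterministic sign convention.

    Each loading vector is oriented so that its largest-magnitude entry
    is positive, which pins the score signs across linear-algebra
    backends.
    """

    feature_names: list
    mean: np.ndarray
    loadings: np.ndarray            # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame            # regions (or region-stage rows) x PCs

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings.T


def fit_pca(matrix: CoverageMatrix, control_mark: str = "IgG") -> PcaModel:
    """PCA on normalized coverage features (IgG excluded), centered only.

    ``matrix`` may be per-replicate or replicate-pooled; each (mark,
    replicate, subinterval) column is one feature.
    """
    if not matrix.normalized:
        raise ValueError("fit_pca expects a normalized coverage matrix")
    m = matrix.drop_marks([control_mark])
    X = m.counts.to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"fewer regions ({n}) than features ({p})")
    mean = X.mean(axis=0)
    Xc = X - mean
    # full SVD-based PCA; components = right singular vectors
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading entry positive
    flip = np.sign(vt[np.arange(vt.shape[0]),
                      np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    var = s ** 2 / (n - 1)
    evr = var / var.sum() if var.sum() > 0 else var
    scores = pd.DataFrame(Xc @ vt.T, index=m.counts.index,
                          columns=[f"PC{i + 1}" for i in range(vt.shape[0])])
    return PcaModel(list(m.counts.columns), mean, vt, evr, scores)


@dataclass
class ReferenceClassifier:
    """RBF SVM over standardized scores on the first three PCs."""

    model: object
    gamma: float = SVM_GAMMA
    cost: float = SVM_COST
    n_pcs: int = N_PCS_FOR_SVM
    training_accuracy: float = float("nan")
    classes: tuple = ("enhancer", "promoter")

    def report(self) -> dict:
        return {"kernel": "radial-basis", "gamma": self.gamma,
                "cost": self.cost, "n_pcs": self.n_pcs,
                "training_accuracy": self.training_accuracy}


def fit_reference_classifier(pca: PcaModel,
                             taxonomy: pd.Series) -> ReferenceClassifier:
    """Train the promoter-vs-enhancer reference SVM.

    Training set: promoter-taxonomy regions (label "promoter") and
    distal-taxonomy regions (label "enhancer"); proximal regions are
    excluded. Features are the first three PC scores, standardized to
    zero mean and unit variance before the RBF kernel (gamma = 1,
    C = 1).
    """
    scores = pca.scores.iloc[:, :N_PCS_FOR_SVM]
    taxonomy = taxonomy.reindex(scores.index)
    train_mask = taxonomy.isin(["promoter", "distal"])
    y = taxonomy[train_mask].map({"promoter": "promoter",
                                  "distal": "enhancer"})
    if y.nunique() < 2:
        raise ValueError("training set must contain both promoter and "
                         "distal regions")
    if (y.value_counts() < 2).any():
        raise ValueError("need >= 2 training examples per class")
    X = scores[train_mask].to_numpy()
    model = make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", gamma=SVM_GAMMA, C=SVM_COST, random_state=0))
    model.fit(X, y.to_numpy())
    acc = float((model.predict(X) == y.to_numpy()).mean())
    if acc <= 0.5:
        raise ValueError(f"reference classifier training accuracy {acc:.2f} "
                         "not above chance; check input features")
    return ReferenceClassifier(model, training_accuracy=acc)


def predict_all(classifier: ReferenceClassifier,
                pca: PcaModel) -> pd.Series:
    """SVM label ("promoter"/"enhancer") for every region."""
    X = pca.scores.iloc[:, :classifier.n_pcs].to_numpy()
    return pd.Series(classifier.model.predict(X), index=pca.scores.index,
                     name="svm_label")


def call_elements(svm_labels: pd.Series,
                  enrichment: pd.DataFrame,
                  taxonomy: pd.Series,
                  pooled: CoverageMatrix,
                  k27ac_min: float = K27AC_ACTIVE_MIN,
                  k4me2_min: float = K4ME2_ENHANCER_MIN,
                  k4me1_min: float = K4ME1_ENHANCER_MIN,
                  k4me2_bg_max: float = K4ME2_BACKGROUND_MAX,
                  k4me3_bg_max: float = K4ME3_BACKGROUND_MAX) -> pd.DataFrame:
    """Final element calls from SVM labels and enrichment thresholds.

    Distal regions, in order: (a) H3K4me2 enhancer if SVM "promoter"
    with H3K27ac >= 1.5 and H3K4me2 >= 2; (b) rescue of SVM "enhancer"
    regions meeting the same enrichment thresholds whose pooled H3K4me2
    center+downstream coverage reaches the 75th percentile of the
    step-(a) calls; (c) H3K4me1 enhancer if SVM "enhancer" with
    H3K4me1 >= 2, H3K4me2 < 1.25 and H3K27ac >= 1.5; (d) poised
    enhancer if mark-bearing (H3K4me1 or H3K4me2 >= 2) with
    H3K27ac <= 1.5; (e) unclassified. At H3K27ac exactly 1.5 the active
    rules take precedence over poised. Proximal regions with
    H3K4me3 < 1.25 are annotated as potential enhancers of either
    class; promoter regions are split by SVM concordance into high- and
    low-K4me2/3 promoters.
    """
    for mark in ("H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac"):
        if mark not in enrichment.columns:
            raise ValueError(f"enrichment table is missing mark {mark!r}")
    idx = enrichment.index
    svm = svm_labels.reindex(idx)
    tax = taxonomy.reindex(idx)
    me1 = enrichment["H3K4me1"]
    me2 = enrichment["H3K4me2"]
    me3 = enrichment["H3K4me3"]
    ac = enrichment["H3K27ac"]
    me2_cov = center_downstream_rpk500(pooled, "H3K4me2").reindex(idx)

    call = pd.Series("unclassified", index=idx, name="call")
    rescue = pd.Series(False, index=idx, name="rescue")

    distal = tax == "distal"
    me2_enh_marks = (ac >= k27ac_min) & (me2 >= k4me2_min)
    step_a = distal & (svm == "promoter") & me2_enh_marks
    call[step_a] = "H3K4me2-enhancer"

    if step_a.any():
        cov_cut = float(np.quantile(me2_cov[step_a], RESCUE_QUANTILE))
        step_b = (distal & (svm == "enhancer") & me2_enh_marks &
                  (me2_cov >= cov_cut) & (call == "unclassified"))
        call[step_b] = "H3K4me2-enhancer"
        rescue[step_b] = True

    step_c = (distal & (svm == "enhancer") & (me1 >= k4me1_min) &
              (me2 < k4me2_bg_max) & (ac >= k27ac_min) &
              (call == "unclassified"))
    call[step_c] = "H3K4me1-enhancer"

    mark_bearing = (me1 >= k4me1_min) | (me2 >= k4me2_min)
    step_d = (distal & mark_bearing & (ac <= k27ac_min) &
              (call == "unclassified"))
    call[step_d] = "poised-enhancer"

    proximal = tax == "proximal"
    prox_me2 = proximal & (me3 < k4me3_bg_max) & (me2 >= k4me2_min)
    prox_me1 = (proximal & (me3 < k4me3_bg_max) & (me1 >= k4me1_min) &
                (me2 < k4me2_bg_max))
    call[prox_me2] = "proximal-potential-H3K4me2"
    call[prox_me1] = "proximal-potential-H3K4me1"

    promoter = tax == "promoter"
    call[promoter & (svm == "promoter")] = "high-K4me23-promoter"
    call[promoter & (svm == "enhancer")] = "low-K4me23-promoter"

    out = pd.DataFrame({"call": call, "svm_label": svm, "rescue": rescue,
                        "taxonomy": tax})
    # the two final enhancer classes are disjoint by construction
    assert not ((out["call"] == "H3K4me1-enhancer") &
                (out["call"] == "H3K4me2-enhancer")).any()
    return out


def initial_heatmap_groups(enrichment: pd.DataFrame,
                           pooled: CoverageMatrix,
                           svm_labels: pd.Series,
                           taxonomy: pd.Series,
                           k4me1_min: float = 2.0,
                           rpkm_min: float = 10.0) -> dict[str, list]:
    """The four initial heatmap groups, gated on dome-stage signal.

    Regions with >= 2-fold pooled H3K4me1 enrichment over IgG and
    >= 10 RPKM coverage on the combined center + downstream interval
    (RPKM = 2 x RPK500) are partitioned by taxonomy x SVM concordance:
    typical (H3K4me1) enhancers, H3K4me2 enhancers, and high/low
    H3K4me2/3 promoters.
    """
    idx = enrichment.index
    svm = svm_labels.reindex(idx)
    tax = taxonomy.reindex(idx)
    rpkm = 2.0 * center_downstream_rpk500(pooled, "H3K4me1").reindex(idx)
    gate = ((enrichment["H3K4me1"] >= k4me1_min) & (rpkm >= rpkm_min) &
            tax.isin(["promoter", "distal"]))
    groups = {
        "typical-enhancers": idx[gate & (tax == "distal") &
                                 (svm == "enhancer")].tolist(),
        "H3K4me2-enhancers": idx[gate & (tax == "distal") &
                                 (svm == "promoter")].tolist(),
        "high-K4me23-promoters": idx[gate & (tax == "promoter") &
                                     (svm == "promoter")].tolist(),
        "low-K4me23-promoters": idx[gate & (tax == "promoter") &
                                    (svm == "enhancer")].tolist(),
    }
    return groups
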