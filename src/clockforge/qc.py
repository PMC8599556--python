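"""Sample quality control.

Three checks mirror standard methylation-array practice:

1. **Inter-array correlation clustering** — all-pairs Pearson
   correlation between sample beta profiles, then average-linkage
   hierarchical clustering on distance ``1 - r``.  Good arrays sit in
   a tight cluster (r > 0.97 is typical); samples cluster by sex, and
   multi-species panels cluster by species.
2. **Sex-mismatch flagging** — a sample whose annotated sex differs
   from the majority sex of its k nearest neighbors (by inter-array
   correlation) is flagged.  The k-NN majority vote is a deterministic
   operationalization of the visual call one makes on a dendrogram
   whose branches split by sex.
3. **Random-forest out-of-bag trait prediction** — OOB
   misclassification for a categorical trait (sex, neuter status),
   optionally after subsetting (e.g. to young animals where neuter
   status is not confounded with age).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "Dendrogram",
    "QCReport",
    "interarray_correlation",
    "average_linkage_tree",
    "flag_sex_mismatches",
    "oob_trait_accuracy",
    "run_qc",
]


def interarray_correlation(matrix) -> pd.DataFrame:
    """All-pairs Pearson correlation between sample beta profiles.

    Missing betas are excluded pairwise.  The result is symmetric with
    a unit diagonal.  A sample with zero variance across probes has no
    defined correlation and is an error.
    """
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 probes")
    X = data.to_numpy(dtype=float)
    zero_var = [sid for sid, row in zip(data.index, X) if np.nanstd(row) == 0]
    if zero_var:
        raise ValueError(f"zero-variance sample(s): {zero_var}")
    if np.isfinite(X).all():
        corr = np.corrcoef(X)
    else:
        corr = pd.DataFrame(X.T).corr(min_periods=2).to_numpy()
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=data.index, columns=data.index)


@dataclass
class Dendrogram:
    """Result of agglomerative clustering: a SciPy-format merge list
    plus leaf labels."""

    merges: np.ndarray  # (n-1, 4) linkage matrix: left, right, height, size
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        n = len(self.labels)
        nodes = {i: f"{self.labels[i]}:0" for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = nodes.pop(a).rsplit(":", 1)
            lb = nodes.pop(b).rsplit(":", 1)
            nodes[n + k] = (f"({la[0]}:{h - heights[a]:.10g},"
                            f"{lb[0]}:{h - heights[b]:.10g}):0")
            heights[n + k] = float(h)
        (root,) = nodes.values()
        return root.rsplit(":", 1)[0] + ";"


def average_linkage_tree(corr: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) clustering on distance ``1 - r``.

    Heights are monotone non-decreasing; the merge list follows
    SciPy's linkage-matrix convention.
    """
    corr = pd.DataFrame(corr)
    if corr.shape[0] != corr.shape[1] or not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation table must be square and symmetric")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    merges = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(merges=merges, labels=list(corr.index))


def flag_sex_mismatches(matrix, sheet: pd.DataFrame, k: int = 5) -> list:
    """Flag samples whose annotated sex disagrees with the majority
    sex of their k nearest neighbors by inter-array correlation.

    Samples with unknown sex neither vote nor get flagged.  Invariant
    to sample order.
    """
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    sheet = sheet.loc[data.index]
    sex = sheet["sex"].astype(str)
    labelled = sex[sex.isin(["female", "male"])].index
    if k >= len(labelled):
        raise ValueError(f"k={k} must be smaller than the number of sex-labelled samples "
                         f"({len(labelled)})")
    corr = interarray_correlation(data.loc[labelled])
    flagged = []
    for sid in labelled:
        neighbors = corr.loc[sid].drop(sid).sort_values(ascending=False)
        # deterministic under ties: stable sort on (-corr, id)
        order = sorted(neighbors.index, key=lambda j: (-neighbors[j], str(j)))[:k]
        votes = sex.loc[order].value_counts()
        majority = sorted(votes.index[votes == votes.max()])[0]
        if majority != sex.loc[sid]:
            flagged.append(sid)
    return sorted(flagged, key=str)


def oob_trait_accuracy(matrix, labels, subset=None, n_trees: int = 500,
                       seed: int = 0) -> float:
    """Random-forest out-of-bag misclassification rate for a
    categorical trait.

    ``subset`` is an optional boolean mask or predicate applied to the
    samples before fitting (e.g. restrict the neuter-status analysis
    to young animals).  500 trees, sqrt(p) features per split; OOB
    votes are aggregated per sample and ties break toward the
    alphabetically first class.
    """
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    y = pd.Series(labels, index=data.index) if not isinstance(labels, pd.Series) else labels
    y = y.loc[data.index].astype(str)
    if subset is not None:
        mask = subset(data) if callable(subset) else np.asarray(subset, dtype=bool)
        data, y = data.loc[mask], y.loc[mask]
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes after subsetting, got {classes}")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=int(seed), n_jobs=1,
    )
    rf.fit(data.to_numpy(dtype=float), y.to_numpy())
    proba = rf.oob_decision_function_
    # argmax breaks ties toward the first class; classes_ is sorted
    pred = rf.classes_[np.argmax(proba, axis=1)]
    has_oob = proba.sum(axis=1) > 0
    return float(np.mean(pred[has_oob] != y.to_numpy()[has_oob]))


@dataclass
class QCReport:
    """Aggregated QC summary for one panel."""

    min_correlation: float
    median_correlation: float
    dendrogram: Dendrogram
    flagged_samples: dict = field(default_factory=dict)  # sample -> reason
    oob_results: dict = field(default_factory=dict)  # trait -> error rate

    def to_dict(self) -> dict:
        return {
            "min_correlation": self.min_correlation,
            "median_correlation": self.median_correlation,
            "n_merges": int(len(self.dendrogram.merges)),
            "flagged_samples": dict(sorted(self.flagged_samples.items())),
            "oob_results": self.oob_results,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def run_qc(matrix, sheet: pd.DataFrame, k: int = 5, n_trees: int = 500,
           seed: int = 0, traits=("sex",)) -> QCReport:
    """Run the full QC battery and collect a report."""
    corr = interarray_correlation(matrix)
    off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
    tree = average_linkage_tree(corr)
    flagged = {}
    sex_known = sheet["sex"].isin(["female", "male"]).sum()
    if sex_known > k:
        for sid in flag_sex_mismatches(matrix, sheet, k=k):
            flagged[str(sid)] = "annotated sex differs from k-NN majority"
    oob = {}
    for trait in traits:
        labels = sheet[trait]
        known = labels[labels != "unknown"]
        if known.nunique() >= 2:
            oob[trait] = oob_trait_accuracy(
                matrix.data.loc[known.index] if hasattr(matrix, "data") else matrix,
                known, n_trees=n_trees, seed=seed)
    return QCReport(
        min_correlation=float(off_diag.min()),
        median_correlation=float(np.median(off_diag)),
        dendrogram=tree,
        flagged_samples=flagged,
        oob_results=oob,
    )
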