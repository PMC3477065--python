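"""PCA of per-patient paired difference vectors and metastasis-age grouping.

Each patient contributes one vector of paired log2 differences over all
genes; covariance-mode PCA (genes centered, not scaled) of the patients x
genes matrix places patients in a low-dimensional space where matched pairs
with similar divergence profiles cluster. Metastasis-age groups are made
explicit with k-means (k=3 by default) on the top components, then named
early/mid/late by decreasing expression divergence: early metastatic events
show the largest number of differentially expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ValidationError


@dataclass
class PairedPcaResult:
    """Patient scores, loadings and explained-variance fractions."""

    scores: pd.DataFrame                  # patients x components
    explained_variance_ratio: np.ndarray  # non-increasing, sums to <= 1
    loadings: pd.DataFrame                # genes x components


@dataclass
class GroupAssignment:
    labels: pd.Series          # patient -> group label
    degenerate: bool = False   # duplicate patients: ties broken by seed
    names: dict = field(default_factory=dict)  # cluster id -> early/mid/late


def pca_of_differences(differences: pd.DataFrame,
                       n_components: int | None = 3) -> PairedPcaResult:
    """Covariance-mode PCA of the patients x genes paired-difference matrix.

    ``differences`` is probes x patients (as produced by
    :func:`paircnv.paired_de.paired_differences`); rows become observations
    after transposition. Component signs are fixed by requiring the
    largest-magnitude loading of each component to be positive, which makes
    scores reproducible across runs and platforms. ``n_components=None``
    keeps the full rank.
    """
    X = differences.to_numpy(dtype=float).T
    n_pat, n_genes = X.shape
    if n_pat < 3 or n_genes < 3:
        raise DegenerateInputError("need at least 3 patients and 3 genes")
    max_rank = min(n_pat, n_genes)
    if n_components is not None and n_components > n_pat:
        raise DegenerateInputError(f"{n_components} components requested for "
                                   f"{n_pat} patients")
    k = min(n_components or max_rank, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_  # k x genes
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] *= -1.0
            scores[:, j] *= -1.0
    names = [f"PC{j + 1}" for j in range(comps.shape[0])]
    return PairedPcaResult(
        scores=pd.DataFrame(scores, index=pd.Index(differences.columns,
                                                   name="patient"),
                            columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(comps.T, index=differences.index, columns=names),
    )


def assign_groups(scores: pd.DataFrame, k: int = 3,
                  seed: int = 0) -> GroupAssignment:
    """k-means clustering of patient scores into k groups.

    Identical patients make the partition seed-dependent; this is reported
    through the ``degenerate`` flag rather than hidden.
    """
    n = len(scores)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of patients ({n})")
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = scores.to_numpy(dtype=float)
    degenerate = bool(pd.DataFrame(X).duplicated().any())
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return GroupAssignment(
        labels=pd.Series(labels, index=scores.index, name="cluster"),
        degenerate=degenerate)


def name_groups(assignment: GroupAssignment, divergence: pd.Series,
                names: tuple[str, ...] = ("early", "mid", "late")) -> pd.Series:
    """Map cluster ids to metastasis-age names by descending divergence.

    ``divergence`` maps patient -> a per-patient divergence measure (e.g.
    the number of differentially expressed genes of the patient's group, or
    the norm of the paired-difference vector). The cluster with the largest
    mean divergence becomes the first name ("early"), and so on.
    """
    labels = assignment.labels
    k = labels.nunique()
    if k > len(names):
        raise ValidationError(f"{k} clusters but only {len(names)} names")
    order = (divergence.groupby(labels).mean()
             .sort_values(ascending=False).index)
    mapping = {cluster: names[i] for i, cluster in enumerate(order)}
    assignment.names = mapping
    return labels.map(mapping).rename("group")


def divergence_per_patient(differences: pd.DataFrame,
                           min_abs_log2: float = 1.0) -> pd.Series:
    """Number of genes whose paired difference clears ``min_abs_log2``,
    per patient — a simple expression-divergence measure for group naming."""
    return (differences.abs() >= min_abs_log2).sum(axis=0).rename("divergence")
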