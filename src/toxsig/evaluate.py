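"""Gene-signature evaluation: can a signature separate animal classes?

A signature (set of genes found co-regulated in liver and blood) is applied
to an independent animal set: the dye-swap-averaged log2-ratio matrix is
subset to the signature genes and one tissue, animals are projected on the
top two principal components, grouped by Euclidean-distance average-linkage
hierarchical clustering, and the two-cluster cut is compared against true
classes (administered dose class, or liver injury defined from serum ALT)
under the agreement-maximizing cluster-to-class mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .groups import VEHICLE_CLASS

__all__ = [
    "SignatureMatrix",
    "SeparationReport",
    "SignatureSeparator",
    "build_signature_matrix",
    "pca_2d",
    "hca",
    "two_cut_labels",
    "separation_report",
    "injury_labels",
    "compare_signatures",
    "linkage_to_newick",
]


@dataclass
class SignatureMatrix:
    """Signature genes × animals for one tissue, with true class labels."""

    values: pd.DataFrame  # genes × animal_ids
    labels: pd.Series  # animal_id -> class label
    tissue: str
    dropped_genes: list

    @property
    def animals(self):
        return list(self.values.columns)


@dataclass
class SeparationReport:
    """Two-cluster separation of animals against their true classes."""

    purity: float
    misclassified: list
    cluster_labels: pd.Series  # animal_id -> cluster (1/2)
    mapping: dict  # cluster -> class
    degenerate: bool = False


def build_signature_matrix(
    corrected: pd.DataFrame,
    column_meta: pd.DataFrame,
    genes,
    tissue: str,
    labels: pd.Series,
    include_vehicle: bool = False,
) -> SignatureMatrix:
    """Subset a dye-swap-corrected matrix to signature genes and one tissue.

    ``corrected`` has one column per animal×tissue (see
    :func:`toxsig.preprocess.dye_swap_correct`); columns are renamed to
    animal ids. Signature genes missing from the matrix are dropped with a
    warning; an empty intersection is an error.
    """
    if tissue not in set(column_meta["tissue"]):
        raise ValueError(f"unknown tissue {tissue!r}")
    genes = list(genes)
    if not genes:
        raise ValueError("empty signature gene set")
    present = [g for g in genes if g in corrected.index]
    dropped = sorted(set(genes) - set(present))
    if not present:
        raise ValueError("no signature gene is present in the matrix")
    if dropped:
        warnings.warn(f"{len(dropped)} signature genes missing from the matrix")

    meta = column_meta.reset_index(drop=True)
    sel = meta["tissue"] == tissue
    if not include_vehicle:
        sel &= meta["dose_class"] != VEHICLE_CLASS
    cols = meta.loc[sel, "column_id"]
    animals = meta.loc[sel, "animal_id"]
    sub = corrected[cols.tolist()].loc[present]
    sub.columns = animals.tolist()
    lab = labels.reindex(sub.columns)
    if lab.isna().any():
        # animals outside the labeling (e.g. indeterminate ALT) are excluded,
        # not silently binned
        unlabeled = lab[lab.isna()].index.tolist()
        warnings.warn(f"{len(unlabeled)} animals without a class label excluded")
        sub = sub.drop(columns=unlabeled)
        lab = lab.dropna()
        if sub.shape[1] == 0:
            raise ValueError("no labeled animals remain")
    return SignatureMatrix(values=sub, labels=lab, tissue=tissue, dropped_genes=dropped)


def pca_2d(sig: SignatureMatrix | pd.DataFrame, scale: bool = False) -> pd.DataFrame:
    """Project animals on the top two principal components.

    Genes are mean-centered (optionally unit-scaled); the component sign is
    fixed by making each component's largest-magnitude gene loading positive,
    so coordinates are deterministic. Rank-1 input gets a zero second
    component (flagged via the ``rank_deficient`` attribute on the result).
    """
    X = sig.values if isinstance(sig, SignatureMatrix) else sig
    A = X.to_numpy(dtype=float).T  # animals × genes
    if A.shape[0] < 3:
        raise ValueError("PCA needs at least 3 animals")
    if A.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes")
    A = A - A.mean(axis=0)
    if scale:
        sd = A.std(axis=0)
        A = A / np.where(sd > 0, sd, 1.0)
    rank = np.linalg.matrix_rank(A)
    n_comp = min(2, rank) if rank >= 1 else 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(A)
    comps = pca.components_
    for k in range(n_comp):  # deterministic axis orientation
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            coords[:, k] *= -1
    out = np.zeros((A.shape[0], 2))
    out[:, :n_comp] = coords
    df = pd.DataFrame(out, columns=["PC1", "PC2"], index=X.columns)
    df.attrs["rank_deficient"] = rank < 2
    df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return df


def hca(sig: SignatureMatrix | pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration of animals, Euclidean distance.

    Returns the standard 4-column linkage matrix. Identical animals merge at
    height zero in a stable order.
    """
    X = sig.values if isinstance(sig, SignatureMatrix) else sig
    A = X.to_numpy(dtype=float).T
    if A.shape[0] < 2:
        raise ValueError("clustering needs at least 2 animals")
    return hierarchy.linkage(A, method="average", metric="euclidean")


def two_cut_labels(Z: np.ndarray, animals) -> pd.Series:
    """Cut the dendrogram into two clusters; labels are 1 and 2."""
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return pd.Series(labels, index=list(animals), name="cluster")


def separation_report(cluster_labels: pd.Series, true_classes: pd.Series) -> SeparationReport:
    """Score a two-cluster cut against true classes.

    The two clusters are mapped to the two classes so as to maximize
    agreement; purity = 1 − misclassified/animals. One-class input is valid
    and reported as degenerate with purity 1.
    """
    truth = true_classes.reindex(cluster_labels.index)
    if truth.isna().any():
        raise ValueError("every animal needs a true class")
    classes = sorted(truth.unique())
    clusters = sorted(cluster_labels.unique())
    if len(classes) == 1:
        return SeparationReport(
            purity=1.0,
            misclassified=[],
            cluster_labels=cluster_labels,
            mapping={c: classes[0] for c in clusters},
            degenerate=True,
        )
    if len(classes) > 2:
        raise ValueError("separation_report compares two classes")
    best = None
    for mapping in (
        {clusters[0]: classes[0], clusters[-1]: classes[1]},
        {clusters[0]: classes[1], clusters[-1]: classes[0]},
    ):
        pred = cluster_labels.map(mapping)
        wrong = cluster_labels.index[(pred != truth).to_numpy()].tolist()
        if best is None or len(wrong) < len(best[0]):
            best = (wrong, mapping)
    wrong, mapping = best
    return SeparationReport(
        purity=1.0 - len(wrong) / len(cluster_labels),
        misclassified=wrong,
        cluster_labels=cluster_labels,
        mapping=mapping,
    )


class SignatureSeparator(BaseEstimator):
    """Estimator wrapper: fit clusters animals, score reports two-cut purity.

    ``fit(X)`` takes a genes × animals DataFrame (or SignatureMatrix values);
    fitted attributes are ``linkage_``, ``labels_`` (two-cut clusters) and
    ``pca_coords_``. ``score(X, y)`` returns the optimal-mapping purity of
    the fitted labels against ``y``.
    """

    def __init__(self, scale: bool = False):
        self.scale = scale

    def fit(self, X, y=None):
        X = X.values if isinstance(X, SignatureMatrix) else X
        self.linkage_ = hca(X)
        self.labels_ = two_cut_labels(self.linkage_, X.columns)
        self.pca_coords_ = pca_2d(X, scale=self.scale)
        return self

    def score(self, X=None, y=None):
        if y is None:
            raise ValueError("score needs true class labels")
        return separation_report(self.labels_, pd.Series(y, index=self.labels_.index) if not isinstance(y, pd.Series) else y).purity

    def report(self, y: pd.Series) -> SeparationReport:
        return separation_report(self.labels_, y)


def injury_labels(alt: pd.DataFrame, low_cut: float = 100.0, high_cut: float = 200.0) -> pd.Series:
    """Classify animals by serum ALT: below ``low_cut`` U/L is no-injury,
    at or above ``high_cut`` is injury, the gap in between is indeterminate.
    """
    a = alt.set_index("animal_id")["alt_u_per_l"] if isinstance(alt, pd.DataFrame) else alt
    if (a < 0).any():
        raise ValueError("negative ALT values")
    out = pd.Series("indeterminate", index=a.index, name="injury")
    out[a < low_cut] = "no_injury"
    out[a >= high_cut] = "injury"
    return out


def compare_signatures(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict:
    """Intersect two gene signatures and cross-tabulate their directions.

    Each input has columns gene_id and direction (sign of the gene's signal,
    'up' or 'down' — a signed S is mapped here if numeric). Returns the
    common gene table, the 2×2 direction cross-tab, and the union count.
    """
    def norm(df, suffix):
        d = df[["gene_id"]].copy()
        direction = df["direction"] if "direction" in df else np.where(df["S"] > 0, "up", "down")
        d[f"direction_{suffix}"] = direction
        return d

    a, b = norm(set_a, "a"), norm(set_b, "b")
    common = a.merge(b, on="gene_id", how="inner")
    crosstab = {
        (da, db): int(((common["direction_a"] == da) & (common["direction_b"] == db)).sum())
        for da in ("down", "up")
        for db in ("down", "up")
    }
    return {
        "common": common,
        "n_common": len(common),
        "n_union": len(set(a["gene_id"]) | set(b["gene_id"])),
        "crosstab": crosstab,
    }


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
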