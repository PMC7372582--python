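"""Response clustering, embeddings, and phenotypic dose trajectories.

Cell-line response clustering operates on a compound x cell-line matrix
of z-scores or Mahalanobis distances: each compound's row is centered and
scaled across the panel, cell lines are compared by Spearman correlation
(distance 1 - rho, range [0, 2]), and agglomeration uses complete
linkage.  On screens where cancer and control lines respond differently,
the control lines separate into their own clade.

PCA and t-SNE embeddings visualise well profiles; a fitted reference PCA
model can project query wells (e.g. a dose series of one compound) into
the reference space, where the dose trajectory — the path from the DMSO
centroid toward a mechanistic class's reference cluster — summarises how
a compound's phenotype develops with concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr
from sklearn.manifold import TSNE

from phenoscreen.hits import PhenotypicDistance
from phenoscreen.preprocess import feature_columns

__all__ = [
    "response_matrix",
    "Linkage",
    "cluster_cell_line_responses",
    "embed_pca",
    "embed_tsne",
    "dose_trajectory",
]


def response_matrix(values: pd.DataFrame, value_col: str = "z") -> tuple[pd.DataFrame, list[str]]:
    """Compound x cell-line matrix, centered and scaled per compound row.

    Accepts a long (compound, cell_line, value) frame or an already-wide
    matrix.  Rows (compounds) are centered to mean 0 and scaled to SD 1
    (sample SD); rows with zero variance or missing entries are excluded
    and returned separately.
    """
    if {"compound", "cell_line"} <= set(values.columns):
        wide = values.pivot_table(index="compound", columns="cell_line", values=value_col, aggfunc="median")
    else:
        wide = values.copy()
    sd = wide.std(axis=1, ddof=1)
    degenerate = sorted(wide.index[(sd == 0) | sd.isna() | wide.isna().any(axis=1)])
    wide = wide.drop(index=degenerate)
    scaled = wide.sub(wide.mean(axis=1), axis=0).div(sd.drop(index=degenerate), axis=0)
    return scaled, degenerate


@dataclass
class Linkage:
    """Agglomerative merge history over labelled leaves."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1) x 4
    method: str = "complete"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node, in merge order."""
        n = len(self.labels)
        sets: dict[int, frozenset[str]] = {i: frozenset([l]) for i, l in enumerate(self.labels)}
        out = []
        for k, (a, b, _, _) in enumerate(self.merges):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.merges)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            return f"({left}:{node.dist - node.left.dist:.6g},{right}:{node.dist - node.right.dist:.6g})"

        return walk(tree) + ";"

    def to_merge_list(self) -> list[dict]:
        return [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.merges
        ]


def spearman_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman rank correlation between columns (cell lines)."""
    for col in matrix.columns:
        if matrix[col].nunique() <= 1:
            raise ValueError(f"cell line {col!r} has a constant response column; correlation undefined")
    rho = spearmanr(matrix.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def cluster_cell_line_responses(matrix: pd.DataFrame, axis: str = "cell_lines") -> Linkage:
    """Complete-linkage clustering of a centered/scaled response matrix.

    ``axis='cell_lines'`` clusters the panel's columns; ``'compounds'``
    clusters rows (both axes are supported for biclustered heat maps).
    Distances are 1 - Spearman correlation.
    """
    if axis == "compounds":
        matrix = matrix.T
    elif axis != "cell_lines":
        raise ValueError("axis must be 'cell_lines' or 'compounds'")
    if matrix.shape[1] < 3 or matrix.shape[0] < 3:
        raise ValueError("need at least 3 cell lines and 3 compounds")
    dist = spearman_distance_matrix(matrix)
    condensed = dist.to_numpy()[np.triu_indices(len(dist), k=1)]
    merges = hierarchy.linkage(condensed, method="complete")
    return Linkage(labels=list(dist.columns), merges=merges, method="complete")


def embed_pca(
    profiles: pd.DataFrame,
    n_components: int = 2,
    model: PhenotypicDistance | None = None,
) -> pd.DataFrame:
    """PC coordinates per well; a supplied fitted model projects without refitting."""
    if model is None:
        model = PhenotypicDistance(n_components=n_components)
        feats = feature_columns(profiles)
        values = profiles[feats].to_numpy(dtype=np.float64)
        model.fit(profiles, dmso_mask=(profiles["role"] == "vehicle_control").to_numpy()
                  if "role" in profiles.columns else np.ones(len(profiles), dtype=bool))
    scores = model.transform(profiles)[:, :n_components]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, columns=cols, index=profiles.index)


def embed_tsne(profiles: pd.DataFrame, perplexity: float = 30.0, seed: int = 0, max_iter: int = 1000) -> pd.DataFrame:
    """2-D t-SNE embedding of well profiles; deterministic given ``seed``."""
    feats = feature_columns(profiles)
    X = profiles[feats].to_numpy(dtype=np.float64)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for {X.shape[0]} wells (need n > 3*perplexity)")
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca", max_iter=max_iter
    ).fit_transform(X)
    return pd.DataFrame(emb, columns=["TSNE1", "TSNE2"], index=profiles.index)


def dose_trajectory(
    model: PhenotypicDistance,
    reference_scores: pd.DataFrame,
    reference_labels: pd.Series,
    query_profiles: pd.DataFrame,
    doses: pd.Series | None = None,
) -> pd.DataFrame:
    """Project a compound's dose series into reference PC space.

    For each dose (ascending): PC coordinates, Euclidean distance to the
    DMSO centroid, and the nearest mechanistic class by reference class
    centroid.  ``reference_scores`` are PC scores of the reference wells
    (e.g. ``model.transform(reference_profiles)``) and
    ``reference_labels`` their class labels (including ``"DMSO"``).
    """
    if doses is None:
        if "concentration" not in query_profiles.columns:
            raise ValueError("provide doses or a 'concentration' column; dose ordering is required")
        doses = query_profiles["concentration"]
    doses = pd.Series(np.asarray(doses, dtype=float), index=query_profiles.index)

    ref = np.asarray(reference_scores, dtype=np.float64)
    labels = np.asarray(reference_labels)
    centroids = {k: ref[labels == k].mean(axis=0) for k in np.unique(labels)}
    if "DMSO" not in centroids:
        raise ValueError("reference labels must include 'DMSO'")

    scores = model.transform(query_profiles)
    rows = []
    for dose in sorted(doses.unique()):
        pt = scores[(doses == dose).to_numpy()].mean(axis=0)
        dists = {k: float(np.linalg.norm(pt - c)) for k, c in centroids.items()}
        nearest = min(sorted(dists), key=lambda k: dists[k])
        rows.append({"dose": dose, "dist_to_dmso": dists["DMSO"], "nearest_class": nearest,
                     **{f"PC{i+1}": pt[i] for i in range(min(3, len(pt)))}})
    out = pd.DataFrame(rows)
    pts = np.array([scores[(doses == d).to_numpy()].mean(axis=0) for d in sorted(doses.unique())])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) if len(pts) > 1 else np.array([])
    out.attrs["trajectory_length"] = float(seg.sum())
    return out
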