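"""Specificity scoring and functional-profile clustering.

A hit that also perturbs JNK signaling, the pMet expression reporters,
total mRNA export, or cell viability — or that recurs across many
unrelated published RNAi screens — is less likely to be a dedicated
RAS/MAPK regulator.  The specificity score aggregates these lines of
evidence as a weighted mean of per-component cleanliness scores in [0, 1]
(1 = fully clean), and bins genes into high/medium/low specificity groups.
Missing components are skipped with renormalized weights and recorded.

Functional profiles across the secondary-screen assays are clustered
agglomeratively with distance 1 - uncentered correlation (average
linkage), so that genes acting in one complex — which perturb every assay
in the same proportions — form tight clades regardless of effect
magnitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

WESTERN_SCORES = {"specific": 1.0, "no_effect": 0.75, "nonspecific": 0.0}

DEFAULT_WEIGHTS = {
    "prior": 1.0,
    "jnk": 2.0,
    "pmet": 1.0,
    "western": 1.0,
    "retention": 1.0,
    "cell_count": 1.0,
}

INPUT_COLUMNS = {
    "prior": "prior_screen_hits",
    "jnk": ("jnk_rac1", "jnk_pgn"),
    "pmet": "pmet_gfp_effect",
    "western": "western_flag",
    "retention": "export_retention_index",
    "cell_count": "cell_count_effect",
}


def _ratio_penalty(effect: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Penalty = |effect| / |reference| clipped to [0, 1].

    An off-pathway effect as large as the gene's own pMAPK effect is fully
    penalized; effects beyond that cannot penalize further.
    """
    ref = np.maximum(np.abs(reference), 1e-12)
    return np.clip(np.abs(effect) / ref, 0.0, 1.0)


class SpecificityScorer(BaseEstimator, TransformerMixin):
    """Composite specificity score over secondary-screen evidence.

    Input is one row per gene with columns (all optional except
    ``pmapk_effect``, the reference magnitude the off-pathway penalties
    are scaled by):

    - ``prior_screen_hits``: occurrence count in previous published RNAi
      screens (supplied, never fetched).
    - ``jnk_rac1``, ``jnk_pgn``: log effects in the two pJNK assays.
    - ``pmet_gfp_effect``: log effect in the pMet-GFP reporter screen.
    - ``western_flag``: {"specific", "no_effect", "nonspecific"}.
    - ``export_retention_index``: nuclear mRNA retention index, 1 = control.
    - ``cell_count_effect``: log cell-count change (negative = toxic).

    Parameters
    ----------
    weights : per-component weights for the final weighted mean.
    prior_cap : prior-screen count at which that penalty saturates.
    retention_scale : retention-index excess over 1 giving full penalty.
    cell_count_scale : log cell-count drop giving full penalty.
    high_threshold, medium_threshold : group cutoffs on the final score.
    """

    def __init__(
        self,
        weights: dict[str, float] | None = None,
        prior_cap: int = 10,
        retention_scale: float = 1.0,
        cell_count_scale: float = 1.0,
        high_threshold: float = 0.75,
        medium_threshold: float = 0.5,
    ):
        self.weights = weights
        self.prior_cap = prior_cap
        self.retention_scale = retention_scale
        self.cell_count_scale = cell_count_scale
        self.high_threshold = high_threshold
        self.medium_threshold = medium_threshold

    def fit(self, X: pd.DataFrame, y=None):
        if "pmapk_effect" not in X.columns:
            raise ValueError("specificity inputs need a 'pmapk_effect' column")
        w = dict(DEFAULT_WEIGHTS)
        if self.weights:
            unknown = set(self.weights) - set(w)
            if unknown:
                raise ValueError(f"unknown component weight(s): {sorted(unknown)}")
            w.update(self.weights)
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("component weights must be nonnegative with positive sum")
        self.weights_ = w
        self.n_features_in_ = X.shape[1]
        return self

    def _component_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        n = len(X)
        ref = X["pmapk_effect"].to_numpy(dtype=float)
        scores = pd.DataFrame(index=X.index)

        def col(name):
            return X[name] if name in X.columns else pd.Series(np.nan, index=X.index)

        prior = col(INPUT_COLUMNS["prior"]).to_numpy(dtype=float)
        scores["score_prior"] = 1.0 - np.clip(prior / self.prior_cap, 0.0, 1.0)

        jnk1 = col(INPUT_COLUMNS["jnk"][0]).to_numpy(dtype=float)
        jnk2 = col(INPUT_COLUMNS["jnk"][1]).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            jnk_worst = np.fmax(np.abs(jnk1), np.abs(jnk2))  # fmax: ignore one NaN
        scores["score_jnk"] = 1.0 - _ratio_penalty(jnk_worst, ref)

        pmet = col(INPUT_COLUMNS["pmet"]).to_numpy(dtype=float)
        scores["score_pmet"] = 1.0 - _ratio_penalty(pmet, ref)

        western = col(INPUT_COLUMNS["western"])
        scores["score_western"] = western.map(WESTERN_SCORES).to_numpy(dtype=float)

        retention = col(INPUT_COLUMNS["retention"]).to_numpy(dtype=float)
        scores["score_retention"] = 1.0 - np.clip(
            np.maximum(retention - 1.0, 0.0) / self.retention_scale, 0.0, 1.0
        )

        cc = col(INPUT_COLUMNS["cell_count"]).to_numpy(dtype=float)
        scores["score_cell_count"] = 1.0 - np.clip(
            np.maximum(-cc, 0.0) / self.cell_count_scale, 0.0, 1.0
        )
        assert len(scores) == n
        return scores

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Specificity report: component scores, final score, group.

        NaN component scores (missing inputs) are excluded with weight
        renormalization; the ``n_components`` column records how many
        components entered each gene's score.
        """
        check_is_fitted(self, "weights_")
        scores = self._component_scores(X)
        comp_names = ["prior", "jnk", "pmet", "western", "retention", "cell_count"]
        mat = scores[[f"score_{c}" for c in comp_names]].to_numpy(dtype=float)
        w = np.asarray([self.weights_[c] for c in comp_names], dtype=float)
        present = ~np.isnan(mat)
        wsum = (present * w).sum(axis=1)
        if np.any(wsum == 0):
            raise ValueError("at least one specificity component must be present per gene")
        final = np.nansum(mat * w, axis=1) / wsum
        out = scores.copy()
        out.insert(0, "gene", X["gene"] if "gene" in X.columns else X.index)
        out["n_components"] = present.sum(axis=1)
        out["final_score"] = final
        out["group"] = np.where(
            final >= self.high_threshold,
            "high",
            np.where(final >= self.medium_threshold, "medium", "low"),
        )
        return out


def specificity_score(inputs: pd.DataFrame, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`SpecificityScorer`."""
    scorer = SpecificityScorer(**params)
    return scorer.fit(inputs).transform(inputs)


def uncentered_correlation_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - uncentered correlation (cosine distance) between rows.

    Raises on zero-norm rows; caller supplies row names for the message.
    """
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm profile row(s)")
    unit = X / norms[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    return 1.0 - corr


class ProfileClusterer(BaseEstimator):
    """Unsupervised hierarchical clustering of functional profiles.

    Fits an average-linkage agglomerative tree on 1 - uncentered
    correlation between gene profiles.  Genes are sorted by id before
    linkage so the tree is invariant to input order (ties broken by id).

    Fitted attributes
    -----------------
    linkage_ : scipy linkage matrix (on the id-sorted genes)
    labels_ : gene ids in the order the linkage refers to them
    leaf_order_ : gene ids in dendrogram leaf order
    """

    def __init__(self, method: str = "average"):
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 2:
            raise ValueError("need at least 2 genes to cluster")
        X = X.sort_index(kind="stable")
        values = X.to_numpy(dtype=float)
        norms = np.linalg.norm(values, axis=1)
        if np.any(norms == 0):
            bad = list(X.index[norms == 0])
            raise ValueError(f"constant (zero-norm) profile row(s): {bad}")
        dist = uncentered_correlation_distance(values)
        condensed = dist[np.triu_indices(len(X), k=1)]
        self.linkage_ = hierarchy.linkage(np.maximum(condensed, 0.0), method=self.method)
        self.labels_ = np.asarray(X.index, dtype=object)
        self.leaf_order_ = self.labels_[hierarchy.leaves_list(self.linkage_)]
        self.n_features_in_ = X.shape[1]
        return self

    def cophenetic_distance(self, gene_a, gene_b) -> float:
        """Tree (cophenetic) distance between two genes."""
        check_is_fitted(self, "linkage_")
        coph = hierarchy.cophenet(self.linkage_)
        n = len(self.labels_)
        idx = {g: i for i, g in enumerate(self.labels_)}
        i, j = sorted((idx[gene_a], idx[gene_b]))
        # condensed index
        k = n * i - i * (i + 1) // 2 + (j - i - 1)
        return float(coph[k])

    def clades(self, height: float) -> dict:
        """Flat clusters cut at the given tree height, as gene -> cluster id."""
        check_is_fitted(self, "linkage_")
        flat = hierarchy.fcluster(self.linkage_, t=height, criterion="distance")
        return dict(zip(self.labels_, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick serialization of the fitted tree with branch lengths."""
        check_is_fitted(self, "linkage_")
        tree = hierarchy.to_tree(self.linkage_)
        labels = self.labels_

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def cluster_profiles(profiles: pd.DataFrame, method: str = "average") -> ProfileClusterer:
    """Fit and return a :class:`ProfileClusterer` on a genes x assays table."""
    return ProfileClusterer(method=method).fit(profiles)
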