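"""PCA state embedding of per-recording metric feature vectors.

Each recording is summarized by a vector of named scalar metrics (burst
rate, network spike statistics, correlation summaries, distances, ...).
Columns are z-scored (the metrics carry wildly different units — percent,
per-minute rates, pixels), constant columns dropped, and the rows embedded
in 2-D by PCA (SVD of the centered, standardized matrix, as scikit-learn
implements it).  A deterministic sign convention — the largest-magnitude
loading of each component is positive — keeps coordinates reproducible.

Feature contributions are ranked by loading magnitude; cosine similarity
between a feature's 2-D loading vector and a "state" direction (for
labelled recordings: the difference of group centroids in the embedding
plane) identifies metrics aligned with a condition contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["FeatureMatrix", "EmbeddingResult", "assemble_features", "pca_embed", "rank_features", "state_direction"]


@dataclass
class FeatureMatrix:
    """Raw and standardized per-recording feature tables."""

    raw: pd.DataFrame
    standardized: pd.DataFrame
    dropped: list[str] = field(default_factory=list)
    means: pd.Series | None = None
    sds: pd.Series | None = None


@dataclass
class EmbeddingResult:
    """2-D PCA coordinates with loadings and the explained-variance spectrum."""

    coordinates: pd.DataFrame  # index = recordings, columns = ["X", "Y"]
    explained_variance_ratio: np.ndarray  # full spectrum, sums to 1
    loadings: pd.DataFrame  # index = features, columns = ["X", "Y"]


def assemble_features(results: dict[str, dict[str, float]]) -> FeatureMatrix:
    """Build a recordings × metrics table from per-recording metric dicts.

    Every recording must provide every metric; the error names the first
    offender.  Columns are ordered deterministically (sorted by name).
    Constant columns are dropped from the standardized copy with a warning.
    """
    if not results:
        raise ValueError("no recordings given")
    names = sorted({m for metrics in results.values() for m in metrics})
    for rec_name, metrics in results.items():
        missing = [m for m in names if m not in metrics]
        if missing:
            raise ValueError(f"recording {rec_name!r} is missing metric {missing[0]!r}")
    raw = pd.DataFrame.from_dict(results, orient="index")[names].astype(float)
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()][0]
        raise ValueError(f"missing value in metric {bad!r}")
    sds = raw.std(ddof=0)
    dropped = list(raw.columns[sds == 0.0])
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}")
    kept = raw.drop(columns=dropped)
    means = kept.mean()
    sds_kept = kept.std(ddof=0)
    standardized = (kept - means) / sds_kept
    return FeatureMatrix(raw=raw, standardized=standardized, dropped=dropped, means=means, sds=sds_kept)


def pca_embed(fm: FeatureMatrix, n_components: int = 2) -> EmbeddingResult:
    """Embed recordings in ``n_components`` dimensions via SVD-based PCA."""
    X = fm.standardized.to_numpy()
    n_rows, n_feats = X.shape
    if n_rows < 2:
        raise ValueError("PCA requires at least two recordings")
    if n_feats < 2:
        raise ValueError("PCA requires at least two non-constant features")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("zero total variance across recordings; PCA undefined")
    pca = PCA(n_components=min(n_rows, n_feats))
    scores = pca.fit_transform(X)
    comps = pca.components_  # (k, n_feats)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[c]))
        if comps[c, j] < 0:
            comps[c] *= -1.0
            scores[:, c] *= -1.0
    k = n_components
    if k > comps.shape[0]:
        raise ValueError(f"only {comps.shape[0]} components available")
    axis_names = ["X", "Y", *[f"PC{i + 1}" for i in range(2, k)]][:k]
    coordinates = pd.DataFrame(scores[:, :k], index=fm.standardized.index, columns=axis_names)
    loadings = pd.DataFrame(comps[:k].T, index=fm.standardized.columns, columns=axis_names)
    evr = pca.explained_variance_ratio_
    return EmbeddingResult(coordinates=coordinates, explained_variance_ratio=evr, loadings=loadings)


def state_direction(emb: EmbeddingResult, labels: dict[str, str] | pd.Series, state: str) -> np.ndarray:
    """Direction in the embedding plane separating recordings labelled
    ``state`` from the rest: difference of the two group centroids."""
    labels = pd.Series(labels).reindex(emb.coordinates.index)
    if labels.isna().any():
        raise ValueError("every recording needs a label")
    in_state = labels == state
    if not in_state.any() or in_state.all():
        raise ValueError(f"state {state!r} must label a proper subset of recordings")
    xy = emb.coordinates[["X", "Y"]].to_numpy()
    direction = xy[in_state.to_numpy()].mean(axis=0) - xy[~in_state.to_numpy()].mean(axis=0)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("group centroids coincide; direction undefined")
    return direction / norm


def rank_features(
    emb: EmbeddingResult,
    top_k: int = 8,
    component: str = "X",
    direction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Most and least significant features for a component or state direction.

    Without ``direction``: features ranked by |loading| on ``component``.
    With a 2-vector ``direction``: ranked by the 2-D loading norm, and a
    ``cosine_similarity`` column gives the cosine between each feature's
    2-D loading vector and the direction.  Returns the full ranking with a
    ``rank`` column (1 = most significant) and a ``group`` column marking
    the top-``top_k`` and bottom-``top_k`` entries.
    """
    load2d = emb.loadings[["X", "Y"]].to_numpy()
    if direction is not None:
        direction = np.asarray(direction, dtype=float)
        dnorm = np.linalg.norm(direction)
        if dnorm == 0:
            raise ValueError("direction must be non-zero")
        score = np.linalg.norm(load2d, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (load2d @ direction) / (np.linalg.norm(load2d, axis=1) * dnorm)
        cos = np.nan_to_num(cos)
    else:
        score = np.abs(emb.loadings[component].to_numpy())
        cos = None
    n = len(score)
    if top_k > n:
        warnings.warn(f"top_k {top_k} exceeds {n} features; truncating")
        top_k = n
    order = np.argsort(-score, kind="stable")
    out = pd.DataFrame(
        {
            "feature": emb.loadings.index.to_numpy()[order],
            "score": score[order],
            "rank": np.arange(1, n + 1),
        }
    )
    if cos is not None:
        out["cosine_similarity"] = cos[order]
    group = np.full(n, "", dtype=object)
    group[:top_k] = "most"
    bottom = np.arange(max(n - top_k, top_k), n)
    group[bottom] = np.where(group[bottom] == "", "least", group[bottom])
    out["group"] = group
    return out
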