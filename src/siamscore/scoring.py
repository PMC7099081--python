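"""Continuous severity scores from anchor pools, and longitudinal change.

A single image is scored by embedding it and a pool of reference "normal"
images (grade-0, or the lowest-ranked images when an expert severity rank is
available) and taking the *median* of the Euclidean distances to the
anchors.  Larger median distance = more severe.  Longitudinal change between
two visits is quantified two ways:

* ``change_delta`` — the signed difference of the two severity scores
  (positive = worsening), both computed against the same anchor pool;
* ``change_pairwise`` — the direct embedding distance between the two
  images, which is symmetric and therefore loses directionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .siamese import euclidean_distance

__all__ = [
    "AnchorPool",
    "SeverityScore",
    "ChangeScore",
    "build_anchor_pool",
    "severity_score",
    "change_delta",
    "change_pairwise",
    "track_longitudinal",
]


@dataclass
class AnchorPool:
    """Reference images against which severity is measured.

    ``records`` are manifest rows; embeddings are computed lazily once per
    (pool, model) and cached.
    """

    records: pd.DataFrame
    strategy: str
    seed: int | None = None
    _embeddings: np.ndarray | None = field(default=None, repr=False)
    _embed_key: int | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def embeddings(self, model, store) -> np.ndarray:
        # cache key includes a weight fingerprint so stale embeddings are
        # never reused after the model's weights change
        fingerprint = getattr(model, "weights_fingerprint", lambda: None)()
        key = (id(model), fingerprint)
        if self._embeddings is None or self._embed_key != key:
            imgs = np.stack([store.get(p) for p in self.records["image_path"]])
            self._embeddings = model.embed_batch(imgs)
            self._embed_key = key
        return self._embeddings


@dataclass(frozen=True)
class SeverityScore:
    """Median anchor distance plus the underlying per-anchor distances."""

    median_distance: float
    per_anchor_distances: tuple[float, ...]


@dataclass(frozen=True)
class ChangeScore:
    """Signed score difference and direct pairwise distance for two visits."""

    delta_median: float
    pairwise_distance: float


def _median(values: np.ndarray) -> float:
    """Median with the even-count convention: mean of the two central values."""
    return float(np.median(values))


def build_anchor_pool(manifest: pd.DataFrame, strategy: str = "random_normal",
                      pool_size: int = 10, seed: int = 0,
                      rank_column: str = "severity_rank") -> AnchorPool:
    """Select anchor images.

    ``random_normal`` draws ``pool_size`` grade-0 images uniformly without
    replacement (default pool of 10).  ``ranked_least`` takes the
    ``pool_size`` images with the lowest value in ``rank_column`` (default
    pool of 5, for manifests carrying an expert severity rank).
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if strategy == "random_normal":
        normals = manifest[manifest["grade"] == 0]
        if len(normals) < pool_size:
            raise ValueError(
                f"need {pool_size} grade-0 images for the anchor pool, found {len(normals)}")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(normals), size=pool_size, replace=False)
        records = normals.iloc[np.sort(idx)].reset_index(drop=True)
    elif strategy == "ranked_least":
        if rank_column not in manifest.columns:
            raise ValueError(f"manifest has no {rank_column!r} column for ranked_least")
        records = manifest.nsmallest(pool_size, rank_column).reset_index(drop=True)
    else:
        raise ValueError(f"unknown anchor strategy {strategy!r}")
    return AnchorPool(records=records, strategy=strategy, seed=seed)


def _distances_to_pool(embedding: np.ndarray, pool_emb: np.ndarray) -> np.ndarray:
    diff = pool_emb.astype(np.float64) - np.asarray(embedding, dtype=np.float64)[None, :]
    return np.sqrt((diff**2).sum(axis=1))


def severity_score(image: np.ndarray, pool: AnchorPool, model, store) -> SeverityScore:
    """Median Euclidean distance from ``image`` to the anchor pool."""
    if len(pool) == 0:
        raise ValueError("anchor pool is empty")
    emb = model.embed(image)
    dists = _distances_to_pool(emb, pool.embeddings(model, store))
    return SeverityScore(_median(dists), tuple(float(d) for d in dists))


def change_delta(image_t1: np.ndarray, image_t2: np.ndarray, pool: AnchorPool,
                 model, store) -> float:
    """Signed severity change: score(t2) − score(t1), same pool for both."""
    s1 = severity_score(image_t1, pool, model, store)
    s2 = severity_score(image_t2, pool, model, store)
    return s2.median_distance - s1.median_distance


def change_pairwise(image_t1: np.ndarray, image_t2: np.ndarray, model) -> float:
    """Direct embedding distance between the two visits (symmetric)."""
    return euclidean_distance(model.embed(image_t1), model.embed(image_t2))


def track_longitudinal(unit_manifest: pd.DataFrame, pool: AnchorPool, model,
                       store) -> pd.DataFrame:
    """Per-visit severity score and pairwise distance to the baseline visit.

    ``unit_manifest`` holds one unit's rows; visits are ordered by timepoint.
    Returns a DataFrame with columns timepoint, severity_score,
    pairwise_to_baseline (0 for the first visit).
    """
    if len(unit_manifest) == 0:
        raise ValueError("unit has no visits")
    rows = unit_manifest.sort_values("timepoint")
    images = [store.get(p) for p in rows["image_path"]]
    baseline_emb = model.embed(images[0])
    out = []
    for (_, rec), img in zip(rows.iterrows(), images):
        sc = severity_score(img, pool, model, store)
        pair = euclidean_distance(model.embed(img), baseline_emb)
        out.append({"timepoint": int(rec["timepoint"]),
                    "severity_score": sc.median_distance,
                    "pairwise_to_baseline": pair})
    out[0]["pairwise_to_baseline"] = 0.0
    return pd.DataFrame(out)
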