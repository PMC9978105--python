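"""Single-subject short-distance ERP averaging (SSE).

The pipeline replaces every trial by an alignment-aware average of its
nearest neighbours, computed strictly within the trial's own
``(subject, label)`` group:

1. partition trials by subject and condition label;
2. within each group, build the symmetric matrix of summed per-channel DTW
   distances between every pair of trials;
3. for each anchor trial take the ``N`` nearest trials (anchor included) —
   its *similar sample group*;
4. for each channel independently, replace the anchor's channel by the
   Soft-DTW barycenter of that channel across the similar group, initialised
   at the anchor's own channel.

The output dataset has exactly the input's trial count, shapes and metadata.
Because every step is confined to one subject and one label, the transform
never mixes subjects, conditions or channels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .barycenter import solve_barycenter
from .data import EpochDataset
from .dtw import epoch_distance

__all__ = ["group_trials", "build_distance_matrix", "similar_group",
           "sse_average", "compute_group_distances", "SSEAverager"]


def group_trials(dataset: EpochDataset) -> dict:
    """Partition trial indices by ``(subject_id, label)``, keys sorted."""
    groups: dict = {}
    for i in range(len(dataset)):
        key = (str(dataset.subject_ids[i]), str(dataset.labels[i]))
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(groups[k]) for k in sorted(groups)}


def build_distance_matrix(epochs, metric: str = "sqeuclidean") -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise summed-channel DTW distances.

    ``epochs`` is a sequence/array of ``(n_samples, n_channels)`` trials.
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("expected a nonempty (n_trials, n_samples, n_channels) array")
    k = epochs.shape[0]
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = epoch_distance(epochs[i], epochs[j], metric)
            dm[i, j] = dm[j, i] = d
    return dm


def similar_group(dm: np.ndarray, anchor: int, n_similar: int) -> np.ndarray:
    """Indices of the ``n_similar`` nearest trials to ``anchor`` (self included).

    Distance ties break by ascending trial index (stable sort); if
    ``n_similar`` exceeds the group size the whole group is returned.
    Members are returned in ascending index order.
    """
    dm = np.asarray(dm)
    k = dm.shape[0]
    if not 0 <= anchor < k:
        raise IndexError(f"anchor {anchor} out of range for group of size {k}")
    if n_similar < 1:
        raise ValueError("n_similar must be >= 1")
    order = np.argsort(dm[anchor], kind="stable")
    members = np.sort(order[:min(n_similar, k)])
    if anchor not in members:                      # degenerate tie at 0 distance
        members = np.sort(np.r_[anchor, members[:-1]])
    return members


def _group_cache_path(cache_dir: Path, key) -> Path:
    tag = hashlib.sha1(f"{key[0]}|{key[1]}".encode()).hexdigest()[:16]
    return cache_dir / f"dm_{tag}.npy"


def compute_group_distances(dataset: EpochDataset, metric: str = "sqeuclidean",
                            cache_dir=None) -> dict:
    """Distance matrices for every ``(subject, label)`` group.

    With ``cache_dir`` set, each matrix is stored as one ``.npy`` file under
    a JSON index and reloaded on subsequent calls (the matrices are the
    pipeline's expensive stage and are computed before any model training).
    """
    groups = group_trials(dataset)
    matrices = {}
    index = {}
    cache_dir = Path(cache_dir) if cache_dir is not None else None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
    for key, idx in groups.items():
        path = _group_cache_path(cache_dir, key) if cache_dir else None
        if path is not None and path.exists():
            dm = np.load(path)
            if dm.shape != (len(idx), len(idx)):
                raise ValueError(
                    f"cached matrix {path} has shape {dm.shape}, group has {len(idx)} trials"
                )
        else:
            dm = build_distance_matrix(dataset.data[idx], metric)
            if path is not None:
                np.save(path, dm)
        matrices[key] = dm
        if cache_dir is not None:
            index[f"{key[0]}|{key[1]}"] = {
                "file": path.name, "n_trials": int(len(idx)), "metric": metric,
            }
    if cache_dir is not None:
        (cache_dir / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    return matrices


def sse_average(dataset: EpochDataset, n_similar: int, gamma: float = 1.0,
                metric: str = "sqeuclidean", max_iter: int = 50,
                tol: float = 1e-5, cache_dir=None,
                distance_matrices: dict | None = None) -> EpochDataset:
    """Run the full SSE pipeline and return the averaged dataset.

    ``n_similar == 1`` returns a verbatim copy (a one-series barycenter is
    the identity up to optimiser drift, so it is bypassed exactly).  Failed
    channel optimisations are collected and reported with their
    ``(trial, channel)`` coordinates.
    """
    if n_similar < 1:
        raise ValueError("n_similar must be >= 1")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    out = dataset.copy()
    if n_similar == 1 or len(dataset) == 0:
        return out
    if distance_matrices is None:
        distance_matrices = compute_group_distances(dataset, metric, cache_dir)
    groups = group_trials(dataset)
    failures = []
    for key, idx in groups.items():
        dm = distance_matrices[key]
        for local, trial in enumerate(idx):
            members = similar_group(dm, local, n_similar)
            if len(members) == 1:
                continue
            member_trials = idx[members]
            for ch in range(dataset.n_channels):
                series = [dataset.data[t, :, ch][np.newaxis, :]
                          for t in member_trials]
                init = dataset.data[trial, :, ch][np.newaxis, :]
                try:
                    res = solve_barycenter(
                        series, init=init, gamma=gamma, metric=metric,
                        max_iter=max_iter, tol=tol, record_trace=False,
                    )
                except FloatingPointError as err:
                    failures.append((int(trial), int(ch), str(err)))
                    continue
                out.data[trial, :, ch] = res.x[0]
    if failures:
        raise FloatingPointError(
            f"barycenter failed for (trial, channel) pairs: "
            f"{[(t, c) for t, c, _ in failures[:10]]}"
            + ("..." if len(failures) > 10 else "")
        )
    return out


class SSEAverager(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer wrapping the SSE pipeline.

    The transform is *transductive*: every trial is averaged with its
    nearest same-subject same-label neighbours inside the dataset being
    transformed, so labels and subject groups must accompany the data.  Use
    :meth:`fit_transform` with ``X`` of shape ``(n_trials, n_samples,
    n_channels)``, ``y`` the string labels and ``groups`` the subject IDs.
    Since no information crosses subjects, applying it to a full dataset
    before subject-wise cross-validation leaks nothing across folds.

    Parameters
    ----------
    n_similar : int, default 25
        Similar-sample-group size ``N`` (the full-scale operating point).
    gamma : float, default 1.0
        Soft-DTW smoothing parameter used for the barycenters.
    metric : {"sqeuclidean", "euclidean"}, default "sqeuclidean"
    max_iter, tol : L-BFGS stopping controls per barycenter.
    cache_dir : optional path for distance-matrix caching.
    """

    def __init__(self, n_similar: int = 25, gamma: float = 1.0,
                 metric: str = "sqeuclidean", max_iter: int = 50,
                 tol: float = 1e-5, cache_dir=None):
        self.n_similar = n_similar
        self.gamma = gamma
        self.metric = metric
        self.max_iter = max_iter
        self.tol = tol
        self.cache_dir = cache_dir

    def _to_dataset(self, X, y, groups) -> EpochDataset:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_trials, n_samples, n_channels), got {X.shape}"
            )
        if y is None or groups is None:
            raise ValueError("SSEAverager requires y (labels) and groups (subject IDs)")
        return EpochDataset(
            data=X, subject_ids=np.asarray(groups), labels=np.asarray(y),
            trial_ids=np.arange(X.shape[0]),
        )

    def fit(self, X, y=None, groups=None):
        """Compute and cache the per-group distance matrices."""
        ds = self._to_dataset(X, y, groups)
        self.distance_matrices_ = compute_group_distances(
            ds, self.metric, self.cache_dir
        )
        self.n_features_in_ = X.shape[1] * X.shape[2] if np.ndim(X) == 3 else None
        self._fit_shape = np.asarray(X).shape
        return self

    def transform(self, X, y=None, groups=None):
        """Averaged trials, same shape as ``X``.

        Must be called with the same data that was fitted (the method is
        transductive); passing new data re-runs fit on it.
        """
        if not hasattr(self, "distance_matrices_") or \
                np.asarray(X).shape != self._fit_shape:
            self.fit(X, y=y, groups=groups)
        ds = self._to_dataset(X, y, groups)
        out = sse_average(
            ds, self.n_similar, gamma=self.gamma, metric=self.metric,
            max_iter=self.max_iter, tol=self.tol,
            distance_matrices=self.distance_matrices_,
        )
        return out.data

    def fit_transform(self, X, y=None, groups=None):
        return self.fit(X, y=y, groups=groups).transform(X, y=y, groups=groups)

    def transform_dataset(self, dataset: EpochDataset) -> EpochDataset:
        """EpochDataset-in, EpochDataset-out convenience wrapper."""
        return sse_average(
            dataset, self.n_similar, gamma=self.gamma, metric=self.metric,
            max_iter=self.max_iter, tol=self.tol, cache_dir=self.cache_dir,
        )
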