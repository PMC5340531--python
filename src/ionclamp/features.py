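"""Trace preprocessing and the two-stage PCA kinetic score space.

Current responses are made conductance-invariant and comparable across
channels by (1) flipping inward-dominated trace sets, (2) dividing by the
set-wide maximum, (3) restricting to the protocol's analysis window,
(4) subsampling each trace to 512 points and (5) concatenating over graded
steps (and calcium levels).  Per protocol, an ensemble of such feature
vectors is Z-scored column-wise and reduced by PCA retaining 99% of the
variance; the resulting *condition scores* are rescaled by the standard
deviation of all their entries, concatenated over the five protocols and
reduced once more by PCA (99%) to a final *total score* per channel.
Kinetic similarity between two channels is the Euclidean distance of their
total scores.

The fitted transforms are stored so that additional channels — simulated
or experimentally recorded — can be projected into the same score space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .protocols import PROTOCOL_NAMES, VoltageProtocol
from .simulate import CurrentTraceSet

__all__ = [
    "SUBSAMPLE_POINTS",
    "FeatureVector",
    "ScoreVector",
    "preprocess",
    "TwoStagePCAScorer",
    "fit_score_space",
    "project",
    "similarity",
]

SUBSAMPLE_POINTS = 512


@dataclass(frozen=True)
class FeatureVector:
    """Normalized, subsampled, concatenated current response of one protocol."""

    protocol_name: str
    values: np.ndarray
    all_zero: bool = False


def window_indices(window: tuple[float, float], dt: float, n_points: int = SUBSAMPLE_POINTS) -> np.ndarray:
    """Sample indices that uniformly subsample [TA, TB] to ``n_points`` (endpoints included)."""
    i_a = round(window[0] / dt)
    i_b = round(window[1] / dt)
    return np.round(np.linspace(i_a, i_b, n_points)).astype(int)


def preprocess(traces: CurrentTraceSet, protocol: VoltageProtocol | None = None) -> FeatureVector:
    """Reduce a trace set to its feature vector.

    A set is *inward-dominated* when its absolute minimum exceeds its
    absolute maximum; such sets are flipped wholesale so that the dominant
    deflection is positive.  Normalization divides the whole (flipped) set
    by its maximum value, cancelling the maximal conductance.  An all-zero
    set cannot be normalized; it yields a zero vector flagged ``all_zero``.
    """
    m = np.asarray(traces.traces, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("trace set contains non-finite values")
    window = protocol.analysis_window if protocol is not None else traces.analysis_window
    dt = protocol.dt if protocol is not None else traces.dt

    if abs(m.min()) > abs(m.max()):
        m = -m
    peak = m.max()
    idx = window_indices(window, dt)
    if peak == 0.0:
        warnings.warn(
            f"all-zero trace set for channel {traces.channel_id!r}, "
            f"protocol {traces.protocol_name!r}; returning a zero feature vector",
            stacklevel=2,
        )
        return FeatureVector(traces.protocol_name, np.zeros(m.shape[0] * idx.size), all_zero=True)
    m = m / peak
    return FeatureVector(traces.protocol_name, m[:, idx].ravel())


def preprocess_all(
    trace_sets: dict[str, CurrentTraceSet],
    protocols: dict[str, VoltageProtocol] | None = None,
) -> dict[str, FeatureVector]:
    """Preprocess one channel's responses to all five protocols."""
    return {
        name: preprocess(trace_sets[name], protocols[name] if protocols else None)
        for name in PROTOCOL_NAMES
    }


@dataclass
class ScoreVector:
    """A channel's kinetic fingerprint in a fitted score space."""

    channel_id: str
    total: np.ndarray
    conditions: dict[str, np.ndarray]
    space: "TwoStagePCAScorer" = field(repr=False, default=None)


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    """Orient each principal axis so its largest-magnitude loading is positive."""
    if components.size == 0:
        return components
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def _fit_pca(x: np.ndarray, variance_threshold: float, center: bool = True) -> tuple[np.ndarray, np.ndarray, float]:
    """PCA retaining the smallest dimensionality with >= threshold variance.

    Returns (mean, components, variance_retained); degenerate inputs with
    no variance yield a single zero component.
    """
    n, p = x.shape
    mean = x.mean(axis=0) if center else np.zeros(p)
    xc = x - mean
    total_var = float(np.sum(xc**2))
    if total_var < 1e-24:
        return mean, np.zeros((1, p)), 1.0
    if center:
        if variance_threshold >= 1.0:
            pca = PCA(n_components=min(n, p), svd_solver="full")
        else:
            pca = PCA(n_components=variance_threshold, svd_solver="full")
        pca.fit(x)
        components = pca.components_
        retained = float(np.sum(pca.explained_variance_ratio_))
    else:
        # uncentered variant (sklearn's PCA always centers): plain SVD
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        ratio = s**2 / np.sum(s**2)
        d = int(np.searchsorted(np.cumsum(ratio), min(variance_threshold, 1.0) - 1e-12) + 1)
        d = min(d, len(s))
        components = vt[:d]
        retained = float(np.sum(ratio[:d]))
    components = _fix_component_signs(components)
    return mean, components, retained


class TwoStagePCAScorer(BaseEstimator, TransformerMixin):
    """Two-stage blockwise PCA score space (scikit-learn transformer).

    ``fit`` takes an ``(N, sum_b L_b)`` matrix of per-channel feature
    vectors, the per-protocol blocks concatenated in ``blocks`` order.
    Per block: columns are Z-scored (population std; zero-variance columns
    map to 0) and reduced by PCA retaining ``variance_threshold`` of the
    variance; the block's scores are divided by the standard deviation of
    all their entries; the normalized condition scores are concatenated and
    reduced by a final PCA (same criterion), giving the total scores.

    Parameters
    ----------
    blocks : list of (name, length) pairs
        Protocol feature-vector layout of the input matrix.
    variance_threshold : float in (0, 1]
        Cumulative explained-variance criterion for both PCA stages.
    zscore_ddof : {0, 1}
        Degrees of freedom for the column standard deviations.
    center_final : bool
        Whether the final PCA re-centers the concatenated condition scores.

    Attributes (after ``fit``)
    --------------------------
    block_means_, block_stds_ : per-block Z-scoring parameters
    block_components_ : per-block principal axes (rows)
    block_dims_ : per-block retained dimensionalities
    block_normalizers_ : per-block condition-score scale factors
    final_mean_, final_components_ : final-stage PCA
    n_dimensions_ : total-score dimensionality D
    scores_ : (N, D) total scores of the fitted ensemble
    ensemble_ids_ : channel ids of the fitted ensemble (if given to fit)
    """

    def __init__(
        self,
        blocks: list[tuple[str, int]] | None = None,
        variance_threshold: float = 0.99,
        zscore_ddof: int = 0,
        center_final: bool = True,
    ):
        self.blocks = blocks
        self.variance_threshold = variance_threshold
        self.zscore_ddof = zscore_ddof
        self.center_final = center_final

    # -- internals ---------------------------------------------------------

    def _block_slices(self) -> list[tuple[str, slice]]:
        out, i0 = [], 0
        for name, length in self.blocks:
            out.append((name, slice(i0, i0 + length)))
            i0 += length
        return out

    def _condition_scores(self, x: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for b, (name, sl) in enumerate(self._block_slices()):
            z = (x[:, sl] - self.block_means_[b]) * self.block_inv_stds_[b]
            scores = (z - self.block_pca_means_[b]) @ self.block_components_[b].T
            out[name] = scores / self.block_normalizers_[b]
        return out

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None, ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if self.blocks is None:
            raise ValueError("blocks must be set before fitting")
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least two channels")
        expected = sum(length for _, length in self.blocks)
        if X.shape[1] != expected:
            raise ValueError(f"feature matrix has {X.shape[1]} columns, blocks imply {expected}")
        if not (0 < self.variance_threshold <= 1):
            raise ValueError("variance_threshold must lie in (0, 1]")

        self.block_means_, self.block_inv_stds_ = [], []
        self.block_pca_means_, self.block_components_ = [], []
        self.block_normalizers_, self.block_dims_ = [], []
        self.block_variance_retained_ = []
        for name, sl in self._block_slices():
            xb = X[:, sl]
            mean = xb.mean(axis=0)
            std = xb.std(axis=0, ddof=self.zscore_ddof)
            inv = np.where(std > 0, 1.0 / np.where(std > 0, std, 1.0), 0.0)
            z = (xb - mean) * inv
            pca_mean, components, retained = _fit_pca(z, self.variance_threshold)
            scores = (z - pca_mean) @ components.T
            norm = float(scores.std())
            if norm == 0.0:
                norm = 1.0
            self.block_means_.append(mean)
            self.block_inv_stds_.append(inv)
            self.block_pca_means_.append(pca_mean)
            self.block_components_.append(components)
            self.block_normalizers_.append(norm)
            self.block_dims_.append(components.shape[0])
            self.block_variance_retained_.append(retained)

        cond = self._condition_scores(X)
        combined = np.hstack([cond[name] for name, _ in self.blocks])
        self.final_mean_, self.final_components_, self.final_variance_retained_ = _fit_pca(
            combined, self.variance_threshold, center=self.center_final
        )
        self.n_dimensions_ = self.final_components_.shape[0]
        self.scores_ = (combined - self.final_mean_) @ self.final_components_.T
        self.ensemble_ids_ = list(ids) if ids is not None else None
        return self

    def transform(self, X) -> np.ndarray:
        """Project feature matrices into the fitted total-score space."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        expected = sum(length for _, length in self.blocks)
        if X.shape[1] != expected:
            raise ValueError(f"feature matrix has {X.shape[1]} columns, space expects {expected}")
        cond = self._condition_scores(X)
        combined = np.hstack([cond[name] for name, _ in self.blocks])
        return (combined - self.final_mean_) @ self.final_components_.T

    # -- persistence -------------------------------------------------------

    def to_npz(self, path) -> None:
        """Serialize the fitted space to a single .npz archive."""
        meta = {
            "blocks": self.blocks,
            "variance_threshold": self.variance_threshold,
            "zscore_ddof": self.zscore_ddof,
            "center_final": self.center_final,
            "block_normalizers": self.block_normalizers_,
            "ensemble_ids": self.ensemble_ids_,
        }
        arrays = {"final_mean": self.final_mean_, "final_components": self.final_components_}
        if getattr(self, "scores_", None) is not None:
            arrays["scores"] = self.scores_
        for b, (name, _) in enumerate(self.blocks):
            arrays[f"{name}__mean"] = self.block_means_[b]
            arrays[f"{name}__inv_std"] = self.block_inv_stds_[b]
            arrays[f"{name}__pca_mean"] = self.block_pca_means_[b]
            arrays[f"{name}__components"] = self.block_components_[b]
        np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def from_npz(cls, path) -> "TwoStagePCAScorer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            obj = cls(
                blocks=[tuple(b) for b in meta["blocks"]],
                variance_threshold=meta["variance_threshold"],
                zscore_ddof=meta["zscore_ddof"],
                center_final=meta["center_final"],
            )
            obj.block_means_, obj.block_inv_stds_ = [], []
            obj.block_pca_means_, obj.block_components_ = [], []
            for name, _ in obj.blocks:
                obj.block_means_.append(data[f"{name}__mean"])
                obj.block_inv_stds_.append(data[f"{name}__inv_std"])
                obj.block_pca_means_.append(data[f"{name}__pca_mean"])
                obj.block_components_.append(data[f"{name}__components"])
            obj.block_normalizers_ = list(meta["block_normalizers"])
            obj.block_dims_ = [c.shape[0] for c in obj.block_components_]
            obj.final_mean_ = data["final_mean"]
            obj.final_components_ = data["final_components"]
            obj.n_dimensions_ = obj.final_components_.shape[0]
            obj.ensemble_ids_ = meta["ensemble_ids"]
            if "scores" in data:
                obj.scores_ = data["scores"]
        return obj


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def stack_features(
    features: dict[str, dict[str, FeatureVector]],
) -> tuple[np.ndarray, list[str], list[tuple[str, int]]]:
    """Stack per-channel, per-protocol features into an (N, sum L) matrix."""
    ids = list(features)
    first = features[ids[0]]
    blocks = [(name, first[name].values.size) for name in PROTOCOL_NAMES if name in first]
    rows = []
    for cid in ids:
        per = features[cid]
        for name, length in blocks:
            if per[name].values.size != length:
                raise ValueError(
                    f"channel {cid!r}: protocol {name!r} feature length "
                    f"{per[name].values.size} != {length}"
                )
        rows.append(np.concatenate([per[name].values for name, _ in blocks]))
    return np.asarray(rows), ids, blocks


def fit_score_space(
    features: dict[str, dict[str, FeatureVector]],
    variance_threshold: float = 0.99,
) -> TwoStagePCAScorer:
    """Fit the score space over an ensemble of channels (one ion class)."""
    x, ids, blocks = stack_features(features)
    scorer = TwoStagePCAScorer(blocks=blocks, variance_threshold=variance_threshold)
    scorer.fit(x, ids=ids)
    return scorer


def project(
    space: TwoStagePCAScorer,
    features: dict[str, FeatureVector],
    channel_id: str = "",
) -> ScoreVector:
    """Project one channel's per-protocol features into a fitted space."""
    parts = []
    for name, length in space.blocks:
        if name not in features:
            raise ValueError(f"missing features for protocol {name!r}")
        vec = features[name].values
        if vec.size != length:
            raise ValueError(
                f"protocol {name!r}: feature length {vec.size} does not match "
                f"the fitted space ({length})"
            )
        parts.append(vec)
    x = np.concatenate(parts)[None, :]
    cond = space._condition_scores(x)
    total = space.transform(x)[0]
    return ScoreVector(
        channel_id=channel_id,
        total=total,
        conditions={name: cond[name][0] for name, _ in space.blocks},
        space=space,
    )


def similarity(a: ScoreVector, b: ScoreVector) -> float:
    """Kinetic similarity: Euclidean distance between total scores."""
    if a.space is not b.space:
        raise ValueError("score vectors come from different score spaces")
    return float(np.linalg.norm(a.total - b.total))
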