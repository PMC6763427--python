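"""Group spatial ICA of stacked deconvolution maps (event-related ICA).

Each session's 48 peri-stimulus parameter maps are treated as an image
"time series".  Sessions are reduced individually by PCA (temporal
whitening), concatenated, reduced again at the group level, and unmixed
with Infomax ICA into spatially independent group components.
Back-reconstruction projects each group component into every dataset,
yielding a subject/condition-specific spatial map and a 48-point
component time course (24 points per RT class) — the quantities the
time-course statistics consume.

The Infomax implementation is native: natural-gradient ascent of the
information of a logistic squashing of the unmixed sources, with
learning-rate annealing, which favors the super-Gaussian sources typical
of spatial brain maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .fir import N_BINS, BIN_TIMES_S, ANALYZED_CLASSES, DeconvMaps

Z_THRESHOLD = 1.5

__all__ = [
    "Z_THRESHOLD",
    "InfomaxICA",
    "stack_datasets",
    "TwoStagePca",
    "GroupEICA",
    "ComponentMapZ",
    "zscore_and_threshold",
    "ComponentSelection",
    "select_components",
    "match_components",
]


# --------------------------------------------------------------------------
# Infomax ICA
# --------------------------------------------------------------------------

class InfomaxICA(TransformerMixin, BaseEstimator):
    """Infomax independent component analysis (natural gradient, logistic).

    Follows the scikit-learn decomposition conventions: ``fit(X)`` with
    ``X`` of shape (n_samples, n_features); ``components_`` has shape
    (n_components, n_features) and ``transform`` returns the estimated
    sources, (n_samples, n_components).

    The input is PCA-whitened, then the square unmixing matrix ``W`` is
    updated in shuffled mini-batches by the natural-gradient rule
    ``W <- W + lr (I + (1 - 2 g(U)) U^T / B) W`` with the logistic
    nonlinearity ``g``.  The learning rate anneals by ``anneal`` whenever
    the update direction turns by more than 60 degrees.  Deterministic
    under ``random_state``.

    Attributes
    ----------
    components_ : (n_components, n_features)
    mixing_ : (n_features, n_components)
    mean_ : (n_features,)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int | None = None,
        learning_rate: float = 0.01,
        anneal: float = 0.95,
        max_iter: int = 500,
        tol: float = 1e-7,
        block_size: int | None = None,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.learning_rate = learning_rate
        self.anneal = anneal
        self.max_iter = max_iter
        self.tol = tol
        self.block_size = block_size
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "InfomaxICA":
        X = np.asarray(X, dtype=float)
        n_samples, n_features = X.shape
        k = self.n_components or n_features
        if k > min(n_samples, n_features):
            raise ValueError("n_components exceeds data dimensions")
        rng = np.random.default_rng(self.random_state)

        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # PCA whitening to k dims
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        if s[k - 1] <= 1e-12 * s[0]:
            raise ValueError("data rank below n_components")
        self.whitening_ = (vt[:k].T / (s[:k] / np.sqrt(n_samples))).T  # (k, n_features)
        Xw = Xc @ self.whitening_.T  # (n_samples, k), identity covariance

        W = np.eye(k)
        block = self.block_size or max(8, int(np.sqrt(n_samples / 3.0)))
        lr = self.learning_rate
        prev_delta = None
        wchange = np.inf
        self.converged_ = False
        for it in range(self.max_iter):
            order = rng.permutation(n_samples)
            W_old = W.copy()
            restarted = False
            for start in range(0, n_samples, block):
                xb = Xw[order[start : start + block]]
                U = xb @ W.T
                Y = 1.0 / (1.0 + np.exp(-U))
                grad = np.eye(k) + (1.0 - 2.0 * Y).T @ U / len(xb)
                W = W + lr * grad @ W
                if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                    # blow-up: restart this pass with a smaller rate
                    lr *= 0.5
                    W = W_old.copy()
                    prev_delta = None
                    restarted = True
                    break
            if restarted:
                continue
            delta = (W - W_old).ravel()
            wchange = float(np.linalg.norm(delta))
            if prev_delta is not None:
                denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
                if denom > 0 and (delta @ prev_delta) / denom < 0.5:  # > 60 deg
                    lr *= self.anneal
            prev_delta = delta
            if wchange < self.tol:
                self.converged_ = True
                break
        self.n_iter_ = it + 1
        if not self.converged_:
            import warnings

            warnings.warn(
                f"Infomax did not converge in {self.max_iter} iterations "
                f"(wchange={wchange:.2e})"
            )
        self.unmixing_ = W  # on whitened data
        self.components_ = W @ self.whitening_
        self.mixing_ = np.linalg.pinv(self.components_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


# --------------------------------------------------------------------------
# stacking and two-stage PCA
# --------------------------------------------------------------------------

def stack_datasets(
    datasets: list[DeconvMaps], mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack DeconvMaps into per-dataset matrices over a common mask.

    Returns ``(data, mask, index)`` where ``data`` has shape
    (n_datasets, 48, n_mask_voxels) and ``index`` records (subject,
    condition) per dataset.  All datasets must share the grid; if no mask
    is given, voxels with nonzero variance in every dataset are used.
    """
    if not datasets:
        raise ValueError("no datasets to stack")
    shape = datasets[0].maps.shape
    for d in datasets:
        if d.maps.shape != shape:
            raise ValueError(
                f"grid mismatch: {d.subject}/{d.condition} has {d.maps.shape}, "
                f"expected {shape}"
            )
    flat = np.stack([d.maps.reshape(d.n_frames, -1) for d in datasets])
    if mask is None:
        mask_flat = np.all(flat.std(axis=1) > 0, axis=0)
    else:
        if mask.shape != shape[1:]:
            raise ValueError(f"mask shape {mask.shape} != grid {shape[1:]}")
        mask_flat = mask.reshape(-1).astype(bool)
    index = pd.DataFrame(
        {
            "subject": [d.subject for d in datasets],
            "condition": [d.condition for d in datasets],
        }
    )
    return flat[:, :, mask_flat], mask_flat, index


@dataclass
class TwoStagePca:
    """Two principal-component reductions: per dataset, then group-level.

    Stage 1 projects each dataset's 48-frame series (mean image removed)
    onto its top ``dataset_dims`` temporal principal directions — an
    unwhitened projection, so stronger directions keep their variance and
    the group stage can weight coherent signal above noise.  Stage 2
    reduces (and whitens) the concatenation of all reduced datasets to
    ``group_dims`` for the ICA.  The operators are retained for
    back-reconstruction (per-dataset basis, pseudo-inverse of the group
    reduction).
    """

    dataset_dims: int
    group_dims: int
    basis_: list[np.ndarray] = field(default_factory=list)  # (T, d1) each
    group_op_: np.ndarray | None = None  # (d2, N*d1)
    group_pinv_: np.ndarray | None = None  # (N*d1, d2)
    mean_: list[np.ndarray] = field(default_factory=list)  # per-voxel means
    var_kept_stage1_: list[float] = field(default_factory=list)
    var_kept_stage2_: float = np.nan

    def fit_transform(self, data: np.ndarray) -> np.ndarray:
        """``data``: (N, T, V) -> whitened group matrix (group_dims, V)."""
        n_sets, T, V = data.shape
        if self.dataset_dims > T:
            raise ValueError(f"dataset_dims {self.dataset_dims} > frames {T}")
        reduced = []
        for i in range(n_sets):
            Xi = data[i]
            mu = Xi.mean(axis=0)  # remove the mean image
            Xi = Xi - mu
            u, s, vt = np.linalg.svd(Xi, full_matrices=False)
            d1 = self.dataset_dims
            if s[d1 - 1] <= 1e-12 * max(s[0], 1e-300):
                raise ValueError(f"dataset {i}: rank below dataset_dims={d1}")
            self.mean_.append(mu)
            self.basis_.append(u[:, :d1])  # (T, d1), orthonormal columns
            reduced.append(self.basis_[-1].T @ Xi)  # (d1, V)
            self.var_kept_stage1_.append(
                float((s[:d1] ** 2).sum() / (s**2).sum())
            )
        R = np.concatenate(reduced, axis=0)  # (N*d1, V)
        if self.group_dims > R.shape[0]:
            raise ValueError("group_dims exceeds stacked dimension")
        u2, s2, _ = np.linalg.svd(R @ R.T / R.shape[1])
        if s2[self.group_dims - 1] <= 1e-12 * s2[0]:
            raise ValueError(f"group rank below group_dims={self.group_dims}")
        d2 = self.group_dims
        self.group_op_ = (u2[:, :d2] / np.sqrt(s2[:d2])).T  # (d2, N*d1)
        self.group_pinv_ = u2[:, :d2] * np.sqrt(s2[:d2])  # (N*d1, d2)
        self.var_kept_stage2_ = float(s2[:d2].sum() / s2.sum())
        self.reduced_ = reduced
        return self.group_op_ @ R

    def dataset_block(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(group_op block, group_pinv block) for dataset i."""
        d1 = self.dataset_dims
        sl = slice(i * d1, (i + 1) * d1)
        return self.group_op_[:, sl], self.group_pinv_[sl, :]


# --------------------------------------------------------------------------
# group eICA estimator
# --------------------------------------------------------------------------

class GroupEICA(BaseEstimator):
    """Group spatial ICA with GICA back-reconstruction.

    Parameters follow the study protocol by default: 20 components from
    the stack of datasets (two per subject), with per-dataset reduction
    to 30 of the 48 frames.  For small synthetic cohorts choose
    ``n_components`` and ``dataset_dims`` commensurate with the data.

    Attributes (after fit)
    ----------------------
    group_maps_ : (n_components, n_mask_voxels)
        Group spatial components, sign-fixed so each component's largest
        |weight| voxel is positive.
    mixing_ : (group_dims, n_components)
    timecourses_ : (n_datasets, 48, n_components)
        Back-reconstructed component time courses, frames ordered
        (class, bin): 0-23 normal, 24-47 lapse.
    dataset_maps_ : (n_datasets, n_components, n_mask_voxels)
    mask_ : flat boolean mask; index_ : DataFrame (subject, condition)
    """

    def __init__(
        self,
        n_components: int = 20,
        dataset_dims: int = 30,
        random_state: int | None = 0,
        max_iter: int = 500,
        learning_rate: float = 0.01,
    ):
        self.n_components = n_components
        self.dataset_dims = dataset_dims
        self.random_state = random_state
        self.max_iter = max_iter
        self.learning_rate = learning_rate

    def fit(self, datasets: list[DeconvMaps], y=None) -> "GroupEICA":
        data, mask_flat, index = stack_datasets(datasets)
        n_sets, T, V = data.shape
        d1 = min(self.dataset_dims, T)
        self.pca_ = TwoStagePca(dataset_dims=d1, group_dims=self.n_components)
        Y = self.pca_.fit_transform(data)  # (d2, V)

        ica = InfomaxICA(
            n_components=self.n_components,
            random_state=self.random_state,
            max_iter=self.max_iter,
            learning_rate=self.learning_rate,
        )
        # samples = voxels, features = reduced dims
        S = ica.fit_transform(Y.T).T  # (n_components, V)
        A = ica.mixing_  # (d2, n_components)

        # per-dataset back-reconstruction (GICA projection)
        tcs = np.empty((n_sets, T, self.n_components))
        dmaps = np.empty((n_sets, self.n_components, V))
        for i in range(n_sets):
            Gi, Gi_pinv = self.pca_.dataset_block(i)
            tcs[i] = self.pca_.basis_[i] @ Gi_pinv @ A  # (T, n_comp)
            Yi = Gi @ self.pca_.reduced_[i]  # dataset in group-reduced space
            Yi = Yi - Yi.mean(axis=1, keepdims=True)
            dmaps[i] = ica.components_ @ Yi

        # sign convention: max |weight| voxel positive, product invariant
        for c in range(self.n_components):
            v = np.argmax(np.abs(S[c]))
            if S[c, v] < 0:
                S[c] *= -1
                A[:, c] *= -1
                tcs[:, :, c] *= -1
                dmaps[:, c, :] *= -1

        self.ica_ = ica
        self.group_maps_ = S
        self.mixing_ = A
        self.timecourses_ = tcs
        self.dataset_maps_ = dmaps
        self.mask_ = mask_flat
        self.index_ = index
        self.grid_shape_ = datasets[0].maps.shape[1:]
        self.bin_times_ = BIN_TIMES_S.copy()
        self.classes_ = ANALYZED_CLASSES
        self.converged_ = ica.converged_
        return self

    def back_reconstruct(self, dataset: int) -> tuple[np.ndarray, np.ndarray]:
        """(per-dataset maps (n_comp, V), time courses (48, n_comp))."""
        check_is_fitted(self, "group_maps_")
        if not (0 <= dataset < len(self.index_)):
            raise KeyError(f"unknown dataset id {dataset}")
        return self.dataset_maps_[dataset], self.timecourses_[dataset]

    def unflatten(self, flat_map: np.ndarray) -> np.ndarray:
        """Embed a masked map back into the 3D grid (zeros outside)."""
        out = np.zeros(int(np.prod(self.grid_shape_)))
        out[self.mask_] = flat_map
        return out.reshape(self.grid_shape_)

    def mean_zmaps(self, threshold: float = Z_THRESHOLD) -> list["ComponentMapZ"]:
        check_is_fitted(self, "group_maps_")
        return [
            zscore_and_threshold(self.dataset_maps_[:, c, :].mean(axis=0), threshold)
            for c in range(self.n_components)
        ]

    def timecourse_table(self) -> pd.DataFrame:
        """Long-format per-dataset component time courses."""
        check_is_fitted(self, "timecourses_")
        rows = []
        labels = [(c, t) for c in self.classes_ for t in self.bin_times_]
        for i, (_, meta) in enumerate(self.index_.iterrows()):
            for comp in range(self.n_components):
                for f, (cls, t) in enumerate(labels):
                    rows.append(
                        (meta["subject"], meta["condition"], comp, cls, t,
                         self.timecourses_[i, f, comp])
                    )
        return pd.DataFrame(
            rows,
            columns=["subject", "condition", "component", "rt_class",
                     "bin_time", "value"],
        )


# --------------------------------------------------------------------------
# z maps and component selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentMapZ:
    """Voxel-wise z-scored mean back-reconstructed map with its support."""

    zmap: np.ndarray
    threshold: float
    support: np.ndarray  # boolean, z > threshold


def zscore_and_threshold(
    mean_map: np.ndarray, threshold: float = Z_THRESHOLD
) -> ComponentMapZ:
    """Scale a mean component map to z-scores and threshold at z > 1.5."""
    m = np.asarray(mean_map, dtype=float)
    sd = m.std()
    if sd == 0:
        raise ValueError("constant map cannot be z-scored")
    z = (m - m.mean()) / sd
    return ComponentMapZ(zmap=z, threshold=threshold, support=z > threshold)


@dataclass(frozen=True)
class ComponentSelection:
    retained: list[int]
    rejected: dict[int, str]
    consistency: dict[int, float]
    rim_overlap: dict[int, float]


def temporal_consistency(timecourses: np.ndarray, bin_times: np.ndarray) -> float:
    """mean over post-stimulus bins (both classes) of |mean| / SEM across
    datasets; higher means more consistent evoked behavior."""
    post = np.concatenate([bin_times >= 0.0, bin_times >= 0.0])
    tc = timecourses[:, post]  # (datasets, post bins)
    mean = tc.mean(axis=0)
    sem = tc.std(axis=0, ddof=1) / np.sqrt(tc.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(mean) / sem
    return float(np.nanmean(np.where(np.isfinite(ratio), ratio, 0.0)))


def select_components(
    model: GroupEICA,
    rim_mask: np.ndarray,
    overlap_fraction: float = 0.25,
    consistency_threshold: float = 1.0,
    z_threshold: float = Z_THRESHOLD,
    force_retain: tuple[int, ...] = (),
    force_reject: tuple[int, ...] = (),
) -> ComponentSelection:
    """Reject artifact-like or temporally inconsistent components.

    A component is rejected when the fraction of its thresholded support
    overlapping the rim/ventricle mask exceeds ``overlap_fraction``
    (peripheral/ventricular pattern), or when its temporal-consistency
    score falls below ``consistency_threshold``.  Overrides are honored
    and logged in the rejection-reason map.
    """
    rim_flat = np.asarray(rim_mask, dtype=bool).reshape(-1)[model.mask_]
    retained, rejected, cons, overlap = [], {}, {}, {}
    for c in range(model.n_components):
        z = zscore_and_threshold(model.dataset_maps_[:, c, :].mean(axis=0),
                                 z_threshold)
        n_sup = int(z.support.sum())
        frac = float((z.support & rim_flat).sum() / n_sup) if n_sup else 0.0
        score = temporal_consistency(model.timecourses_[:, :, c], model.bin_times_)
        cons[c] = score
        overlap[c] = frac
        if c in force_retain:
            retained.append(c)
            rejected.pop(c, None)
            continue
        if c in force_reject:
            rejected[c] = "forced rejection (override)"
        elif frac > overlap_fraction:
            rejected[c] = f"peripheral/ventricular overlap {frac:.2f}"
        elif score < consistency_threshold:
            rejected[c] = f"inconsistent time course (score {score:.2f})"
        else:
            retained.append(c)
    return ComponentSelection(
        retained=retained, rejected=rejected, consistency=cons, rim_overlap=overlap
    )


def match_components(
    estimated_maps: np.ndarray, truth_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of estimated to ground-truth maps by |corr|.

    Returns (assignment, |correlation| per truth map); ``assignment[j]``
    is the estimated component matched to truth map j.
    """
    from scipy.optimize import linear_sum_assignment

    est = np.asarray(estimated_maps, dtype=float)
    tru = np.asarray(truth_maps, dtype=float)
    corr = np.zeros((tru.shape[0], est.shape[0]))
    for j in range(tru.shape[0]):
        for c in range(est.shape[0]):
            corr[j, c] = np.corrcoef(tru[j], est[c])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = np.argsort(rows)
    return cols[order], np.abs(corr[rows, cols])[order]
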