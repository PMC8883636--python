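"""Second detection stage: class-specific linear refinement of proposal boxes.

A proposal box P = (P_lh, P_lw) is mapped toward the ground-truth box
G = (G_lh, G_lw) by two scalar offsets predicted from the proposal's global
feature f_mp:

    G_hat_lh = P_lw * d_lh + P_lh          (scale-invariant center shift)
    G_hat_lw = P_lw * exp(d_lw)            (log-space width change)

The regression targets are t_lh = (G_lh - P_lh) / P_lw and
t_lw = log(G_lw / P_lw); each offset is a linear function of f_mp with
weight vector T_* fitted by ridge (L2-regularized least squares) in closed
form via the normal equations.  Features are standardized with training-set
statistics stored in the regressor; the intercept is appended and left
unpenalized.  A gradient-descent fit of the same objective is available as an
optional cross-check path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Box3D, ConfigError, PixelCloud, clip_box, points_in_box
from .nn import PointSetClassifier
from .proposals import ScoredBox3D, normalize_points, sample_points

__all__ = [
    "RegressionTarget",
    "BoxRegressor",
    "RegressionDataset",
    "regression_targets",
    "apply_regression",
    "fit_regressor",
    "fit_regressor_gd",
    "predict_offsets",
    "refine_box",
    "train_regressor",
]


@dataclass(frozen=True)
class RegressionTarget:
    """Dimensionless transformation targets between a proposal and its truth."""

    t_lh: float
    t_lw: float


@dataclass
class BoxRegressor:
    """Linear ridge models T_lh, T_lw over standardized global features.

    ``w_lh`` and ``w_lw`` have length feature_dim + 1 (intercept last);
    ``feature_mean`` / ``feature_std`` are the training-set standardization
    statistics applied before the dot product.
    """

    class_label: str
    w_lh: np.ndarray
    w_lw: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    lam: float = 1.0

    @classmethod
    def identity(cls, class_label: str, feature_dim: int, lam: float = 1.0) -> "BoxRegressor":
        """A regressor predicting zero offsets (refinement is a no-op)."""
        return cls(
            class_label=class_label,
            w_lh=np.zeros(feature_dim + 1),
            w_lw=np.zeros(feature_dim + 1),
            feature_mean=np.zeros(feature_dim),
            feature_std=np.ones(feature_dim),
            lam=lam,
        )

    @property
    def feature_dim(self) -> int:
        return len(self.w_lh) - 1


def regression_targets(P: Box3D, G: Box3D) -> RegressionTarget:
    """Transformation targets t_lh, t_lw mapping proposal P onto truth G."""
    if P.l_w <= 0 or G.l_w <= 0:
        raise ValueError("regression targets require positive box widths")
    return RegressionTarget(
        t_lh=(G.l_h - P.l_h) / P.l_w,
        t_lw=float(np.log(G.l_w / P.l_w)),
    )


def apply_regression(P: Box3D, d_lh: float, d_lw: float) -> Box3D:
    """Transform proposal P by predicted offsets into a refined box (clipped)."""
    if P.l_w <= 0:
        raise ValueError("proposal width must be positive")
    return clip_box(
        Box3D(
            l_h=P.l_w * d_lh + P.l_h,
            l_w=P.l_w * float(np.exp(d_lw)),
            footprint=P.footprint,
        )
    )


def _design(F: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    Z = (F - mean) / std
    return np.column_stack([Z, np.ones(len(Z))])


def fit_regressor(
    features: np.ndarray,
    targets: list[RegressionTarget] | np.ndarray,
    lam: float = 1.0,
    class_label: str = "object",
) -> BoxRegressor:
    """Closed-form ridge fit of the two offset models.

    Solves (X'X + lam*D) w = X'y per target dimension, with X the
    standardized features plus an appended intercept column and D the
    identity zeroed at the intercept position (the intercept is not
    penalized).  Deterministic; raises on a singular system when lam = 0.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or len(F) < 1:
        raise ValueError("features must be a non-empty 2D matrix")
    if isinstance(targets, np.ndarray):
        T = np.asarray(targets, dtype=float)
    else:
        T = np.array([[t.t_lh, t.t_lw] for t in targets], dtype=float)
    if T.shape != (len(F), 2):
        raise ValueError("need one (t_lh, t_lw) target per feature row")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    mean = F.mean(axis=0)
    std = F.std(axis=0)
    std[std < 1e-12] = 1.0
    X = _design(F, mean, std)
    d = X.shape[1]
    pen = lam * np.eye(d)
    pen[-1, -1] = 0.0
    A = X.T @ X + pen
    B = X.T @ T
    try:
        W = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal equations are singular; use a ridge penalty lam > 0"
        ) from exc
    if lam == 0.0 and np.linalg.matrix_rank(A) < d:
        raise np.linalg.LinAlgError(
            "normal equations are singular; use a ridge penalty lam > 0"
        )
    return BoxRegressor(
        class_label=class_label,
        w_lh=W[:, 0],
        w_lw=W[:, 1],
        feature_mean=mean,
        feature_std=std,
        lam=lam,
    )


def fit_regressor_gd(
    features: np.ndarray,
    targets: list[RegressionTarget] | np.ndarray,
    lam: float = 1.0,
    class_label: str = "object",
    lr: float = 1e-4,
    epochs: int = 200,
    seed: int = 0,
) -> BoxRegressor:
    """Iterative (SGD) fit of the same ridge objective; cross-check path.

    Mirrors the closed-form objective with full-batch gradient steps at a
    small learning rate; primarily useful to validate :func:`fit_regressor`.
    """
    F = np.asarray(features, dtype=float)
    if isinstance(targets, np.ndarray):
        T = np.asarray(targets, dtype=float)
    else:
        T = np.array([[t.t_lh, t.t_lw] for t in targets], dtype=float)
    mean = F.mean(axis=0)
    std = F.std(axis=0)
    std[std < 1e-12] = 1.0
    X = _design(F, mean, std)
    d = X.shape[1]
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((d, 2)) * 0.01
    mask = np.ones((d, 1))
    mask[-1] = 0.0
    for _ in range(epochs):
        resid = X @ W - T
        grad = 2.0 * X.T @ resid + 2.0 * lam * W * mask
        W -= lr * grad
    return BoxRegressor(
        class_label=class_label,
        w_lh=W[:, 0],
        w_lw=W[:, 1],
        feature_mean=mean,
        feature_std=std,
        lam=lam,
    )


def predict_offsets(regressor: BoxRegressor, f_mp: np.ndarray) -> tuple[float, float]:
    """Predicted offsets d_* = T_* . [standardized f_mp, 1]."""
    f = np.asarray(f_mp, dtype=float)
    if f.shape != (regressor.feature_dim,):
        raise ValueError(
            f"feature length {f.shape} does not match regressor dim {regressor.feature_dim}"
        )
    x = np.append((f - regressor.feature_mean) / regressor.feature_std, 1.0)
    return float(regressor.w_lh @ x), float(regressor.w_lw @ x)


def refine_box(
    model: PointSetClassifier,
    regressor: BoxRegressor,
    cloud: PixelCloud,
    proposal: ScoredBox3D,
    n_max: int = 256,
    seed: int = 0,
) -> Box3D:
    """Refine one proposal box using its global feature and class regressor.

    The points inside the proposal are sampled and normalized exactly as in
    the classification stage; the resulting f_mp feeds the linear offset
    models and the offsets are applied and clipped.  An empty proposal box is
    returned unchanged (clipped) with a warning.
    """
    P = proposal.box
    inside = points_in_box(cloud, P)
    if len(inside) == 0:
        warnings.warn("refine_box: empty proposal box, returning proposal unchanged")
        return clip_box(P)
    pts = sample_points(inside.points, n_max, np.random.default_rng(seed))
    f = model.global_features(normalize_points(pts, P))
    d_lh, d_lw = predict_offsets(regressor, f)
    return apply_regression(P, d_lh, d_lw)


@dataclass
class RegressionDataset:
    """Training pairs for box refinement.

    ``X`` holds the normalized point sets of the proposal boxes
    ((M, n_max, 3), same construction as for classification), ``proposals``
    and ``truths`` the corresponding boxes, ``labels`` their class names.
    """

    X: np.ndarray
    proposals: list[Box3D]
    truths: list[Box3D]
    labels: list[str]

    def __len__(self) -> int:
        return int(self.X.shape[0])


def train_regressor(
    model: PointSetClassifier,
    dataset: RegressionDataset,
    lam: float = 1.0,
    class_names: tuple[str, ...] | None = None,
) -> dict[str, BoxRegressor]:
    """Fit one ridge regressor per candidate class from proposal/truth pairs.

    Global features are computed with the trained classifier; targets with
    :func:`regression_targets`.  A class with no training pairs receives an
    identity (zero-weight) regressor.  Deterministic.
    """
    if len(dataset) < 1:
        raise ConfigError("regression training requires at least one pair")
    _, feats, _ = model.forward(np.ascontiguousarray(dataset.X, dtype=np.float32))
    targets = np.array(
        [
            [
                regression_targets(P, G).t_lh,
                regression_targets(P, G).t_lw,
            ]
            for P, G in zip(dataset.proposals, dataset.truths)
        ]
    )
    labels = np.asarray(dataset.labels)
    wanted = class_names if class_names is not None else tuple(sorted(set(dataset.labels)))
    out: dict[str, BoxRegressor] = {}
    for label in wanted:
        if label == "background":
            continue
        sel = labels == label
        if not sel.any():
            out[label] = BoxRegressor.identity(label, model.feature_dim, lam)
            continue
        out[label] = fit_regressor(feats[sel], targets[sel], lam=lam, class_label=label)
    return out
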