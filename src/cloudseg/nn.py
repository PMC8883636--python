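"""A small point-set classification network in plain numpy.

Architecture (PointNet-style): each point of a fixed-size normalized point set
is passed through a shared multi-layer perceptron; a max-pool over points
aggregates the per-point features into a single order-invariant global feature
vector ``f_mp``; fully connected layers map ``f_mp`` to class probabilities.

The max-pool makes both the class scores and the global feature exactly
invariant to any permutation of the input points, and the global feature is
elementwise monotone under adding points.  ``f_mp`` doubles as the feature
vector consumed by the linear box-refinement stage.

An optional input-alignment hook (a learnable 3x3 transform applied to the raw
points, identity-initialized) stands in for the heavier alignment mini-networks
used by full PointNet; it is off by default because the points are already
canonicalized into [-1, 1]^3 before they reach the network.

Training (Adam on cross-entropy, manual backprop) lives in
:mod:`cloudseg.proposals`; this module holds the model, its forward/backward
passes and checkpoint I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ConfigError

__all__ = ["PointSetClassifier"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class PointSetClassifier:
    """Shared per-point MLP + max-pool + fully connected classification head.

    Parameters are float32 numpy arrays in ``params``:
    ``pp_W{i}/pp_b{i}`` for the per-point layers, ``hd_W{i}/hd_b{i}`` for the
    head (the last head layer outputs one logit per class) and, when
    ``use_input_tnet`` is set, a 3x3 alignment matrix ``tnet_A``.
    """

    n_classes: int
    class_names: tuple[str, ...]
    per_point_layer_sizes: tuple[int, ...] = (64, 128, 256)
    head_layer_sizes: tuple[int, ...] = (128,)
    use_input_tnet: bool = False
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        self.per_point_layer_sizes = tuple(int(s) for s in self.per_point_layer_sizes)
        self.head_layer_sizes = tuple(int(s) for s in self.head_layer_sizes)
        if len(self.class_names) != self.n_classes:
            raise ConfigError("class_names length must equal n_classes")
        if min(self.per_point_layer_sizes) < 1 or self.n_classes < 2:
            raise ConfigError("invalid layer sizes or class count")

    @property
    def feature_dim(self) -> int:
        """Length of the global feature f_mp (last per-point width)."""
        return self.per_point_layer_sizes[-1]

    # ------------------------------------------------------------------ init
    def init_params(self, rng: np.random.Generator) -> None:
        """He-initialize all weights (deterministic for a given generator)."""
        p: dict[str, np.ndarray] = {}
        sizes = (3,) + self.per_point_layer_sizes
        for i in range(len(sizes) - 1):
            fan_in = sizes[i]
            p[f"pp_W{i}"] = (
                rng.standard_normal((sizes[i], sizes[i + 1])) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            p[f"pp_b{i}"] = np.zeros(sizes[i + 1], dtype=np.float32)
        hsizes = (self.feature_dim,) + self.head_layer_sizes + (self.n_classes,)
        for i in range(len(hsizes) - 1):
            p[f"hd_W{i}"] = (
                rng.standard_normal((hsizes[i], hsizes[i + 1])) * np.sqrt(2.0 / hsizes[i])
            ).astype(np.float32)
            p[f"hd_b{i}"] = np.zeros(hsizes[i + 1], dtype=np.float32)
        if self.use_input_tnet:
            p["tnet_A"] = np.eye(3, dtype=np.float32)
        self.params = p

    # --------------------------------------------------------------- forward
    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        """Forward pass on a batch of point sets.

        Parameters
        ----------
        X : (B, N, 3) array of normalized points.

        Returns
        -------
        probs : (B, n_classes) class probabilities (rows sum to 1).
        f_mp : (B, feature_dim) max-pooled global features.
        cache : intermediates needed for the backward pass.
        """
        if not self.params:
            raise ConfigError("model parameters not initialized")
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError(f"expected (B, N, 3) points, got {X.shape}")
        B, N, _ = X.shape
        cache: dict = {"X": X}
        H = X.reshape(B * N, 3)
        if self.use_input_tnet:
            H = H @ self.params["tnet_A"]
            cache["aligned"] = H
        pp_acts = []
        for i in range(len(self.per_point_layer_sizes)):
            H = H @ self.params[f"pp_W{i}"]
            H += self.params[f"pp_b{i}"]
            np.maximum(H, 0.0, out=H)
            pp_acts.append(H)
        cache["pp_acts"] = pp_acts
        per_point = H.reshape(B, N, self.feature_dim)
        argmax = per_point.argmax(axis=1)  # (B, D) winning point per feature
        f_mp = np.take_along_axis(per_point, argmax[:, None, :], axis=1)[:, 0, :]
        cache["argmax"] = argmax
        cache["N"] = N
        hd_acts = [f_mp]
        G = f_mp
        n_head = len(self.head_layer_sizes) + 1
        for i in range(n_head):
            G = G @ self.params[f"hd_W{i}"] + self.params[f"hd_b{i}"]
            if i < n_head - 1:
                G = _relu(G)
            hd_acts.append(G)
        cache["hd_acts"] = hd_acts
        probs = _softmax(G.astype(np.float64))
        cache["probs"] = probs
        return probs, f_mp.astype(np.float64), cache

    def backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy wrt all parameters.

        ``y`` holds integer class labels, one per point set in the batch.
        """
        B = cache["probs"].shape[0]
        N = cache["N"]
        D = self.feature_dim
        grads: dict[str, np.ndarray] = {}
        dG = cache["probs"].copy()
        dG[np.arange(B), y] -= 1.0
        dG = (dG / B).astype(np.float32)
        n_head = len(self.head_layer_sizes) + 1
        for i in range(n_head - 1, -1, -1):
            inp = cache["hd_acts"][i]
            grads[f"hd_W{i}"] = inp.T @ dG
            grads[f"hd_b{i}"] = dG.sum(axis=0)
            dG = dG @ self.params[f"hd_W{i}"].T
            if i > 0:
                dG *= cache["hd_acts"][i] > 0
        # route the pooled gradient back to each feature's winning point
        dper = np.zeros((B, N, D), dtype=np.float32)
        np.put_along_axis(dper, cache["argmax"][:, None, :], dG[:, None, :], axis=1)
        dH = dper.reshape(B * N, D)
        n_pp = len(self.per_point_layer_sizes)
        for i in range(n_pp - 1, -1, -1):
            np.multiply(dH, cache["pp_acts"][i] > 0, out=dH)
            if i > 0:
                inp = cache["pp_acts"][i - 1]
            elif self.use_input_tnet:
                inp = cache["aligned"]
            else:
                inp = cache["X"].reshape(B * N, 3)
            grads[f"pp_W{i}"] = inp.T @ dH
            grads[f"pp_b{i}"] = dH.sum(axis=0)
            dH = dH @ self.params[f"pp_W{i}"].T
        if self.use_input_tnet:
            grads["tnet_A"] = cache["X"].reshape(B * N, 3).T @ dH
        return grads

    # ------------------------------------------------------------- inference
    def classify(self, points: np.ndarray) -> np.ndarray:
        """Class probabilities for a single (N, 3) normalized point set."""
        probs, _, _ = self.forward(np.asarray(points)[None, :, :])
        return probs[0]

    def global_features(self, points: np.ndarray) -> np.ndarray:
        """Global feature f_mp for a single (N, 3) normalized point set."""
        _, f, _ = self.forward(np.asarray(points)[None, :, :])
        return f[0]

    # ------------------------------------------------------------ checkpoint
    def save(self, path: str | Path) -> None:
        """Write an .npz container: flat parameter arrays plus JSON metadata
        (layer sizes, class names, flags) under the key ``meta``."""
        meta = json.dumps(
            {
                "n_classes": self.n_classes,
                "class_names": list(self.class_names),
                "per_point_layer_sizes": list(self.per_point_layer_sizes),
                "head_layer_sizes": list(self.head_layer_sizes),
                "use_input_tnet": self.use_input_tnet,
            }
        )
        np.savez(path, meta=np.array(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "PointSetClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = {k: data[k] for k in data.files if k != "meta"}
        model = cls(
            n_classes=meta["n_classes"],
            class_names=tuple(meta["class_names"]),
            per_point_layer_sizes=tuple(meta["per_point_layer_sizes"]),
            head_layer_sizes=tuple(meta["head_layer_sizes"]),
            use_input_tnet=meta["use_input_tnet"],
            params=params,
        )
        return model
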