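"""Feed-forward regression networks implemented on numpy.

Two estimators share one training core (mini-batch Adam on a squared
-error loss, ReLU hidden units, optional inverted dropout):

* :class:`DeepNetRegressor` — a plain multilayer perceptron whose depth,
  width, dropout, epochs and learning rate are hyperparameters.
* :class:`ForkedNetRegressor` — a multi-branch network with a separate
  input branch per feature block. Each branch is an affine map from its
  block's columns to a per-branch width followed by ReLU; branch outputs
  are concatenated and fed to a trunk of ``depth`` layers whose widths
  halve geometrically (floor 16) down to a single linear output. The
  branch layer is realized as one block-diagonal weight matrix with a
  structural mask, so the whole model trains with ordinary dense
  backpropagation while keeping cross-block first-layer weights at
  exactly zero.

Both are sklearn estimators (get_params/set_params, fit/predict) and are
run-to-run reproducible on CPU for a fixed ``random_state`` (all
randomness — init, batch shuffling, dropout — flows from one generator).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DeepNetRegressor",
    "ForkedNetRegressor",
    "forked_trunk_widths",
    "forked_parameter_count",
    "DEFAULT_BRANCH_SIZES",
]

#: Default per-branch widths for the seven feature-block branches.
DEFAULT_BRANCH_SIZES = {
    "experimental": 39,
    "cargo": 239,
    "anomaly_type": 79,
    "whole_peptide": 155,
    "sequence": 850,
    "genomics": 687,
    "anomaly_position": 45,
}

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _MLPCore:
    """Dense MLP with optional structural mask on the first weight matrix."""

    def __init__(
        self,
        dims: Sequence[int],
        rng: np.random.Generator,
        first_layer_mask: Optional[np.ndarray] = None,
        zero_init: bool = False,
    ):
        self.dims = list(dims)
        self.mask0 = first_layer_mask
        self.W, self.b = [], []
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            if zero_init:
                W = np.zeros((dims[i], dims[i + 1]))
            else:
                W = rng.standard_normal((dims[i], dims[i + 1])) * math.sqrt(
                    2.0 / max(fan_in, 1)
                )
            if i == 0 and self.mask0 is not None:
                W = W * self.mask0
            self.W.append(W)
            self.b.append(np.zeros(dims[i + 1]))
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(bb) for bb in self.b]
        self._vb = [np.zeros_like(bb) for bb in self.b]
        self._t = 0

    def n_parameters(self) -> int:
        total = 0
        for i, (W, bb) in enumerate(zip(self.W, self.b)):
            if i == 0 and self.mask0 is not None:
                total += int(self.mask0.sum())
            else:
                total += W.size
            total += bb.size
        return total

    def forward(
        self,
        X: np.ndarray,
        dropout_rate: float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ):
        """Returns (prediction, cache). Dropout applied iff rate>0 and rng."""
        a = X
        caches = []
        n_layers = len(self.W)
        for i in range(n_layers):
            z = a @ self.W[i] + self.b[i]
            if i < n_layers - 1:
                h = _relu(z)
                if dropout_rate > 0.0 and rng is not None:
                    keep = 1.0 - dropout_rate
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                else:
                    mask = None
                caches.append((a, z, mask))
                a = h
            else:
                caches.append((a, z, None))
                a = z
        return a[:, 0], caches

    def backward(self, caches, grad_out: np.ndarray):
        """Gradient of the loss w.r.t. all weights given d loss/d output."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = grad_out[:, None]  # (m, 1)
        for i in reversed(range(len(self.W))):
            a_in, z, mask = caches[i]
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                prev_z, prev_mask = caches[i - 1][1], caches[i - 1][2]
                if prev_mask is not None:
                    delta = delta * prev_mask
                delta = delta * (prev_z > 0)
        if self.mask0 is not None:
            gW[0] = gW[0] * self.mask0
        return gW, gb

    def adam_step(self, gW, gb, lr: float, weight_decay: float = 0.0) -> None:
        """One Adam update; ``weight_decay`` is decoupled (AdamW-style),
        applied to weight matrices only, never to biases."""
        self._t += 1
        t = self._t
        for i in range(len(self.W)):
            for p, g, m, v in (
                (self.W[i], gW[i], self._mW[i], self._vW[i]),
                (self.b[i], gb[i], self._mb[i], self._vb[i]),
            ):
                m *= _ADAM_B1
                m += (1 - _ADAM_B1) * g
                v *= _ADAM_B2
                v += (1 - _ADAM_B2) * g * g
                mhat = m / (1 - _ADAM_B1**t)
                vhat = v / (1 - _ADAM_B2**t)
                p -= lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)
            if weight_decay:
                self.W[i] *= 1.0 - lr * weight_decay
            if i == 0 and self.mask0 is not None:
                self.W[0] *= self.mask0


class _BaseNet(RegressorMixin, BaseEstimator):
    """Shared fit loop; subclasses define the architecture."""

    def _build_core(self, n_features: int, rng) -> _MLPCore:
        raise NotImplementedError

    def _dropout_rate(self) -> float:
        return self.dropout_rate if self.use_dropout else 0.0

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        rng = np.random.default_rng(self.random_state)
        self._core = self._build_core(X.shape[1], rng)
        self.n_features_in_ = X.shape[1]
        self.n_parameters_ = self._core.n_parameters()
        self._y_offset = float(y.mean())
        yc = y - self._y_offset
        n = len(y)
        bs = min(self.batch_size, n)
        drop = self._dropout_rate()
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                xb, yb = X[idx], yc[idx]
                pred, caches = self._core.forward(xb, drop, rng)
                err = pred - yb
                epoch_loss += float(err @ err)
                seen += len(idx)
                gW, gb = self._core.backward(caches, 2.0 * err / len(idx))
                self._core.adam_step(
                    gW, gb, self.learning_rate,
                    getattr(self, "weight_decay", 0.0),
                )
            self.loss_curve_.append(epoch_loss / seen)
        self.is_fitted_ = True
        return self

    def predict(self, X):
        check_is_fitted(self, "is_fitted_")
        X = np.asarray(X, dtype=float)
        pred, _ = self._core.forward(X)
        return pred + self._y_offset


class DeepNetRegressor(_BaseNet):
    """Fully connected MLP: ``depth`` hidden layers of ``layer_size`` units.

    Parameters mirror the tunable quantities of the model family:
    depth (1–10), layer size, dropout (rate + enable flag), epochs and
    learning rate; squared-error loss, Adam, batch size 32.
    """

    def __init__(
        self,
        depth: int = 1,
        layer_size: int = 500,
        use_dropout: bool = True,
        dropout_rate: float = 0.3,
        epochs: int = 230,
        learning_rate: float = 0.0005,
        batch_size: int = 32,
        weight_decay: float = 0.0,
        random_state: Optional[int] = None,
    ):
        self.depth = depth
        self.layer_size = layer_size
        self.use_dropout = use_dropout
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.random_state = random_state

    def _build_core(self, n_features: int, rng) -> _MLPCore:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        dims = [n_features] + [self.layer_size] * self.depth + [1]
        return _MLPCore(dims, rng)


def forked_trunk_widths(
    concat_width: int, depth: int, floor: int = 16
) -> list[int]:
    """Geometric-halving trunk widths from the concatenated branch width."""
    widths, w = [], concat_width
    for _ in range(depth):
        w = max(w // 2, floor)
        widths.append(w)
    return widths


def forked_parameter_count(
    block_dims: Sequence[int],
    branch_widths: Sequence[int],
    depth: int,
    floor: int = 16,
) -> int:
    """Closed-form trainable-parameter count of the forked architecture."""
    total = sum((d + 1) * w for d, w in zip(block_dims, branch_widths))
    prev = sum(branch_widths)
    for w in forked_trunk_widths(prev, depth, floor):
        total += (prev + 1) * w
        prev = w
    return total + (prev + 1) * 1


class ForkedNetRegressor(_BaseNet):
    """Multi-branch network with one input branch per feature block.

    Parameters
    ----------
    blocks : list of (name, column indices)
        Routing of feature columns to branches. With the full schema this
        is the seven-branch grouping from
        :func:`cppuptake.pipeline.branch_block_indices`.
    branch_sizes : dict, optional
        Branch name -> width. Missing names fall back to
        ``DEFAULT_BRANCH_SIZES`` and then to ``default_branch_size``.
    depth : int
        Number of trunk layers (geometric halving, floor 16).
    """

    def __init__(
        self,
        blocks=None,
        branch_sizes: Optional[dict] = None,
        default_branch_size: int = 32,
        depth: int = 7,
        use_dropout: bool = False,
        dropout_rate: float = 0.9,
        epochs: int = 170,
        learning_rate: float = 0.0001,
        batch_size: int = 32,
        weight_decay: float = 0.0,
        trunk_floor: int = 16,
        weight_init: str = "he",
        random_state: Optional[int] = None,
    ):
        self.blocks = blocks
        self.branch_sizes = branch_sizes
        self.default_branch_size = default_branch_size
        self.depth = depth
        self.use_dropout = use_dropout
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.trunk_floor = trunk_floor
        self.weight_init = weight_init
        self.random_state = random_state

    # -- architecture ---------------------------------------------------
    def _resolved_blocks(self) -> list[tuple[str, np.ndarray]]:
        if not self.blocks:
            raise ValueError(
                "ForkedNetRegressor requires `blocks`: a list of "
                "(name, column indices) pairs"
            )
        out = []
        for name, idx in self.blocks:
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValueError(f"branch {name!r} has no columns")
            out.append((name, idx))
        return out

    def _branch_width(self, name: str) -> int:
        sizes = dict(DEFAULT_BRANCH_SIZES)
        if self.branch_sizes:
            sizes.update(self.branch_sizes)
        w = int(sizes.get(name, self.default_branch_size))
        if w < 1:
            raise ValueError(f"branch {name!r} width must be positive")
        return w

    def _build_core(self, n_features: int, rng) -> _MLPCore:
        blocks = self._resolved_blocks()
        for name, idx in blocks:
            if idx.min() < 0 or idx.max() >= n_features:
                raise ValueError(
                    f"branch {name!r} routes column {int(idx.max())} but the "
                    f"input has only {n_features} features"
                )
        widths = [self._branch_width(name) for name, _ in blocks]
        concat = sum(widths)
        mask = np.zeros((n_features, concat))
        start = 0
        for (name, idx), w in zip(blocks, widths):
            mask[idx, start : start + w] = 1.0
            start += w
        dims = (
            [n_features]
            + [concat]
            + forked_trunk_widths(concat, self.depth, self.trunk_floor)
            + [1]
        )
        self.branch_widths_ = dict(zip((n for n, _ in blocks), widths))
        self.n_branches_ = len(blocks)
        return _MLPCore(
            dims,
            rng,
            first_layer_mask=mask,
            zero_init=(self.weight_init == "zeros"),
        )

    # -- analytic access ------------------------------------------------
    def initialize(self, n_features: int) -> "ForkedNetRegressor":
        """Build weights without training (for structural/analytic checks)."""
        rng = np.random.default_rng(self.random_state)
        self._core = self._build_core(n_features, rng)
        self.n_features_in_ = n_features
        self.n_parameters_ = self._core.n_parameters()
        self._y_offset = 0.0
        self.is_fitted_ = True
        return self

    def output_bias(self) -> float:
        check_is_fitted(self, "is_fitted_")
        return float(self._core.b[-1][0])
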