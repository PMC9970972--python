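"""Slice-level 2D CNN classifier.

Architecture: three convolutional modules (3x3 convolution stride 1 with
same padding, batch normalization, ReLU, 2x2/stride-2 max pooling) with 8,
16 and 32 filters, followed by a classification head of two fully
connected layers (hidden width 64, output width = number of classes) and a
softmax. Trained with stochastic gradient descent with momentum
(learning rate 0.01, momentum 0.9, L2 penalty 1e-4, minibatch 128, data
reshuffled every epoch, no early stopping); inputs are zero-centered by
the training-set mean image, recomputed at every fit.

The third module's post-ReLU activations ("ReLU-3") are the feature-
visualization layer: their channel-wise sum, bilinearly upsampled to the
slice grid and min-max normalized per datum, is the slice's activation
map.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._layers import (
    BatchNorm,
    Conv3x3,
    Dense,
    Flatten,
    MaxPool2,
    Network,
    ReLU,
    softmax,
)

__all__ = ["SliceCNNClassifier"]


class SliceCNNClassifier(ClassifierMixin, BaseEstimator):
    """2D CNN for labeled axial gray-matter slices.

    Parameters
    ----------
    conv_filters : tuple of 3 ints
        Filters per convolutional module. The third stays 32 (the
        feature-visualization layer has 32 channels).
    hidden_units : int
        Width of the hidden fully connected layer.
    learning_rate, momentum, l2, batch_size, epochs
        SGDM training configuration.
    validation_frequency : int
        Log validation accuracy every this many iterations.
    random_state : int
        Seeds initialization and epoch shuffling.

    Attributes
    ----------
    classes_ : sorted class labels; argmax ties break toward the lowest
        class index.
    input_mean_ : training-set mean image subtracted from every input.
    history_ : dict with per-iteration training loss and periodic
        validation accuracy.
    """

    def __init__(
        self,
        conv_filters=(8, 16, 32),
        hidden_units=64,
        learning_rate=0.01,
        momentum=0.9,
        l2=1e-4,
        batch_size=128,
        epochs=30,
        validation_frequency=50,
        random_state=0,
    ):
        self.conv_filters = conv_filters
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.l2 = l2
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_frequency = validation_frequency
        self.random_state = random_state

    # index of the third module's ReLU in the layer stack
    _RELU3_INDEX = 10

    def _build(self, input_shape, n_classes, rng):
        h, w = input_shape
        if h < 8 or w < 8:
            raise ValueError(
                f"input {h}x{w} too small: three 2x2 poolings need >= 8 "
                "pixels per axis"
            )
        f1, f2, f3 = self.conv_filters
        layers = []
        c_in = 1
        for f in (f1, f2, f3):
            layers += [Conv3x3(c_in, f, rng), BatchNorm(f), ReLU(), MaxPool2()]
            c_in = f
        h3, w3 = h // 2 // 2 // 2, w // 2 // 2 // 2
        layers += [
            Flatten(),
            Dense(f3 * h3 * w3, self.hidden_units, rng),
            ReLU(),
            Dense(self.hidden_units, n_classes, rng),
        ]
        return Network(layers)

    # ------------------------------------------------------------------
    def _as_images(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2 and hasattr(self, "input_shape_"):
            X = X.reshape(-1, *self.input_shape_)
        if X.ndim != 3:
            raise ValueError("X must be (n_slices, H, W)")
        return X

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must be (n_slices, H, W)")
        if len(X) == 0:
            raise ValueError("empty training set")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        self.input_shape_ = X.shape[1:]

        ss = np.random.SeedSequence(self.random_state)
        init_seed, shuffle_seed = ss.spawn(2)
        init_rng = np.random.default_rng(init_seed)
        shuffle_rng = np.random.default_rng(shuffle_seed)

        self.net_ = self._build(self.input_shape_, n_classes, init_rng)
        self.input_mean_ = X.mean(axis=0)

        Xc = (X - self.input_mean_)[:, None, :, :]
        eye = np.eye(n_classes, dtype=np.float32)
        Y = eye[y_idx]

        if validation_data is not None:
            Xv, yv = validation_data
            Xv = self._as_images(Xv)
            yv = np.asarray(yv)

        history = {"loss": [], "val_iteration": [], "val_accuracy": []}
        n = len(Xc)
        it = 0
        for _epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                loss = self.net_.loss_and_backward(Xc[idx], Y[idx])
                self.net_.sgdm_step(self.learning_rate, self.momentum, self.l2)
                history["loss"].append(loss)
                it += 1
                if validation_data is not None and it % self.validation_frequency == 0:
                    acc = float(np.mean(self.predict(Xv) == yv))
                    history["val_iteration"].append(it)
                    history["val_accuracy"].append(acc)
        self.history_ = history
        return self

    # ------------------------------------------------------------------
    def _forward_eval(self, X, upto=None, batch=256):
        X = self._as_images(X)
        Xc = (X - self.input_mean_)[:, None, :, :]
        outs = []
        for start in range(0, len(Xc), batch):
            outs.append(
                self.net_.forward(Xc[start:start + batch], training=False, upto=upto)
            )
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return softmax(self._forward_eval(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def relu3_sum(self, X):
        """Channel-wise sum of the ReLU-3 feature maps, bilinearly
        upsampled to the slice grid and min-max normalized per datum
        (constant maps normalize to all zeros)."""
        check_is_fitted(self, "net_")
        act = self._forward_eval(X, upto=self._RELU3_INDEX)  # (n, 32, h3, w3)
        summed = act.sum(axis=1)
        h, w = self.input_shape_
        n, h3, w3 = summed.shape
        out = np.empty((n, h, w), dtype=np.float64)
        for i in range(n):
            up = ndimage.zoom(
                summed[i].astype(np.float64),
                (h / h3, w / w3),
                order=1,
                mode="nearest",
                grid_mode=True,
            )
            lo, hi = up.min(), up.max()
            out[i] = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
        return out
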