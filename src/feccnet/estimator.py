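"""scikit-learn style estimator facade over the network and training loop."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .architecture import FECCNet, NetworkConfig
from .data_io import SliceRecord, SplitConfig, split_dataset
from .errors import InputError
from .harness import TrainConfig, train
from .metrics import dsc, stratify_by_lesion_size


class FECCNetSegmenter(BaseEstimator):
    """Binary lesion segmenter with a fit/predict interface.

    X is an array of grayscale slices on the [0, 255] scale, shape
    (n_slices, H, W) with H = W = ``image_size``; y holds the matching
    {0, 1} masks. ``fit`` holds out ``validation_fraction`` of the slices
    for early stopping on validation DSC.

    Parameters mirror the network/training configuration; after ``fit`` the
    trained network is available as ``net_`` and the loss/validation curves
    as ``history_``.
    """

    def __init__(self, image_size=64, depth=4, channel_schedule=(8, 16, 32, 64),
                 aspp_rates=(1, 6, 12, 18), aspp_channels=32,
                 enhanced_encoder=True, enhanced_schedule=(8, 16, 32, 64),
                 enhanced_stack=1, threshold=0.5, loss="hybrid",
                 learning_rate=1e-3, batch_size=16, max_epochs=30,
                 early_stop_patience=20, validation_fraction=0.1,
                 augment=False, random_state=0):
        self.image_size = image_size
        self.depth = depth
        self.channel_schedule = channel_schedule
        self.aspp_rates = aspp_rates
        self.aspp_channels = aspp_channels
        self.enhanced_encoder = enhanced_encoder
        self.enhanced_schedule = enhanced_schedule
        self.enhanced_stack = enhanced_stack
        self.threshold = threshold
        self.loss = loss
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.augment = augment
        self.random_state = random_state

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            input_size=self.image_size,
            depth=self.depth,
            channel_schedule=tuple(self.channel_schedule),
            aspp_rates=tuple(self.aspp_rates),
            aspp_channels=self.aspp_channels,
            enhanced_encoder=self.enhanced_encoder,
            enhanced_schedule=tuple(self.enhanced_schedule),
            enhanced_stack=self.enhanced_stack,
            threshold=self.threshold,
        )

    def _as_records(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1:] != (self.image_size, self.image_size):
            raise InputError(
                f"X must be (n, {self.image_size}, {self.image_size}); got {X.shape}"
            )
        if y.shape != X.shape:
            raise InputError("y must match X's shape")
        return [
            SliceRecord(image=X[i], mask=(y[i] > 0.5).astype(np.uint8),
                        case_id=f"s{i:05d}", slice_index=i,
                        stratum=stratify_by_lesion_size(y[i]))
            for i in range(len(X))
        ]

    def fit(self, X, y):
        records = self._as_records(X, y)
        if len(records) >= 5 and self.validation_fraction > 0:
            frac = self.validation_fraction
            split = SplitConfig(ratios=(1 - 2 * frac, frac, frac),
                                seed=self.random_state, unit="slice")
            train_recs, val_recs, extra = split_dataset(records, split)
            train_recs = train_recs + extra  # only one held-out part is needed
        else:
            train_recs, val_recs = records, []
        cfg = TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, early_stop_patience=self.early_stop_patience,
            loss=self.loss, seed=self.random_state, image_size=self.image_size,
            variant="full" if self.enhanced_encoder else "lite",
            augment=self.augment,
        )
        self.net_, result = train(cfg, self._network_config(), train_recs, val_recs)
        self.history_ = {"train_loss": result.train_loss, "val_dsc": result.val_dsc,
                         "best_epoch": result.best_epoch}
        self.n_parameters_ = self.net_.total_parameters
        return self

    def predict_proba(self, X):
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        self._check_fitted()
        return self.net_.predict_proba(np.asarray(X, dtype=np.float64))

    def predict(self, X):
        """Binary masks thresholded at ``threshold``, shape (n, H, W)."""
        return (self.predict_proba(X) > self.threshold).astype(np.uint8)

    def score(self, X, y):
        """Mean per-slice DSC (empty/empty pairs score 1)."""
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([dsc(y[i], pred[i]) for i in range(len(y))]))

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise InputError("this FECCNetSegmenter instance is not fitted yet")
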