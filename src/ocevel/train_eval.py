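"""Training recipe, evaluation metrics and gradient-based saliency.

Training minimises mean absolute error with Adam (MAE; squared error
makes optimisation of this regression unstable), with early stopping on
validation MAE and best-weights restoration.  Evaluation reports
per-slice squared and absolute errors grouped by material/site, in the
mean +/- std convention.  Grad-CAM is adapted to scalar regression: the
differentiated quantity is the predicted velocity itself rather than a
class score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Adam, mae_loss
from .vpnet import VPNet

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "EvalReport",
    "evaluate",
    "GradCamMap",
    "grad_cam",
]


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters for VP-Net velocity regression."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 1000
    patience: int = 30
    loss: str = "mae"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "mae":
            raise ValueError("only the MAE loss is supported (MSE trains unstably)")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainHistory:
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mae: float = float("inf")
    stopped_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_mae)),
                "train_mae": self.train_mae,
                "val_mae": self.val_mae,
            }
        )


def _check_disjoint(*id_sets: set[str]) -> None:
    for i in range(len(id_sets)):
        for j in range(i + 1, len(id_sets)):
            overlap = id_sets[i] & id_sets[j]
            if overlap:
                raise ValueError(
                    f"acquisition ids shared between splits (data leakage): {sorted(overlap)[:5]}"
                )


def train(
    net: VPNet,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
    train_ids: set[str] | None = None,
    val_ids: set[str] | None = None,
    verbose: bool = False,
) -> TrainHistory:
    """Fit the network in place; returns the per-epoch history.

    Early stopping: training halts once validation MAE has not improved
    for ``cfg.patience`` consecutive epochs, and the weights of the best
    validation epoch (ties broken toward the earlier epoch) are
    restored.  Reproducible given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if train_ids is not None and val_ids is not None:
        _check_disjoint(set(train_ids), set(val_ids))

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.model, lr=cfg.learning_rate)
    history = TrainHistory()
    best_state = net.model.copy_state()
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = net.forward(x_tr[idx], training=True)
            loss, grad = mae_loss(pred, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            net.model.backward(grad[:, None].astype(np.float32))
            opt.step()
            epoch_losses.append(loss)

        val_mae = float(np.abs(net.predict(x_va) - y_va).mean())
        history.train_mae.append(float(np.mean(epoch_losses)))
        history.val_mae.append(val_mae)
        if verbose:
            print(f"epoch {epoch:4d}  train MAE {history.train_mae[-1]:.4f}  val MAE {val_mae:.4f}")

        if val_mae < history.best_val_mae:
            history.best_val_mae = val_mae
            history.best_epoch = epoch
            best_state = net.model.copy_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    history.stopped_epoch = len(history.train_mae) - 1
    net.model.load_state_dict(best_state)
    return history


@dataclass
class EvalReport:
    """Per-slice errors plus grouped mean +/- std summaries."""

    frame: pd.DataFrame  # columns: group, label, prediction, mse, mae

    def group_summary(self) -> pd.DataFrame:
        """mean +/- std of MSE, MAE and predicted velocity per group."""
        g = self.frame.groupby("group")
        out = pd.DataFrame(
            {
                "mse_mean": g["mse"].mean(),
                "mse_std": g["mse"].std(ddof=0),
                "mae_mean": g["mae"].mean(),
                "mae_std": g["mae"].std(ddof=0),
                "pred_mean": g["prediction"].mean(),
                "pred_std": g["prediction"].std(ddof=0),
                "n": g.size(),
            }
        )
        return out


def evaluate(
    net: VPNet,
    test_set: tuple[np.ndarray, np.ndarray],
    groups: np.ndarray | list[str] | None = None,
    test_ids: set[str] | None = None,
    seen_ids: set[str] | None = None,
) -> EvalReport:
    """Per-slice squared/absolute error against labels, grouped.

    ``seen_ids`` (train + validation acquisition ids) are checked
    against ``test_ids`` to enforce the no-leakage precondition.
    """
    x, y = test_set
    if len(x) == 0:
        raise ValueError("test set is empty")
    if test_ids is not None and seen_ids is not None:
        _check_disjoint(set(test_ids), set(seen_ids))
    if groups is None:
        groups = ["all"] * len(y)
    groups = np.asarray(groups)
    for gname, count in zip(*np.unique(groups, return_counts=True)):
        if count == 0:  # pragma: no cover - unique() never yields 0
            raise ValueError(f"group {gname} has zero slices")

    pred = net.predict(x)
    err = np.asarray(y, dtype=float) - pred
    frame = pd.DataFrame(
        {
            "group": groups,
            "label": np.asarray(y, dtype=float),
            "prediction": pred,
            "mse": err**2,
            "mae": np.abs(err),
        }
    )
    return EvalReport(frame=frame)


@dataclass
class GradCamMap:
    """Gradient-weighted activation map for one probed layer."""

    heatmap: np.ndarray  # probed layer's spatial resolution, >= 0
    overlay: np.ndarray  # bilinear upsample to the input size, in [0, 1]
    probed_layer: str
    predicted_velocity: float


def grad_cam(net: VPNet, slice_values: np.ndarray, probe: str = "cbr1") -> GradCamMap:
    """Regression Grad-CAM: saliency of the predicted velocity.

    Channel weights are the spatial means of d v_hat / d A over the
    probed activation A; the map is ReLU(sum_k w_k A_k), then bilinearly
    upsampled to the input size and min-max normalised for the overlay.
    """
    layer_name = net.resolve_probe(probe)
    x = np.asarray(slice_values, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, :, :, None]
    elif x.ndim != 4 or x.shape[0] != 1:
        raise ValueError("grad_cam expects a single (H, W) slice")

    out = net.model.forward(x, training=False, record=True)
    net.model.backward(np.ones_like(out), record=True)
    act = net.model.activations[layer_name][0]  # (h, w, c)
    grad = net.model.activation_grads[layer_name][0]

    weights = grad.mean(axis=(0, 1))  # (c,)
    heat = np.maximum((act * weights).sum(axis=-1), 0.0)

    zoom = (x.shape[1] / heat.shape[0], x.shape[2] / heat.shape[1])
    overlay = ndimage.zoom(heat, zoom, order=1, grid_mode=True, mode="nearest")
    span = overlay.max() - overlay.min()
    if span > 0:
        overlay = (overlay - overlay.min()) / span
    else:
        overlay = np.zeros_like(overlay)
    return GradCamMap(
        heatmap=heat,
        overlay=overlay,
        probed_layer=layer_name,
        predicted_velocity=float(max(out[0, 0], 0.0)),
    )
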