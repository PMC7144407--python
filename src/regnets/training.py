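"""Training of the per-alpha networks by SGD with momentum on an MAE loss.

The loss compares the ground-truth coefficients c^(k) with the full
reconstruction R_alpha(y^(k)) = b^(k) + P U_theta(b^(k)), where
b^(k) = B_alpha y^(k) is a fixed input and P is the fixed band projector of
the model's mode.  Only the network parameters are free, so the gradient of
the mean absolute error flows through P alone:
d loss / d U_out = -P sign(c - R(y)) / batch.

Defaults follow the reference protocol: learning rate 0.05, momentum 0.99,
mean absolute error, trained on noise-free data.
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._utils import derive_seed
from .filters import FilterSpec
from .models import RegNetModel
from .phantoms import Dataset, make_dataset
from .spectral import SpectralSystem

__all__ = ["TrainingConfig", "mae_loss", "train_regnet", "train_alpha_family"]


@dataclass
class TrainingConfig:
    learning_rate: float = 0.05
    momentum: float = 0.99
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    alpha: Optional[float] = None
    loss: str = "mae"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def mae_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean over the batch of the entrywise l1 norm of the residual."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: predictions {predictions.shape} vs targets {targets.shape}"
        )
    if predictions.ndim == 2:
        predictions, targets = predictions[None], targets[None]
    bsz = predictions.shape[0]
    return float(np.abs(predictions - targets).reshape(bsz, -1).sum(axis=1).mean())


def _batch_projector(model: RegNetModel, imgs: np.ndarray) -> np.ndarray:
    """Apply the model's (symmetric) band projector to a batch of images."""
    flat = imgs.reshape(imgs.shape[0], -1)
    u = model.system.domain_basis
    if model.mode == "null_space":
        q = u[:, model.system.positive_mask]
        out = flat - (flat @ q) @ q.T
    elif model.mode == "continued_svd" and model.kernel_band == "complement":
        q = u[:, model.retained_mask]
        out = flat - (flat @ q) @ q.T
    elif model.mode == "continued_svd":
        q = u[:, (~model.retained_mask) & model.system.positive_mask]
        out = (flat @ q) @ q.T
    else:
        out = np.zeros_like(flat)
    return out.reshape(imgs.shape)


def train_regnet(
    model: RegNetModel,
    dataset: Dataset,
    config: TrainingConfig,
) -> Tuple[RegNetModel, np.ndarray]:
    """Optimize the model's network through the full reconstruction map.

    Returns the trained model (same object, parameters updated in place) and
    the per-epoch mean training loss.  Fully deterministic given
    ``config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if config.alpha is not None and not np.isclose(config.alpha, model.alpha):
        raise ValueError(
            f"config.alpha={config.alpha} does not match model.alpha={model.alpha}"
        )
    if not np.isclose(dataset.alpha, model.alpha):
        raise ValueError(
            f"dataset was built for alpha={dataset.alpha}, model has alpha={model.alpha}"
        )
    net = model.network
    if net is None or not net.trainable:
        raise ValueError("model has no trainable network")

    params = net.get_params()
    velocity = [np.zeros_like(p) for p in params]
    rng = np.random.default_rng(config.seed)
    n_samples = len(dataset)
    bsz = min(config.batch_size, n_samples)
    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(n_samples)
        epoch_losses = []
        for start in range(0, n_samples, bsz):
            idx = order[start : start + bsz]
            b = dataset.inputs[idx]
            c = dataset.targets[idx]
            u_out, ctx = net.forward_cached(b)
            recon = b + _batch_projector(model, np.asarray(u_out, dtype=float))
            resid = c - recon
            loss = mae_loss(recon, c)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at alpha={model.alpha}"
                )
            epoch_losses.append(loss)
            # gradient of the per-pixel mean absolute error: same minimizer as
            # the summed l1 objective, but keeps update magnitudes independent
            # of image size so the stated learning rate is usable as-is
            grad_out = _batch_projector(model, -np.sign(resid)) / resid.size
            grads = net.backward_cached(grad_out, ctx)
            for p, v, g in zip(params, velocity, grads):
                v *= config.momentum
                v -= (config.learning_rate * g).astype(p.dtype, copy=False)
                p += v
        losses.append(float(np.mean(epoch_losses)))
    return model, np.asarray(losses)


def train_alpha_family(
    system: SpectralSystem,
    filter_spec: FilterSpec,
    alpha_grid: Sequence[float],
    dataset_spec: dict,
    config: TrainingConfig,
    *,
    mode: str = "continued_svd",
    network_factory=None,
) -> Tuple[List[RegNetModel], List[dict]]:
    """Train one network per alpha, each on its own regenerated dataset.

    ``dataset_spec`` carries the keyword arguments of `make_dataset` except
    the filter/alpha (keys: n_samples, seed, delta_train, geometry,
    complexity).  ``network_factory(seed)`` builds a fresh untrained network;
    by default a small convolutional encoder-decoder.  Returns the trained
    models and per-run manifests (alpha, seed, epochs, final loss).
    """
    alpha_grid = list(alpha_grid)
    if any(a2 >= a1 for a1, a2 in zip(alpha_grid, alpha_grid[1:])):
        raise ValueError("alpha_grid must be strictly decreasing")
    if network_factory is None:
        from .networks import ConvEncoderDecoder

        network_factory = lambda seed: ConvEncoderDecoder(seed=seed)

    models, manifests = [], []
    for i, alpha in enumerate(alpha_grid):
        run_seed = derive_seed(config.seed, i)
        dataset = make_dataset(
            system,
            filter_spec,
            alpha,
            n_samples=dataset_spec["n_samples"],
            seed=dataset_spec.get("seed", 0),
            delta_train=dataset_spec.get("delta_train", 0.0),
            geometry=dataset_spec["geometry"],
            complexity=dataset_spec.get("complexity", (5, 12)),
        )
        model = RegNetModel(
            system=system,
            filter=filter_spec,
            alpha=float(alpha),
            network=network_factory(run_seed),
            mode=mode,
        )
        run_config = replace(config, seed=run_seed, alpha=float(alpha))
        model, losses = train_regnet(model, dataset, run_config)
        models.append(model)
        manifests.append(
            {
                "alpha": float(alpha),
                "mode": mode,
                "seed": run_seed,
                "epochs": config.epochs,
                "final_loss": float(losses[-1]),
                "loss_trajectory": losses.tolist(),
            }
        )
    return models, manifests
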