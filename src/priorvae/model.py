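"""Prior-conditioned variational autoencoder with attention fusion.

The network classifies a binary phenotype (immunotherapy response) from
high-dimensional gene-level microbial abundance while conditioning its latent
space on a fixed matrix of protein-sequence embeddings ("biological prior
knowledge"):

* an encoder maps the standardized abundance vector x (dim M) through
  M -> 512 (batch-normalized) -> 256 to a latent mean mu;
* the latent sample is reparameterized as z = mu + eps, eps ~ N(0, I)
  (eps = 0 in evaluation mode, so inference is deterministic);
* the prior matrix R (P x E, E = 320, never trained) is projected to the
  latent width, R' = proj(R) in R^{P x d}, and multi-head scaled dot-product
  attention with query mu and keys/values R' produces a prior-aware
  embedding a, layer-normalized;
* decoder input is the convex fusion z~ = lambda * z + (1 - lambda) * a
  (lambda = 0.7), mapped d -> 512 (batch norm, ReLU) -> M (batch norm) with a
  final sigmoid giving the reconstruction;
* a classifier head reads mu through 256 -> 128 -> 64 -> 1 (batch norm +
  ReLU per hidden layer, sigmoid output).

Training minimizes  L_total = lambda_rec * L_rec + lambda_kl * L_KL + L_cls
with L_rec the per-sample squared reconstruction error averaged over the
batch, L_KL = 1/2 * sum_j mu_j^2 (the KL divergence to a standard normal
under a unit-variance posterior) and L_cls the binary cross-entropy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from . import nn
from .io import PriorMatrix
from .nn import Tensor, Parameter

logger = logging.getLogger("priorvae")

__all__ = [
    "NetworkConfig",
    "LatentState",
    "LossBreakdown",
    "PriorFusionVAE",
    "reconstruction_loss",
    "kl_loss",
    "classification_loss",
    "total_loss",
    "save_checkpoint",
    "load_checkpoint",
]

_CLAMP = 1e-7  # probability clamp for the cross-entropy


@dataclass
class NetworkConfig:
    """Architecture and loss hyperparameters.

    latent width d must be divisible by the head count H; per-head width is
    d / H.  ``fusion_lambda`` weights the latent sample against the
    attention embedding in the decoder input.  ``reconstruction_target``
    selects what the sigmoid decoder is regressed against: the z-scored
    input itself (``zscore``, the literal formulation) or a per-feature
    min-max rescaling of it into [0, 1] (``minmax``).
    """

    input_dim: int
    latent_dim: int = 256
    hidden_dim: int = 512
    prior_dim: int = 320
    n_heads: int = 4
    fusion_lambda: float = 0.7
    classifier_dims: tuple[int, int] = (128, 64)
    lambda_rec: float = 0.1
    lambda_kl: float = 0.2
    reconstruction_target: Literal["zscore", "minmax"] = "zscore"
    loss_reduction: Literal["mean", "sum"] = "mean"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.latent_dim % self.n_heads != 0:
            raise ValueError(
                f"latent_dim {self.latent_dim} not divisible by n_heads {self.n_heads}"
            )
        for name in ("fusion_lambda", "lambda_rec", "lambda_kl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.input_dim, self.latent_dim, self.hidden_dim, self.prior_dim,
               *self.classifier_dims) < 1:
            raise ValueError("all widths must be positive")

    @property
    def head_dim(self) -> int:
        return self.latent_dim // self.n_heads


@dataclass
class LatentState:
    """Latent mean, sample and the noise that produced it (z = mu + epsilon)."""

    mu: np.ndarray
    z: np.ndarray
    epsilon: np.ndarray


@dataclass
class LossBreakdown:
    """The four loss terms of one batch; total = lr*rec + lk*kl + cls."""

    total: float
    reconstruction: float
    kl: float
    classification: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _clip01(p: Tensor) -> Tensor:
    """Clamp probabilities into [eps, 1-eps]; gradient passes only inside."""
    clipped = np.clip(p.data, _CLAMP, 1.0 - _CLAMP)
    if np.any(clipped != p.data):
        logger.debug("classification_loss: probabilities clamped by epsilon guard")
    mask = (p.data > _CLAMP) & (p.data < 1.0 - _CLAMP)
    out = Tensor(clipped, parents=(p,))
    out._backward = lambda g: p.accumulate(g * mask)
    return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _batch_reduce(per_sample: Tensor, reduction: str) -> Tensor:
    if reduction == "mean":
        return nn.mean_all(per_sample)
    return nn.sum_all(per_sample)


def reconstruction_loss(x_recon, x_target) -> Tensor:
    """Mean over samples of the squared Euclidean reconstruction residual."""
    xr, xt = _as_tensor(x_recon), _as_tensor(x_target)
    if xr.shape != xt.shape:
        raise ValueError(f"shape mismatch {xr.shape} vs {xt.shape}")
    resid = nn.sub(xr, xt)
    return nn.scale(nn.sum_all(nn.mul(resid, resid)), 1.0 / xr.shape[0])


def kl_loss(mu, reduction: str = "mean") -> Tensor:
    """1/2 * sum_j mu_j^2 per sample, reduced over the batch.

    This is the KL divergence of N(mu, I) from N(0, I); the posterior
    variance is fixed at one, so only the mean term survives.
    """
    m = _as_tensor(mu)
    per_sample = nn.scale(nn.mul(m, m), 0.5)
    if reduction == "mean":
        return nn.scale(nn.sum_all(per_sample), 1.0 / m.shape[0])
    return nn.sum_all(per_sample)


def classification_loss(y_hat, y, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy between predicted probabilities and 0/1 labels."""
    p = _clip01(_as_tensor(y_hat))
    yv = np.asarray(y, dtype=float).reshape(p.shape)
    term_pos = nn.mul(Tensor(yv), nn.log(p))
    term_neg = nn.mul(Tensor(1.0 - yv), nn.log(nn.sub(Tensor(np.ones_like(yv)), p)))
    nll = nn.scale(nn.add(term_pos, term_neg), -1.0)
    return _batch_reduce(nll, reduction)


def total_loss(
    rec: Tensor | float,
    kl: Tensor | float,
    cls: Tensor | float,
    lambda_rec: float = 0.1,
    lambda_kl: float = 0.2,
) -> tuple[Tensor, LossBreakdown]:
    """Weighted composite loss and its logged breakdown."""
    rec_t, kl_t, cls_t = _as_tensor(rec), _as_tensor(kl), _as_tensor(cls)
    tot = nn.add(nn.add(nn.scale(rec_t, lambda_rec), nn.scale(kl_t, lambda_kl)), cls_t)
    parts = LossBreakdown(
        total=float(tot.data),
        reconstruction=float(rec_t.data),
        kl=float(kl_t.data),
        classification=float(cls_t.data),
    )
    return tot, parts


class PriorFusionVAE(nn.Module):
    """The full network.  The prior matrix is stored as a constant tensor."""

    def __init__(self, config: NetworkConfig, prior: PriorMatrix):
        if prior.embedding_dim != config.prior_dim:
            raise ValueError(
                f"prior width {prior.embedding_dim} != configured {config.prior_dim}"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, dh, H = config.latent_dim, config.head_dim, config.n_heads
        self.prior = Tensor(prior.values.copy())  # never trained
        self.prior_ids = list(prior.protein_ids)

        # encoder
        self.enc1 = nn.Linear(config.input_dim, config.hidden_dim, rng)
        self.enc_bn = nn.BatchNorm1d(config.hidden_dim)
        self.enc2 = nn.Linear(config.hidden_dim, d, rng)

        # prior projection + multi-head attention
        self.prior_proj = nn.Linear(config.prior_dim, d, rng)
        bound = 1.0 / np.sqrt(d)
        self.Wq = [Parameter(rng.uniform(-bound, bound, (d, dh))) for _ in range(H)]
        self.Wk = [Parameter(rng.uniform(-bound, bound, (d, dh))) for _ in range(H)]
        self.Wv = [Parameter(rng.uniform(-bound, bound, (d, dh))) for _ in range(H)]
        self.Wo = Parameter(rng.uniform(-bound, bound, (d, d)))
        self.attn_ln = nn.LayerNorm(d)

        # decoder
        self.dec1 = nn.Linear(d, config.hidden_dim, rng)
        self.dec_bn1 = nn.BatchNorm1d(config.hidden_dim)
        self.dec2 = nn.Linear(config.hidden_dim, config.input_dim, rng)
        self.dec_bn2 = nn.BatchNorm1d(config.input_dim)

        # classifier
        c1, c2 = config.classifier_dims
        self.cls1 = nn.Linear(d, c1, rng)
        self.cls_bn1 = nn.BatchNorm1d(c1)
        self.cls2 = nn.Linear(c1, c2, rng)
        self.cls_bn2 = nn.BatchNorm1d(c2)
        self.cls3 = nn.Linear(c2, 1, rng)

        self.training = True
        self.last_attention_weights: Optional[np.ndarray] = None  # (H, B, P)

    # -- mode switches -------------------------------------------------
    def _bn_layers(self) -> list[nn.BatchNorm1d]:
        return [self.enc_bn, self.dec_bn1, self.dec_bn2, self.cls_bn1, self.cls_bn2]

    def train_mode(self) -> "PriorFusionVAE":
        self.training = True
        for bn in self._bn_layers():
            bn.training = True
        return self

    def eval_mode(self) -> "PriorFusionVAE":
        self.training = False
        for bn in self._bn_layers():
            bn.training = False
        return self

    # -- forward pieces ------------------------------------------------
    def encode(self, x: Tensor | np.ndarray) -> Tensor:
        xt = _as_tensor(x)
        if xt.shape[-1] != self.config.input_dim:
            raise ValueError(
                f"input width {xt.shape[-1]} != configured {self.config.input_dim}"
            )
        h = nn.relu(self.enc_bn(self.enc1(xt)))
        return self.enc2(h)

    def reparameterize(
        self, mu: Tensor, rng: Optional[np.random.Generator] = None
    ) -> tuple[Tensor, np.ndarray]:
        """z = mu + eps.  eps ~ N(0, I) in training, 0 in evaluation mode."""
        if self.training:
            if rng is None:
                raise ValueError("training-mode reparameterization needs an rng")
            eps = rng.standard_normal(mu.shape)
        else:
            eps = np.zeros(mu.shape)
        return nn.add(mu, Tensor(eps)), eps

    def project_prior(self) -> Tensor:
        """R' = proj(R), recomputed from current projection weights each pass."""
        return self.prior_proj(self.prior)

    def attend(self, mu: Tensor, r_prime: Tensor) -> Tensor:
        """Multi-head scaled dot-product attention of mu over the prior rows.

        Per head h: softmax_P((mu Wq_h)(R' Wk_h)^T / sqrt(dh)) (R' Wv_h);
        heads concatenated, mixed by Wo, layer-normalized.
        """
        dh = self.config.head_dim
        heads = []
        weights = []
        for Wq, Wk, Wv in zip(self.Wq, self.Wk, self.Wv):
            q = nn.matmul(mu, Wq)                      # B x dh
            k = nn.matmul(r_prime, Wk)                 # P x dh
            v = nn.matmul(r_prime, Wv)                 # P x dh
            logits = nn.scale(nn.matmul(q, _transpose(k)), 1.0 / np.sqrt(dh))
            if not np.all(np.isfinite(logits.data)):
                raise FloatingPointError("non-finite attention logits")
            w = nn.softmax_rows(logits)                # B x P
            weights.append(w.data)
            heads.append(nn.matmul(w, v))
        self.last_attention_weights = np.stack(weights)
        mixed = nn.matmul(nn.concat(heads, axis=1), self.Wo)
        return self.attn_ln(mixed)

    def fuse(self, z: Tensor, a: Tensor) -> Tensor:
        lam = self.config.fusion_lambda
        return nn.add(nn.scale(z, lam), nn.scale(a, 1.0 - lam))

    def decode(self, z_tilde: Tensor) -> Tensor:
        h = nn.relu(self.dec_bn1(self.dec1(z_tilde)))
        return nn.sigmoid(self.dec_bn2(self.dec2(h)))

    def classify(self, mu: Tensor) -> Tensor:
        h = nn.relu(self.cls_bn1(self.cls1(mu)))
        h = nn.relu(self.cls_bn2(self.cls2(h)))
        return nn.sigmoid(self.cls3(h))

    # -- full pass -----------------------------------------------------
    def forward(
        self, x: Tensor | np.ndarray, rng: Optional[np.random.Generator] = None
    ) -> dict[str, Tensor]:
        xt = _as_tensor(x)
        mu = self.encode(xt)
        z, eps = self.reparameterize(mu, rng)
        r_prime = self.project_prior()
        a = self.attend(mu, r_prime)
        z_tilde = self.fuse(z, a)
        x_recon = self.decode(z_tilde)
        y_hat = self.classify(mu)
        return {
            "mu": mu, "z": z, "epsilon": Tensor(eps), "a": a,
            "z_tilde": z_tilde, "x_recon": x_recon, "y_hat": y_hat,
        }

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Deterministic responder probabilities (evaluation mode enforced)."""
        was_training = self.training
        self.eval_mode()
        p = self.classify(self.encode(_as_tensor(np.atleast_2d(x)))).data.ravel()
        if was_training:
            self.train_mode()
        return p

    def latent_state(self, x: np.ndarray) -> LatentState:
        mu = self.encode(_as_tensor(np.atleast_2d(x)))
        z, eps = self.reparameterize(mu)
        return LatentState(mu.data, z.data, eps)

    def batch_loss(
        self,
        x: np.ndarray,
        x_target: np.ndarray,
        y: np.ndarray,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[Tensor, LossBreakdown]:
        out = self.forward(x, rng)
        red = self.config.loss_reduction
        rec = reconstruction_loss(out["x_recon"], Tensor(np.asarray(x_target, float)))
        kl = kl_loss(out["mu"], red)
        cls = classification_loss(out["y_hat"], np.asarray(y, float), red)
        return total_loss(rec, kl, cls, self.config.lambda_rec, self.config.lambda_kl)


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))
    out._backward = lambda g: t.accumulate(g.T)
    return out


# ---------------------------------------------------------------------------
# checkpointing: weights + config serialized together


def _state_arrays(model: PriorFusionVAE) -> dict[str, np.ndarray]:
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(model._bn_layers()):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    return arrays


def save_checkpoint(model: PriorFusionVAE, path: str | Path) -> None:
    cfg = asdict(model.config)
    cfg["classifier_dims"] = list(cfg["classifier_dims"])
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        __prior__=model.prior.data,
        __prior_ids__=np.array(model.prior_ids),
        **_state_arrays(model),
    )


def load_checkpoint(path: str | Path) -> PriorFusionVAE:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["classifier_dims"] = tuple(cfg["classifier_dims"])
        prior = PriorMatrix([str(s) for s in data["__prior_ids__"]], data["__prior__"])
        model = PriorFusionVAE(NetworkConfig(**cfg), prior)
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i}"].copy()
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean = data[f"bn{i}_mean"].copy()
            bn.running_var = data[f"bn{i}_var"].copy()
    return model
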