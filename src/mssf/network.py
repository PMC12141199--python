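"""The multi-source fusion network and its composite loss.

Architecture, per (drug, side-effect) pair:

1. three feature-combination branches — an attention autoencoder on the
   concatenation feature (EN-con), an attention autoencoder on the
   addition feature (EN-add), and a three-block CNN on the stack of
   rank-1 interaction maps (CNN-im);
2. the branch latents are concatenated and fused by a self-attention
   block (token-wise, within each sample);
3. a variational head maps the fused vector to a Gaussian mean and
   log-variance; the latent is drawn by the reparameterization trick
   F_l = μ + ε·σ with σ = exp(½·logσ²) (ε = 0 at evaluation);
4. a two-hidden-layer MLP with five sigmoid outputs scores the five
   frequency classes; the prediction is the argmax (ties → lower class).

The training loss is
    L = BCE + α1·MSE(EN-con) + α2·MSE(EN-add) + α3·KL(μ, σ) + γ·Σθ²
with the standard non-negative Gaussian KL (a ``paper_literal_kl`` flag
flips its sign to the printed form, which is the negative divergence).
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import RunConfig

_EPS = 1e-7


# ---------------------------------------------------------------------------
# module infrastructure
# ---------------------------------------------------------------------------


class Module:
    """Parameter container with recursive collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self):
        self.training = True
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self):
        self.train()
        self._set_eval()
        return self

    def _set_eval(self):
        self.training = False
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value._set_eval()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_eval()

    def state_arrays(self) -> list:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int):
        super().__init__()
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias

    __call__ = forward


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * gamma + beta


class AttentionBlock(Module):
    """Single-head self-attention over a sample's tokens, with the
    residual map F_e = ReLU(LN(Attention + X)) + X."""

    def __init__(self, rng, width: int):
        super().__init__()
        self.width = width
        self.w_q = Tensor(_glorot(rng, width, width, (width, width)), requires_grad=True)
        self.w_k = Tensor(_glorot(rng, width, width, (width, width)), requires_grad=True)
        self.w_v = Tensor(_glorot(rng, width, width, (width, width)), requires_grad=True)
        self.ln_gamma = Tensor(np.ones(width), requires_grad=True)
        self.ln_beta = Tensor(np.zeros(width), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        """x: (..., tokens, width) → same shape."""
        if x.shape[-1] != self.width:
            raise ValueError(f"token width {x.shape[-1]} != block width {self.width}")
        q = ag.matmul(x, self.w_q)
        k = ag.matmul(x, self.w_k)
        v = ag.matmul(x, self.w_v)
        scores = ag.matmul(q, k.swap_last()) * (1.0 / math.sqrt(self.width))
        att = ag.matmul(ag.softmax(scores, axis=-1), v)
        return ag.relu(layer_norm(att + x, self.ln_gamma, self.ln_beta)) + x

    __call__ = forward

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Softmax attention matrix (diagnostic; rows sum to 1)."""
        q = ag.matmul(x, self.w_q)
        k = ag.matmul(x, self.w_k)
        scores = ag.matmul(q, k.swap_last()) * (1.0 / math.sqrt(self.width))
        return ag.softmax(scores, axis=-1).data


class AutoEncoder(Module):
    """Two-linear-layer encoder with a self-attention layer in between,
    and a two-linear-layer decoder reconstructing the input."""

    def __init__(self, rng, in_dim: int, hidden: int, latent: int, tokens: int):
        super().__init__()
        if hidden % tokens:
            raise ValueError("hidden width must be divisible by token count")
        self.in_dim = in_dim
        self.tokens = tokens
        self.latent_width = latent
        self.enc_linear1 = Linear(rng, in_dim, hidden)
        self.attention = AttentionBlock(rng, hidden // tokens)
        self.enc_linear2 = Linear(rng, hidden, latent)
        self.dec_linear1 = Linear(rng, latent, hidden)
        self.dec_linear2 = Linear(rng, hidden, in_dim)

    def forward(self, x: Tensor):
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"input width {x.shape[-1]} != {self.in_dim}")
        b = x.shape[0]
        h1 = self.enc_linear1(x)
        tok = h1.reshape(b, self.tokens, -1)
        att = self.attention(tok).reshape(b, -1)
        latent = self.enc_linear2(att)
        recon = self.dec_linear2(self.dec_linear1(latent))
        return latent, recon

    __call__ = forward


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data - self.running_mean)
            self.running_var += self.momentum * (var.data - self.running_var)
        else:
            mu, var = Tensor(self.running_mean), Tensor(self.running_var)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta

    __call__ = forward


class InteractionCNN(Module):
    """Three (conv → batch-norm → ReLU) blocks on the interaction-map
    stack, followed by flattening."""

    def __init__(self, rng, in_channels: int, h: int, channels=(32, 64, 64), kernel: int = 3):
        super().__init__()
        self.in_channels = in_channels
        self.h = h
        self.kernel = kernel
        self.convs, self.bns = [], []
        c_prev, size = in_channels, h
        for c in channels:
            fan_in = c_prev * kernel * kernel
            w = rng.standard_normal((c, c_prev, kernel, kernel)) * math.sqrt(2.0 / fan_in)
            self.convs.append(
                (Tensor(w, requires_grad=True), Tensor(np.zeros(c), requires_grad=True))
            )
            self.bns.append(BatchNorm2d(c))
            c_prev = c
            size = size - kernel + 1
            if size < 1:
                raise ValueError("interaction maps too small for the CNN depth")
        self.out_len = c_prev * size * size
        # conv weights are tuples, invisible to Module.parameters()
        self._conv_params = [t for pair in self.convs for t in pair]

    def parameters(self) -> list:
        return list(self._conv_params) + super().parameters()

    def forward(self, maps: Tensor) -> Tensor:
        if maps.shape[1] != self.in_channels or maps.shape[-1] != self.h:
            raise ValueError(
                f"expected maps of shape (B, {self.in_channels}, {self.h}, {self.h}),"
                f" got {maps.shape}"
            )
        x = maps
        for (w, b), bn in zip(self.convs, self.bns):
            x = ag.relu(bn(ag.conv2d(x, w, b)))
        return x.reshape(x.shape[0], -1)

    __call__ = forward


class BVIHead(Module):
    """Gaussian mean / log-variance maps over the fused representation."""

    def __init__(self, rng, in_dim: int, d: int):
        super().__init__()
        self.d = d
        self.mean_map = Linear(rng, in_dim, d)
        self.logvar_map = Linear(rng, in_dim, d)

    def forward(self, f_f: Tensor):
        return self.mean_map(f_f), self.logvar_map(f_f)

    __call__ = forward


def bvi_sample(mu: Tensor, logvar: Tensor, eps) -> Tensor:
    """Reparameterized sample F_l = μ + ε·σ with σ = exp(½·logσ²)."""
    if not (np.isfinite(mu.data).all() and np.isfinite(logvar.data).all()):
        raise FloatingPointError("non-finite variational parameters")
    sigma = (logvar * 0.5).exp()
    return mu + Tensor(np.asarray(eps, dtype=float)) * sigma


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


class MSSFModel(Module):
    """End-to-end fusion model for one similarity bank geometry.

    ``n_drugs`` / ``n_side_effects`` are the entity counts, ``p`` / ``q``
    the numbers of drug and side-effect similarity sources (11/4 or the
    masked 9/2).  Ablation switches in the config drop whole branches;
    the fused width shrinks accordingly.
    """

    def __init__(self, n_drugs: int, n_side_effects: int, p: int, q: int,
                 config: RunConfig, rng: np.random.Generator):
        super().__init__()
        cfg = config
        self.config = cfg
        self.n_drugs, self.n_side_effects = n_drugs, n_side_effects
        self.p, self.q = p, q
        if not (cfg.use_en_con or cfg.use_en_add or cfg.use_cnn):
            raise ValueError("at least one extractor branch must be enabled")

        fused = 0
        if cfg.use_en_con:
            self.en_con = AutoEncoder(
                rng, p * n_drugs + q * n_side_effects,
                cfg.hidden_con, cfg.latent_con, cfg.tokens,
            )
            fused += cfg.latent_con
        if cfg.use_en_add:
            self.en_add = AutoEncoder(
                rng, n_drugs + n_side_effects,
                cfg.hidden_add, cfg.latent_add, cfg.tokens,
            )
            fused += cfg.latent_add
        if cfg.use_cnn:
            self.drug_proj_w = Tensor(
                _glorot(rng, n_drugs, cfg.h, (p, n_drugs, cfg.h)), requires_grad=True
            )
            self.drug_proj_b = Tensor(np.zeros((p, 1, cfg.h)), requires_grad=True)
            self.se_proj_w = Tensor(
                _glorot(rng, n_side_effects, cfg.h, (q, n_side_effects, cfg.h)),
                requires_grad=True,
            )
            self.se_proj_b = Tensor(np.zeros((q, 1, cfg.h)), requires_grad=True)
            self.cnn = InteractionCNN(rng, p * q, cfg.h, cfg.cnn_channels, cfg.kernel)
            fused += self.cnn.out_len

        self.fused_len = fused
        pad = (-fused) % cfg.tokens
        self._fusion_pad = pad
        self.fusion = AttentionBlock(rng, (fused + pad) // cfg.tokens)

        clf_in = cfg.d if cfg.use_bvi else fused
        if cfg.use_bvi:
            self.bvi = BVIHead(rng, fused, cfg.d)
        h1, h2 = cfg.clf_hidden
        self.clf1 = Linear(rng, clf_in, h1)
        self.clf2 = Linear(rng, h1, h2)
        self.clf3 = Linear(rng, h2, 5)

    # -- branch forwards ----------------------------------------------------

    def project_maps(self, drug_raw: np.ndarray, se_raw: np.ndarray) -> Tensor:
        """Learnable per-source projections and outer products.

        drug_raw (B, P, n), se_raw (B, Q, m) → maps (B, P·Q, h, h),
        map index k = p·Q + q (drug-major).
        """
        b = drug_raw.shape[0]
        h = self.config.h
        xd = ag.matmul(Tensor(drug_raw).reshape(b, self.p, 1, -1), self.drug_proj_w)
        xd = (xd + self.drug_proj_b).reshape(b, self.p, h)
        xs = ag.matmul(Tensor(se_raw).reshape(b, self.q, 1, -1), self.se_proj_w)
        xs = (xs + self.se_proj_b).reshape(b, self.q, h)
        maps = xd.reshape(b, self.p, 1, h, 1) * xs.reshape(b, 1, self.q, 1, h)
        return maps.reshape(b, self.p * self.q, h, h)

    def fuse(self, latents: list) -> Tensor:
        """Concatenate branch latents and run the fusion attention.

        The concatenated vector is zero-padded to a multiple of the
        token count, tokenized, passed through the attention block and
        un-padded back to its original length.
        """
        x_f = ag.concat(latents, axis=-1) if len(latents) > 1 else latents[0]
        b = x_f.shape[0]
        if self._fusion_pad:
            x_f = ag.concat([x_f, Tensor(np.zeros((b, self._fusion_pad)))], axis=-1)
        tok = x_f.reshape(b, self.config.tokens, -1)
        out = self.fusion(tok).reshape(b, -1)
        if self._fusion_pad:
            out = out.narrow(0, self.fused_len)
        return out

    def classify(self, f_l: Tensor, rng: np.random.Generator) -> Tensor:
        cfg = self.config
        z = ag.dropout(ag.relu(self.clf1(f_l)), cfg.dropout, rng, self.training)
        z = ag.dropout(ag.relu(self.clf2(z)), cfg.dropout, rng, self.training)
        return ag.sigmoid(self.clf3(z))

    def forward(self, batch: dict, rng: np.random.Generator, eps=None) -> dict:
        """Full forward pass on an ``assemble_batch`` dictionary.

        ``eps`` overrides the reparameterization noise; by default it is
        standard normal in training mode and zero in evaluation mode.
        """
        cfg = self.config
        out: dict = {}
        latents = []
        if cfg.use_en_con:
            x = Tensor(batch["concat"])
            f_con, recon = self.en_con(x)
            out["f_con"], out["recon_con"], out["input_con"] = f_con, recon, x
            latents.append(f_con)
        if cfg.use_en_add:
            x = Tensor(batch["add"])
            f_add, recon = self.en_add(x)
            out["f_add"], out["recon_add"], out["input_add"] = f_add, recon, x
            latents.append(f_add)
        if cfg.use_cnn:
            maps = self.project_maps(batch["drug_raw"], batch["se_raw"])
            out["maps"] = maps
            f_im = self.cnn(maps)
            out["f_im"] = f_im
            latents.append(f_im)

        f_f = self.fuse(latents)
        out["f_f"] = f_f

        if cfg.use_bvi:
            mu, logvar = self.bvi(f_f)
            if eps is None:
                if self.training or cfg.sample_eval_eps:
                    eps = rng.standard_normal(mu.shape)
                else:
                    eps = np.zeros(mu.shape)
            f_l = bvi_sample(mu, logvar, eps)
            out["mu"], out["logvar"], out["f_l"] = mu, logvar, f_l
        else:
            f_l = f_f
            out["f_l"] = f_l

        out["scores"] = self.classify(f_l, rng)
        return out

    __call__ = forward

    def predict_classes(self, scores: np.ndarray) -> np.ndarray:
        """Argmax over the five sigmoid scores; ties break to the lower
        class.  Returns classes in 1..5."""
        return np.argmax(scores, axis=-1) + 1


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def bce_loss(scores: Tensor, one_hot: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy against one-hot class labels."""
    y = Tensor(np.asarray(one_hot, dtype=float))
    p = scores * (1 - 2 * _EPS) + _EPS  # clamp away from {0, 1}
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def mse_loss(pred: Tensor, target: Tensor) -> Tensor:
    return ((pred - target) ** 2).mean()


def kl_term(mu: Tensor, logvar: Tensor, paper_literal: bool = False) -> Tensor:
    """Gaussian-to-standard-normal KL, summed over latent dimensions and
    averaged over the batch: −½ Σ (1 + logσ² − μ² − σ²) ≥ 0.

    ``paper_literal`` flips the sign to the printed form ½ Σ (1 + 2lnσ −
    μ² − σ²), which is the negative of the divergence.
    """
    per = (1.0 + logvar - mu**2 - logvar.exp()) * (-0.5)
    kl = per.sum(axis=-1).mean() if per.ndim > 1 else per.sum()
    return -kl if paper_literal else kl


def l2_penalty(params: list) -> Tensor:
    total = None
    for p in params:
        sq = (p**2).sum()
        total = sq if total is None else total + sq
    return total if total is not None else Tensor(0.0)


def total_loss(out: dict, one_hot: np.ndarray, weights: RunConfig, params: list):
    """Composite training loss and its component breakdown.

    L = BCE + α1·MSE(con) + α2·MSE(add) + α3·KL + γ·Σθ².  Missing
    branches contribute nothing.  Raises on a non-finite total, naming
    the offending component.
    """
    parts = {"bce": bce_loss(out["scores"], one_hot)}
    if "recon_con" in out:
        parts["mse_con"] = mse_loss(out["recon_con"], out["input_con"].detach()) * weights.alpha1
    if "recon_add" in out:
        parts["mse_add"] = mse_loss(out["recon_add"], out["input_add"].detach()) * weights.alpha2
    if "mu" in out:
        parts["kl"] = kl_term(out["mu"], out["logvar"], weights.paper_literal_kl) * weights.alpha3
    if weights.gamma > 0:
        parts["l2"] = l2_penalty(params) * weights.gamma
    loss = None
    for term in parts.values():
        loss = term if loss is None else loss + term
    bad = {k: v.item() for k, v in parts.items() if not np.isfinite(v.data).all()}
    if bad:
        raise FloatingPointError(f"non-finite loss components: {bad}")
    return loss, parts


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
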