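"""Three-stage predictor network, implemented in NumPy.

The architecture maps a genomic feature vector to a predictive Gaussian:

* encoder: a linear embedding (input -> 128) followed by three blocks of
  linear -> layer-norm -> ReLU -> dropout with widths 256, 128 and 64,
  producing the manifold embedding Z;
* planner: a two-layer MLP (64 -> 128 -> m) producing an action matrix A
  whose m components are trained to track the standardized capability
  indicators;
* forecaster: a shared ReLU trunk on A feeding two linear heads, one for
  the predictive mean and one for the log-variance (sigma^2 = exp(log_var),
  clamped to [variance_floor, variance_ceiling]).

Forward, backward (hand-written, validated by finite differences in the
test suite) and Monte-Carlo-dropout prediction all live here.  Dropout
sits after every ReLU in the encoder and planner; the forecaster carries
none, so epistemic variation flows through the representation layers.

Ablation variants are wired structurally: ``no_manifold`` shrinks the
encoder to the embedding plus a single 64-unit block, ``no_planner``
routes Z straight into the forecaster trunk, and ``no_uncertainty``
drops the log-variance head (and with it MC sampling).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_LN_EPS = 1e-5

VARIANTS = ("full", "no_manifold", "no_planner", "no_uncertainty",
            "no_constraint")


@dataclass(frozen=True)
class ModelSpec:
    input_dim: int
    embed_dim: int = 128
    encoder_dims: tuple[int, ...] = (256, 128, 64)
    planner_hidden: int = 128
    action_dim: int = 3
    trunk_hidden: int = 64
    dropout_p: float = 0.1
    variance_floor: float = 1e-6
    variance_ceiling: float = 1e6
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        for d in (self.embed_dim, *self.encoder_dims, self.planner_hidden,
                  self.action_dim, self.trunk_hidden):
            if d <= 0:
                raise ValueError("all layer dimensions must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant '{self.variant}'")
        if self.variance_floor <= 0 or self.variance_ceiling <= self.variance_floor:
            raise ValueError("need 0 < variance_floor < variance_ceiling")

    @property
    def effective_encoder_dims(self) -> tuple[int, ...]:
        if self.variant == "no_manifold":
            return (self.encoder_dims[-1],)
        return self.encoder_dims

    @property
    def latent_dim(self) -> int:
        return self.effective_encoder_dims[-1]

    @property
    def trunk_input_dim(self) -> int:
        return self.latent_dim if self.variant == "no_planner" else self.action_dim

    @property
    def has_planner(self) -> bool:
        return self.variant != "no_planner"

    @property
    def has_variance_head(self) -> bool:
        return self.variant != "no_uncertainty"

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim, "embed_dim": self.embed_dim,
            "encoder_dims": list(self.encoder_dims),
            "planner_hidden": self.planner_hidden,
            "action_dim": self.action_dim, "trunk_hidden": self.trunk_hidden,
            "dropout_p": self.dropout_p,
            "variance_floor": self.variance_floor,
            "variance_ceiling": self.variance_ceiling,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["encoder_dims"] = tuple(d["encoder_dims"])
        return cls(**d)


@dataclass
class PredictiveOutput:
    mu: np.ndarray
    var_aleatoric: np.ndarray
    var_epistemic: np.ndarray
    var_total: np.ndarray
    T: int
    draws: np.ndarray | None = None      # optional T x n matrix of mu_t


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    bound = 1.0 / math.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=fan_out)
    return W, b


def init_model(spec: ModelSpec, seed: int) -> dict[str, np.ndarray]:
    """Deterministic fan-in-scaled uniform initialization."""
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    p["embed.W"], p["embed.b"] = _init_linear(rng, spec.input_dim,
                                              spec.embed_dim)
    prev = spec.embed_dim
    for i, width in enumerate(spec.effective_encoder_dims):
        p[f"enc{i}.W"], p[f"enc{i}.b"] = _init_linear(rng, prev, width)
        p[f"enc{i}.g"] = np.ones(width)
        p[f"enc{i}.beta"] = np.zeros(width)
        prev = width
    if spec.has_planner:
        p["plan0.W"], p["plan0.b"] = _init_linear(rng, spec.latent_dim,
                                                  spec.planner_hidden)
        p["plan1.W"], p["plan1.b"] = _init_linear(rng, spec.planner_hidden,
                                                  spec.action_dim)
    p["trunk.W"], p["trunk.b"] = _init_linear(rng, spec.trunk_input_dim,
                                              spec.trunk_hidden)
    p["mean.W"], p["mean.b"] = _init_linear(rng, spec.trunk_hidden, 1)
    if spec.has_variance_head:
        p["logvar.W"], p["logvar.b"] = _init_linear(rng, spec.trunk_hidden, 1)
    return p


def zero_params(spec: ModelSpec) -> dict[str, np.ndarray]:
    """All-zero weights/biases (layer-norm gains stay 1) — test helper."""
    p = init_model(spec, 0)
    for k in p:
        if not k.endswith(".g"):
            p[k] = np.zeros_like(p[k])
    return p


# ---------------------------------------------------------------------------
# Forward
# ---------------------------------------------------------------------------

def _layer_norm_fwd(a: np.ndarray, g: np.ndarray, beta: np.ndarray):
    mean = a.mean(axis=1, keepdims=True)
    var = a.var(axis=1, keepdims=True)
    std = np.sqrt(var + _LN_EPS)
    xhat = (a - mean) / std
    return g * xhat + beta, (xhat, std)


def _layer_norm_bwd(dy: np.ndarray, g: np.ndarray, xhat: np.ndarray,
                    std: np.ndarray):
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * g
    m1 = dxhat.mean(axis=1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
    dx = (dxhat - m1 - xhat * m2) / std
    return dx, dgamma, dbeta


def forward(params: dict[str, np.ndarray], spec: ModelSpec, X: np.ndarray,
            train: bool = False, rng: np.random.Generator | None = None,
            return_cache: bool = False):
    """Run the network; returns (Z, A, mu, log_var[, cache]).

    Dropout is applied only when ``train`` is true and a generator is
    supplied (MC prediction passes ``train=True`` with its own rng).
    ``log_var`` is ``None`` for the ``no_uncertainty`` variant; otherwise
    sigma^2 = exp(clip(log_var)) is left to the caller.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(f"X must be n x {spec.input_dim}, got {X.shape}")
    drop = train and spec.dropout_p > 0 and rng is not None
    keep = 1.0 - spec.dropout_p
    cache: dict = {"X": X, "drop": drop, "blocks": []}

    h = X @ params["embed.W"] + params["embed.b"]
    cache["embed_out"] = h
    for i in range(len(spec.effective_encoder_dims)):
        blk: dict = {"x_in": h}
        a = h @ params[f"enc{i}.W"] + params[f"enc{i}.b"]
        ln, (xhat, std) = _layer_norm_fwd(a, params[f"enc{i}.g"],
                                          params[f"enc{i}.beta"])
        r = np.maximum(ln, 0.0)
        blk.update(xhat=xhat, std=std, relu_mask=(ln > 0))
        if drop:
            mask = (rng.random(r.shape) < keep) / keep
            r = r * mask
            blk["drop_mask"] = mask
        h = r
        cache["blocks"].append(blk)
    Z = h

    if spec.has_planner:
        cache["plan_in"] = Z
        p1 = Z @ params["plan0.W"] + params["plan0.b"]
        pr = np.maximum(p1, 0.0)
        cache["plan_relu_mask"] = p1 > 0
        if drop:
            mask = (rng.random(pr.shape) < keep) / keep
            pr = pr * mask
            cache["plan_drop_mask"] = mask
        cache["plan_hidden"] = pr
        A = pr @ params["plan1.W"] + params["plan1.b"]
    else:
        A = Z

    cache["trunk_in"] = A
    t = A @ params["trunk.W"] + params["trunk.b"]
    tr = np.maximum(t, 0.0)
    cache["trunk_relu_mask"] = t > 0
    cache["trunk_hidden"] = tr

    mu = (tr @ params["mean.W"] + params["mean.b"]).ravel()
    if spec.has_variance_head:
        log_var = (tr @ params["logvar.W"] + params["logvar.b"]).ravel()
    else:
        log_var = None

    if not np.all(np.isfinite(mu)) or (
            log_var is not None and not np.all(np.isfinite(log_var))):
        raise FloatingPointError("non-finite activations in forecaster heads")

    if return_cache:
        return Z, A, mu, log_var, cache
    return Z, A, mu, log_var


def clamp_variance(log_var: np.ndarray, spec: ModelSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(sigma^2, pass-through-gradient mask) from raw log-variance."""
    lmin = math.log(spec.variance_floor)
    lmax = math.log(spec.variance_ceiling)
    clipped = np.clip(log_var, lmin, lmax)
    mask = (log_var > lmin) & (log_var < lmax)
    return np.exp(clipped), mask


# ---------------------------------------------------------------------------
# Backward
# ---------------------------------------------------------------------------

def backward(params: dict[str, np.ndarray], spec: ModelSpec, cache: dict,
             dmu: np.ndarray, dlog_var: np.ndarray | None,
             dA_extra: np.ndarray | None = None,
             dZ_extra: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every parameter.

    ``dmu``/``dlog_var`` are the loss gradients at the heads;
    ``dA_extra``/``dZ_extra`` inject gradients that attach directly to the
    action matrix (reward term) and the embedding (manifold term).
    """
    g: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in params.items()}
    tr = cache["trunk_hidden"]

    dmu = np.asarray(dmu, dtype=float).reshape(-1, 1)
    g["mean.W"] = tr.T @ dmu
    g["mean.b"] = dmu.sum(axis=0)
    dtr = dmu @ params["mean.W"].T
    if spec.has_variance_head and dlog_var is not None:
        dlv = np.asarray(dlog_var, dtype=float).reshape(-1, 1)
        g["logvar.W"] = tr.T @ dlv
        g["logvar.b"] = dlv.sum(axis=0)
        dtr = dtr + dlv @ params["logvar.W"].T

    dt = dtr * cache["trunk_relu_mask"]
    g["trunk.W"] = cache["trunk_in"].T @ dt
    g["trunk.b"] = dt.sum(axis=0)
    dA = dt @ params["trunk.W"].T
    if dA_extra is not None:
        dA = dA + dA_extra

    if spec.has_planner:
        g["plan1.W"] = cache["plan_hidden"].T @ dA
        g["plan1.b"] = dA.sum(axis=0)
        dpr = dA @ params["plan1.W"].T
        if cache["drop"]:
            dpr = dpr * cache["plan_drop_mask"]
        dp1 = dpr * cache["plan_relu_mask"]
        g["plan0.W"] = cache["plan_in"].T @ dp1
        g["plan0.b"] = dp1.sum(axis=0)
        dZ = dp1 @ params["plan0.W"].T
    else:
        dZ = dA

    if dZ_extra is not None:
        dZ = dZ + dZ_extra

    dh = dZ
    for i in reversed(range(len(spec.effective_encoder_dims))):
        blk = cache["blocks"][i]
        if cache["drop"]:
            dh = dh * blk["drop_mask"]
        dln = dh * blk["relu_mask"]
        da, dgamma, dbeta = _layer_norm_bwd(dln, params[f"enc{i}.g"],
                                            blk["xhat"], blk["std"])
        g[f"enc{i}.g"] = dgamma
        g[f"enc{i}.beta"] = dbeta
        g[f"enc{i}.W"] = blk["x_in"].T @ da
        g[f"enc{i}.b"] = da.sum(axis=0)
        dh = da @ params[f"enc{i}.W"].T

    g["embed.W"] = cache["X"].T @ dh
    g["embed.b"] = dh.sum(axis=0)
    return g


# ---------------------------------------------------------------------------
# Monte-Carlo-dropout prediction
# ---------------------------------------------------------------------------

def aggregate_mc_passes(mus: np.ndarray, sigma2s: np.ndarray,
                        keep_draws: bool = False) -> PredictiveOutput:
    """Decompose T stochastic passes into mean + variance components.

    mu = mean over passes; aleatoric = mean of per-pass sigma^2;
    epistemic = population variance (denominator T) of per-pass means;
    total = aleatoric + epistemic (law of total variance).
    """
    mus = np.atleast_2d(np.asarray(mus, dtype=float))
    sigma2s = np.atleast_2d(np.asarray(sigma2s, dtype=float))
    T = mus.shape[0]
    mu = mus.mean(axis=0)
    var_alea = sigma2s.mean(axis=0)
    var_epi = mus.var(axis=0)          # ddof=0: population variance over T
    # identical passes (e.g. dropout off) must give exactly zero, not
    # mean-subtraction roundoff
    var_epi = np.where(np.ptp(mus, axis=0) == 0.0, 0.0, var_epi)
    return PredictiveOutput(mu=mu, var_aleatoric=var_alea,
                            var_epistemic=var_epi,
                            var_total=var_alea + var_epi, T=T,
                            draws=mus if keep_draws else None)


def mc_predict(params: dict[str, np.ndarray], spec: ModelSpec, X: np.ndarray,
               T: int = 20, seed: int = 0,
               keep_draws: bool = False) -> PredictiveOutput:
    """T forward passes with dropout active; decomposed uncertainty."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not spec.has_variance_head:
        raise ValueError("variant without a variance head cannot produce "
                         "uncertainty estimates")
    rng = np.random.default_rng(seed)
    n = np.asarray(X).shape[0]
    scale = float(params.get("sigma_scale", 1.0))
    mus = np.empty((T, n))
    sig = np.empty((T, n))
    for t in range(T):
        _, _, mu, lv = forward(params, spec, X, train=spec.dropout_p > 0,
                               rng=rng)
        sigma2, _ = clamp_variance(lv, spec)
        mus[t] = mu
        sig[t] = scale * sigma2
    return aggregate_mc_passes(mus, sig, keep_draws=keep_draws)


def predict_mean_variance(params: dict[str, np.ndarray], spec: ModelSpec,
                          X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Single deterministic (dropout-off) pass."""
    _, _, mu, lv = forward(params, spec, X, train=False)
    if lv is None:
        return mu, None
    sigma2, _ = clamp_variance(lv, spec)
    return mu, float(params.get("sigma_scale", 1.0)) * sigma2


# ---------------------------------------------------------------------------
# Checkpointing: .npz blob + JSON sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, params: dict[str, np.ndarray],
                    spec: ModelSpec, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **params)
    sidecar = {"spec": spec.to_dict(), "meta": meta or {}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str | Path
                    ) -> tuple[dict[str, np.ndarray], ModelSpec, dict]:
    path = Path(path)
    blob = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    params = {k: blob[k] for k in blob.files}
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return params, ModelSpec.from_dict(sidecar["spec"]), sidecar["meta"]
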