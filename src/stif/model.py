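"""The spatiotemporal transformer forward pass.

Architecture: each variable (encoder) and each time position (decoder) is
one token; a learned linear embedding lifts the token scalar to
``value_width`` features (w = 8 by default) so the spatial Gram of the
transformation attention carries a full w x w summary of the encoder state.

encoder
    X_t (D,) --FFN(DxD)+ELU--> D tokens --continuous spatial
    self-attention--> residual + layer norm --> SSA (D, w)
decoder
    Ybar_t (L,) --FFN(LxL)+ELU--> L tokens --masked continuous temporal
    self-attention--> residual + layer norm --> TSA (L, w)
    --transformation attention TSA SSA' SSA / d_SSA--> residual + norm
    --ELU(W . + b)--> predicted window Yhat_t (L,)

"Continuous" attention is the elementwise exponential of the scaled
query-key product with NO softmax normalization; the classical softmax
form is kept as the ``stnn_star`` variant.  Two ablations replace either
attention block with a fully connected layer (``stnn_hash`` spatial,
``stnn_hashhash`` temporal).

All ops accept plain ndarrays (fast inference) or autodiff Tensors
(training); leading batch axes broadcast through every op.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import value_of
from .errors import DimensionError, NumericRangeError

__all__ = [
    "VARIANTS",
    "StnnConfig",
    "StnnParams",
    "AttentionTrace",
    "ffn_embed",
    "continuous_attention",
    "canonical_attention",
    "residual_norm",
    "transformation_attention",
    "build_mask",
    "stnn_forward",
    "init_params",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("stnn", "stnn_star", "stnn_hash", "stnn_hashhash")

#: logits above this are clipped before exponentiation; exp(50) ~ 5e21 stays
#: comfortably finite in float64 while preserving the ordering of weights
LOGIT_CLIP = 50.0


@dataclass(frozen=True)
class StnnConfig:
    """Hyperparameters of one model instance."""

    D: int
    L: int
    d_E: int = 32  # encoder query/key width
    d_D: int = 32  # decoder query/key width
    value_width: int = 8  # token feature width
    variant: str = "stnn"
    lambda_reg: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise DimensionError(f"unknown variant {self.variant!r}")
        if min(self.D, self.d_E, self.d_D, self.value_width) < 1 or self.L < 2:
            raise DimensionError("all widths must be positive and L >= 2")

    @property
    def d_M(self) -> int:
        """Mask dimension — always the embedded dimension L."""
        return self.L

    @property
    def d_SSA(self) -> int:
        """Transformation-attention scale: the token count D of SSA."""
        return self.D


#: parameter names -> shape builders, given a config
def _param_shapes(cfg: StnnConfig) -> dict[str, tuple[int, ...]]:
    d, l, w = cfg.D, cfg.L, cfg.value_width
    return {
        "W_FFN": (d, d),
        "b_FFN": (d,),
        "W_EQ": (w, cfg.d_E),
        "W_EK": (w, cfg.d_E),
        "W_EV": (w, w),
        "W_DFFN": (l, l),
        "b_DFFN": (l,),
        "W_DQ": (w, cfg.d_D),
        "W_DK": (w, cfg.d_D),
        "W_DV": (w, w),
        # scalar -> feature token embeddings (one per stream)
        "E_enc": (1, w),
        "b_Eenc": (w,),
        "E_dec": (1, w),
        "b_Edec": (w,),
        # head projection collapsing token features back to scalars
        "W_head": (w, 1),
        # fully connected stand-ins used by the ablation variants
        "W_SFC": (d, d),
        "b_SFC": (d,),
        "W_TFC": (l, l),
        "b_TFC": (l,),
        # layer-norm affine parameters at the three norm sites
        "enc_scale": (d, 1),
        "enc_shift": (d, 1),
        "dec_scale": (l, 1),
        "dec_shift": (l, 1),
        "out_scale": (l, 1),
        "out_shift": (l, 1),
        # output head
        "W_out": (l, l),
        "b_out": (l,),
    }


#: matrices included in the L2 penalty (weights, not biases or norm affines)
PENALIZED = (
    "W_FFN", "W_EQ", "W_EK", "W_EV", "W_DFFN", "W_DQ", "W_DK", "W_DV",
    "W_SFC", "W_TFC", "W_out", "E_enc", "E_dec", "W_head",
)


class StnnParams(dict):
    """Named parameter arrays (a dict with checkpoint helpers)."""

    def copy(self) -> "StnnParams":
        return StnnParams({k: np.array(value_of(v)) for k, v in self.items()})

    def as_tensors(self) -> "StnnParams":
        return StnnParams({k: ad.Tensor(np.array(value_of(v))) for k, v in self.items()})

    def values_only(self) -> "StnnParams":
        return StnnParams({k: value_of(v) for k, v in self.items()})


def init_params(config: StnnConfig) -> StnnParams:
    """Seeded Glorot-uniform weights, zero biases, identity norm affines."""
    rng = np.random.default_rng(config.seed)
    params = StnnParams()
    for name, shape in _param_shapes(config).items():
        if name.startswith("b_") or name.endswith("_shift"):
            params[name] = np.zeros(shape)
        elif name.endswith("_scale"):
            params[name] = np.ones(shape)
        else:
            fan_in, fan_out = shape[-1], shape[0]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            params[name] = rng.uniform(-limit, limit, size=shape)
    return params


@dataclass
class AttentionTrace:
    """Diagnostic record of one attention application."""

    weights: np.ndarray
    masked: bool


def ffn_embed(x, weight, bias):
    """ELU(weight @ x + bias) for x of shape (..., N)."""
    if value_of(weight).shape[1] != value_of(x).shape[-1]:
        raise DimensionError(
            f"FFN weight {value_of(weight).shape} incompatible with input "
            f"{value_of(x).shape}"
        )
    return ad.elu(ad.matmul(x, ad.swapaxes(weight, -1, -2)) + bias)


def _qkv(tokens, wq, wk, wv):
    q = ad.matmul(tokens, wq)
    k = ad.matmul(tokens, wk)
    v = ad.matmul(tokens, wv)
    return q, k, v


def continuous_attention(tokens, wq, wk, wv, scale_dim: int, mask=None, *,
                         literal_mask: bool = False, clip: float | None = LOGIT_CLIP):
    """Unnormalized exponential attention over (..., N, w) tokens.

    weights = exp(Q K' / scale_dim) — note the division by scale_dim itself,
    not its square root, and no softmax: attention strengths live on a
    continuous positive scale.  A binary mask zeroes excluded positions
    *after* the exponential so they contribute exactly nothing.
    ``literal_mask=True`` instead multiplies the logits by the mask before
    exponentiation (giving excluded positions weight 1); it exists only to
    demonstrate why that reading leaks future information.
    """
    if scale_dim < 1:
        raise DimensionError("scale_dim must be >= 1")
    q, k, v = _qkv(tokens, wq, wk, wv)
    logits = ad.matmul(q, ad.swapaxes(k, -1, -2)) / float(scale_dim)
    if mask is not None and literal_mask:
        logits = logits * np.asarray(mask, dtype=np.float64)
    if clip is not None:
        logits = ad.minimum_const(logits, clip)
    weights = ad.exp(logits)
    if not np.all(np.isfinite(value_of(weights))):
        raise NumericRangeError(
            f"attention overflow: max logit {np.max(value_of(logits)):.3g}"
        )
    if mask is not None and not literal_mask:
        weights = weights * np.asarray(mask, dtype=np.float64)
    out = ad.matmul(weights, v)
    return out, AttentionTrace(np.array(value_of(weights)), mask is not None)


def canonical_attention(tokens, wq, wk, wv, scale_dim: int, mask=None):
    """Classical softmax attention, sqrt(scale_dim) scaling, -inf masking."""
    if scale_dim < 1:
        raise DimensionError("scale_dim must be >= 1")
    q, k, v = _qkv(tokens, wq, wk, wv)
    logits = ad.matmul(q, ad.swapaxes(k, -1, -2)) / float(np.sqrt(scale_dim))
    if mask is not None:
        logits = ad.where_const(np.asarray(mask, dtype=bool), logits, -1e30)
    weights = ad.softmax(logits, axis=-1)
    out = ad.matmul(weights, v)
    return out, AttentionTrace(np.array(value_of(weights)), mask is not None)


def residual_norm(base, delta, scale=1.0, shift=0.0, eps: float = 1e-5):
    """Layer-normalize (base + delta) over the token axis, then affine map.

    base and delta have shape (..., N, w); normalization runs over the N
    tokens with population variance and an epsilon guard.
    """
    return ad.layer_norm(base + delta, -2, scale, shift, eps=eps)


def transformation_attention(tsa, ssa, d_ssa: int):
    """(1/d_ssa) * TSA SSA' SSA — the bridge from spatial to temporal info."""
    if value_of(tsa).shape[-1] != value_of(ssa).shape[-1]:
        raise DimensionError("tsa and ssa must share the value width")
    gram = ad.matmul(ad.swapaxes(ssa, -1, -2), ssa)
    return ad.matmul(tsa, gram) / float(d_ssa)


def build_mask(d_m: int) -> np.ndarray:
    """Lower-triangular causal mask (1 on and below the diagonal)."""
    if d_m < 1:
        raise DimensionError("mask dimension must be >= 1")
    return np.tri(d_m)


def _tokens(x, embed, bias):
    """(..., N) scalars -> (..., N, w) tokens via a learned linear embedding.

    Each position's scalar multiplies a shared feature direction; the bias
    gives every token a resting feature pattern.  With value_width > 1 the
    spatial Gram of the transformation attention becomes a full w x w
    matrix, which is what lets encoder information reach the decoder.
    """
    shp = value_of(x).shape
    return ad.matmul(ad.reshape(x, shp + (1,)), embed) + bias


def encode(x_state, params, config: StnnConfig):
    """Encoder: FFN + continuous spatial self-attention -> SSA (..., D, w)."""
    xf = ffn_embed(x_state, params["W_FFN"], params["b_FFN"])
    tokens = _tokens(xf, params["E_enc"], params["b_Eenc"])
    if config.variant == "stnn_hash":
        delta = _tokens(ffn_embed(xf, params["W_SFC"], params["b_SFC"]),
                        params["E_enc"], params["b_Eenc"])
    elif config.variant == "stnn_star":
        delta, _ = canonical_attention(
            tokens, params["W_EQ"], params["W_EK"], params["W_EV"], config.d_E
        )
    else:
        delta, _ = continuous_attention(
            tokens, params["W_EQ"], params["W_EK"], params["W_EV"], config.d_E
        )
    return residual_norm(tokens, delta, params["enc_scale"], params["enc_shift"])


def decode(ssa, decoder_input, params, config: StnnConfig):
    """Decoder: masked temporal attention + transformation attention + head."""
    yf = ffn_embed(decoder_input, params["W_DFFN"], params["b_DFFN"])
    tokens = _tokens(yf, params["E_dec"], params["b_Edec"])
    mask = build_mask(config.d_M)
    if config.variant == "stnn_hashhash":
        delta = _tokens(ffn_embed(yf, params["W_TFC"], params["b_TFC"]),
                        params["E_dec"], params["b_Edec"])
    elif config.variant == "stnn_star":
        delta, _ = canonical_attention(
            tokens, params["W_DQ"], params["W_DK"], params["W_DV"], config.d_D, mask
        )
    else:
        delta, _ = continuous_attention(
            tokens, params["W_DQ"], params["W_DK"], params["W_DV"], config.d_D, mask
        )
    tsa = residual_norm(tokens, delta, params["dec_scale"], params["dec_shift"])
    ta = transformation_attention(tsa, ssa, config.d_SSA)
    ta = residual_norm(tsa, ta, params["out_scale"], params["out_shift"])
    # collapse token features to scalars, then the output head of Eq-style
    # ELU(W . + b) over the L positions
    flat = ad.matmul(ta, params["W_head"])
    shp = value_of(flat).shape
    flat = ad.reshape(flat, shp[:-1])
    return ffn_embed(flat, params["W_out"], params["b_out"])


def stnn_forward(x_state, decoder_input, params, config: StnnConfig):
    """Full forward pass; accepts single samples (D,) / (L,) or batches."""
    xs = value_of(x_state)
    ds = value_of(decoder_input)
    if xs.shape[-1] != config.D or ds.shape[-1] != config.L:
        raise DimensionError(
            f"inputs {xs.shape}/{ds.shape} do not match D={config.D}, L={config.L}"
        )
    ssa = encode(x_state, params, config)
    return decode(ssa, decoder_input, params, config)


# ---- checkpointing -------------------------------------------------------

def save_checkpoint(path, params: StnnParams, config: StnnConfig) -> None:
    """Single zip archive: config.json + one .npy per parameter (bit-exact)."""
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr("config.json", json.dumps(asdict(config), indent=2))
        for name, arr in params.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(value_of(arr), dtype=np.float64))
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_checkpoint(path) -> tuple[StnnParams, StnnConfig]:
    path = Path(path)
    with zipfile.ZipFile(path, "r") as zf:
        config = StnnConfig(**json.loads(zf.read("config.json")))
        params = StnnParams()
        for info in zf.namelist():
            if info.startswith("params/") and info.endswith(".npy"):
                name = info[len("params/"):-len(".npy")]
                params[name] = np.load(io.BytesIO(zf.read(info)))
    return params, config
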