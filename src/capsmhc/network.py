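"""The predictive network: convolution-attention branches, capsule fusion
with dynamic routing, and the fully-connected binding-score head.

The two feature branches are pooling-free stacks of valid 1-D convolutions
with a position-wise attention unit in the middle; each maps its encoded
input (23 x 15 peptide, 23 x 385 MHC) to a 20 x 11 latent tensor.  The
two flattened latents form the two input capsules u_0, u_1 (dim 220).
Capsule fusion transforms them with learned matrices, u_hat_{j|i} = W_ij u_i,
combines the predictions by dynamic routing,

    s_j = sum_i c_ij u_hat_{j|i},      v_j = |s_j|^2/(1+|s_j|^2) * s_j/|s_j|,

with coupling coefficients c_ij the softmax (over output capsules j) of
agreement-updated logits b_ij, and feeds the output capsules to a
three-layer fully-connected head producing a binding score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._autodiff import (
    Tensor,
    as_tensor,
    concatenate,
    conv1d,
    einsum,
    glorot_uniform,
    softmax as _softmax_t,
)

LATENT_CHANNELS = 20
LATENT_POSITIONS = 11


class ConfigurationError(ValueError):
    pass


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class BranchConfig:
    """Geometry of one convolution-attention feature branch.

    ``conv_layers`` lists (out_channels, kernel_width, stride);
    ``attention_after`` is how many conv layers run before the attention
    unit.  The composed geometry must land on a 20 x 11 latent.
    """

    role: str  # "peptide" | "mhc"
    input_positions: int
    conv_layers: Tuple[Tuple[int, int, int], ...]
    attention_after: int
    input_channels: int = 23

    def __post_init__(self) -> None:
        if not 0 < self.attention_after < len(self.conv_layers):
            raise ConfigurationError(
                "attention unit must sit strictly between conv layers"
            )
        p = self.input_positions
        for ch, k, s in self.conv_layers:
            if p < k:
                raise GeometryError(
                    f"{self.role} branch: {p} positions < kernel width {k}"
                )
            p = (p - k) // s + 1
        ch_out = self.conv_layers[-1][0]
        if (ch_out, p) != (LATENT_CHANNELS, LATENT_POSITIONS):
            raise GeometryError(
                f"{self.role} branch maps to {ch_out} x {p}; the latent contract "
                f"is {LATENT_CHANNELS} x {LATENT_POSITIONS}"
            )


def default_peptide_branch() -> BranchConfig:
    # 15 -> 13 -> (attention) -> 12 -> 11 positions; wider early layers so
    # length-dependent C-terminal patterns have room to form
    return BranchConfig(
        role="peptide",
        input_positions=15,
        conv_layers=((32, 3, 1), (32, 2, 1), (20, 2, 1)),
        attention_after=1,
    )


def default_mhc_branch() -> BranchConfig:
    # 385 -> 77 -> 25 -> (attention) -> 12 -> 11 positions
    return BranchConfig(
        role="mhc",
        input_positions=385,
        conv_layers=((32, 5, 5), (32, 5, 3), (20, 3, 2), (20, 2, 1)),
        attention_after=2,
    )


@dataclass(frozen=True)
class CapsuleConfig:
    n_input_capsules: int = 2
    input_dim: int = LATENT_CHANNELS * LATENT_POSITIONS  # 220
    n_output_capsules: int = 16
    output_dim: int = 16
    routing_iterations: int = 3
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.n_output_capsules, self.output_dim, self.routing_iterations) < 1:
            raise ConfigurationError("capsule counts and routing iterations must be >= 1")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")


@dataclass(frozen=True)
class PredictorConfig:
    hidden_layers: Tuple[int, int, int] = (128, 64, 32)
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if len(self.hidden_layers) != 3:
            raise ConfigurationError("the predictor uses exactly three hidden layers")
        if self.output_activation not in ("sigmoid", "softmax", "tanh"):
            raise ConfigurationError(
                f"unknown output activation {self.output_activation!r}"
            )


@dataclass(frozen=True)
class RoutingState:
    """All capsule-layer quantities of one forward pass (numpy copies)."""

    u: np.ndarray  # (B, I, E) input capsule vectors
    W: np.ndarray  # (I, J, E, D) transform matrices
    u_hat: np.ndarray  # (B, I, J, D) transformed prediction vectors
    b: np.ndarray  # (B, I, J) final routing logits
    c: np.ndarray  # (B, I, J) coupling coefficients
    s: np.ndarray  # (B, J, D) pre-squash sums
    v: np.ndarray  # (B, J, D) output capsules


# ---------------------------------------------------------------------------
# capsule math


def squash(s, axis: int = -1, epsilon: float = 1e-8):
    """Capsule nonlinearity v = (|s|^2/(1+|s|^2)) * s/|s|.

    Stable at s = 0 (the norm in the direction factor is offset by
    ``epsilon``, giving v = 0).  Accepts a numpy array or a Tensor and
    returns the same kind.
    """
    is_np = not isinstance(s, Tensor)
    t = as_tensor(s)
    n2 = (t * t).sum(axis=axis, keepdims=True)
    norm = (n2 + 1e-30) ** 0.5
    out = t * (n2 / (1.0 + n2)) / (norm + epsilon)
    return out.data if is_np else out


def dynamic_routing(
    u_hat,
    iterations: int = 3,
    epsilon: float = 1e-8,
    return_state: bool = False,
):
    """Route prediction vectors to output capsules by iterative agreement.

    ``u_hat``: (B, I, J, D) (or (I, J, D), treated as batch 1).  Logits
    ``b`` start at zero; each iteration sets c = softmax_J(b), forms
    s_j = sum_i c_ij u_hat_{j|i}, squashes to v_j, then (except after the
    final iteration) updates b_ij += u_hat_{j|i} . v_j.  Returns (v, c)
    with c the couplings that produced the returned v; for every input
    capsule the couplings sum to 1 over output capsules.
    """
    if iterations < 1:
        raise ConfigurationError(f"routing iterations must be >= 1, got {iterations}")
    is_np = not isinstance(u_hat, Tensor)
    u = as_tensor(u_hat)
    squeeze = u.ndim == 3
    if squeeze:
        u = u.reshape((1,) + u.shape)
    if u.ndim != 4:
        raise GeometryError(f"u_hat must be (B, I, J, D), got shape {u.shape}")
    B, I, J, D = u.shape
    b = Tensor(np.zeros((B, I, J)))
    c = s = v = None
    for it in range(iterations):
        c = _softmax_t(b, axis=2)
        s = (c.reshape(B, I, J, 1) * u).sum(axis=1)
        v = squash(s, axis=-1, epsilon=epsilon)
        if it < iterations - 1:
            agreement = (u * v.reshape(B, 1, J, D)).sum(axis=-1)
            b = b + agreement
    if squeeze:
        v, c = v.reshape(J, D), c.reshape(I, J)
        b, s = b.reshape(I, J), s.reshape(J, D)
    if is_np:
        v_out, c_out = v.data, c.data
    else:
        v_out, c_out = v, c
    if return_state:
        return v_out, c_out, {"b": b, "s": s}
    return v_out, c_out


# ---------------------------------------------------------------------------
# layers


class Conv1DLayer:
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int):
        self.stride = stride
        fan_in, fan_out = in_ch * kernel, out_ch * kernel
        self.w = glorot_uniform(rng, (out_ch, in_ch, kernel), fan_in, fan_out)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, self.stride)

    def params(self) -> List[Tensor]:
        return [self.w, self.b]


class PositionAttention:
    """Position-wise attention: a learned linear map over channels scores
    each position; softmax over positions gives nonnegative weights summing
    to 1 per sample, which rescale the features."""

    def __init__(self, rng, channels: int):
        # zero score map -> exactly uniform attention at initialization, so
        # no position is starved of gradient before the map is learned
        self.w = Tensor(np.zeros(channels), requires_grad=True)
        self.b = Tensor(np.zeros(1), requires_grad=True)

    def weights(self, x: Tensor) -> Tensor:
        B, C, P = x.shape
        scores = (x * self.w.reshape(1, -1, 1)).sum(axis=1) + self.b  # (B, P)
        return _softmax_t(scores, axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, P = x.shape
        a = self.weights(x)
        return x * a.reshape(B, 1, P)

    def params(self) -> List[Tensor]:
        return [self.w, self.b]


class DenseLayer:
    def __init__(self, rng, in_dim: int, out_dim: int):
        self.w = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self) -> List[Tensor]:
        return [self.w, self.b]


class FeatureBranch:
    """Pooling-free conv stack with one attention unit; 23 x P -> 20 x 11."""

    def __init__(self, rng, config: BranchConfig):
        self.config = config
        self.layers: List[object] = []
        in_ch = config.input_channels
        for li, (out_ch, k, s) in enumerate(config.conv_layers):
            if li == config.attention_after:
                self.layers.append(PositionAttention(rng, in_ch))
            self.layers.append(Conv1DLayer(rng, in_ch, out_ch, k, s))
            in_ch = out_ch

    def __call__(self, x: Tensor) -> Tensor:
        B, C, P = x.shape
        if (C, P) != (self.config.input_channels, self.config.input_positions):
            raise GeometryError(
                f"{self.config.role} branch expects input "
                f"{self.config.input_channels} x {self.config.input_positions}, "
                f"got {C} x {P}"
            )
        for layer in self.layers:
            x = layer(x)
            if isinstance(layer, Conv1DLayer):
                x = x.relu()
        return x

    def params(self) -> List[Tensor]:
        return [p for layer in self.layers for p in layer.params()]


class CapsuleFusion:
    """Two primary capsules (flattened branch latents) fused into J output
    capsules via learned transforms and dynamic routing."""

    def __init__(self, rng, config: CapsuleConfig):
        self.config = config
        I, J = config.n_input_capsules, config.n_output_capsules
        E, D = config.input_dim, config.output_dim
        self.W = glorot_uniform(rng, (I, J, E, D), E, D)

    def __call__(
        self, u: Tensor, routing: bool = True, capture: bool = False
    ) -> Tuple[Tensor, Optional[RoutingState]]:
        cfg = self.config
        B = u.shape[0]
        if u.shape[1:] != (cfg.n_input_capsules, cfg.input_dim):
            raise GeometryError(
                f"capsule input must be (B, {cfg.n_input_capsules}, {cfg.input_dim}),"
                f" got {u.shape}"
            )
        u_hat = einsum("bie,ijed->bijd", u, self.W)
        iters = cfg.routing_iterations if routing else 1
        v, c, extra = dynamic_routing(
            u_hat, iterations=iters, epsilon=cfg.epsilon, return_state=True
        )
        state = None
        if capture:
            state = RoutingState(
                u=u.data.copy(),
                W=self.W.data.copy(),
                u_hat=u_hat.data.copy(),
                b=extra["b"].data.copy(),
                c=c.data.copy(),
                s=extra["s"].data.copy(),
                v=v.data.copy(),
            )
        return v, state

    def params(self) -> List[Tensor]:
        return [self.W]


class PredictorHead:
    """Three fully-connected layers then the output layer."""

    def __init__(self, rng, in_dim: int, config: PredictorConfig):
        self.config = config
        self.layers: List[DenseLayer] = []
        d = in_dim
        for h in config.hidden_layers:
            self.layers.append(DenseLayer(rng, d, h))
            d = h
        out_units = 2 if config.output_activation == "softmax" else 1
        self.out = DenseLayer(rng, d, out_units)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
        z = self.out(x)
        act = self.config.output_activation
        if act == "sigmoid":
            return z.sigmoid().reshape(z.shape[0])
        if act == "tanh":
            # map (-1, 1) -> (0, 1) so every activation shares the scoring range
            return (z.tanh().reshape(z.shape[0]) + 1.0) * 0.5
        probs = _softmax_t(z, axis=1)
        return probs[:, 1]

    def params(self) -> List[Tensor]:
        return [p for layer in self.layers for p in layer.params()] + self.out.params()


# ---------------------------------------------------------------------------
# assembled model


@dataclass(frozen=True)
class NetworkConfig:
    peptide_branch: BranchConfig = field(default_factory=default_peptide_branch)
    mhc_branch: BranchConfig = field(default_factory=default_mhc_branch)
    capsule: CapsuleConfig = field(default_factory=CapsuleConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    fusion: str = "capsule"  # "capsule" | "concat" | "conv"
    routing: bool = True  # False -> uniform couplings throughout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion not in ("capsule", "concat", "conv"):
            raise ConfigurationError(f"unknown fusion mode {self.fusion!r}")


class CapsNetCore:
    """The assembled forward graph over already-encoded batches."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.peptide_branch = FeatureBranch(rng, config.peptide_branch)
        self.mhc_branch = FeatureBranch(rng, config.mhc_branch)
        flat = LATENT_CHANNELS * LATENT_POSITIONS
        self.fusion_conv: Optional[Conv1DLayer] = None
        self.capsules: Optional[CapsuleFusion] = None
        if config.fusion == "capsule":
            self.capsules = CapsuleFusion(rng, config.capsule)
            head_in = config.capsule.n_output_capsules * config.capsule.output_dim
        elif config.fusion == "concat":
            head_in = 2 * flat
        else:  # conv fusion baseline: conv over the position-concatenated latents
            self.fusion_conv = Conv1DLayer(rng, LATENT_CHANNELS, LATENT_CHANNELS, 3, 1)
            head_in = LATENT_CHANNELS * (2 * LATENT_POSITIONS - 2)
        self.head = PredictorHead(rng, head_in, config.predictor)

    # -- forward ----------------------------------------------------------
    def latents(self, pep, mhc) -> Tuple[Tensor, Tensor]:
        pep_lat = self.peptide_branch(as_tensor(pep))
        mhc_lat = self.mhc_branch(as_tensor(mhc))
        if pep_lat.shape[0] != mhc_lat.shape[0]:
            raise GeometryError(
                f"batch mismatch: {pep_lat.shape[0]} peptides vs "
                f"{mhc_lat.shape[0]} MHC encodings"
            )
        return pep_lat, mhc_lat

    def forward(
        self, pep, mhc, capture: bool = False
    ) -> Tuple[Tensor, Dict[str, np.ndarray]]:
        """Score a batch; ``capture`` additionally returns fusion internals."""
        pep_lat, mhc_lat = self.latents(pep, mhc)
        B = pep_lat.shape[0]
        flat = LATENT_CHANNELS * LATENT_POSITIONS
        captured: Dict[str, np.ndarray] = {}
        if capture:
            captured["peptide_latent"] = pep_lat.data.copy()
            captured["mhc_latent"] = mhc_lat.data.copy()
        if self.config.fusion == "capsule":
            u = concatenate(
                [pep_lat.reshape(B, 1, flat), mhc_lat.reshape(B, 1, flat)], axis=1
            )
            v, state = self.capsules(u, routing=self.config.routing, capture=capture)
            if capture:
                captured["routing_state"] = state
            cfg = self.config.capsule
            x = v.reshape(B, cfg.n_output_capsules * cfg.output_dim)
        elif self.config.fusion == "concat":
            x = concatenate([pep_lat.reshape(B, flat), mhc_lat.reshape(B, flat)], axis=1)
            if capture:
                captured["concat_latent"] = x.data.copy()
        else:
            joint = concatenate([pep_lat, mhc_lat], axis=2)  # (B, 20, 22)
            fmap = self.fusion_conv(joint).relu()  # (B, 20, 20)
            if capture:
                captured["conv_feature_map"] = fmap.data.copy()
            x = fmap.reshape(B, fmap.shape[1] * fmap.shape[2])
        scores = self.head(x)
        return scores, captured

    def predict_scores(self, pep, mhc) -> np.ndarray:
        scores, _ = self.forward(pep, mhc)
        return scores.data

    # -- introspection ----------------------------------------------------
    def params(self) -> List[Tensor]:
        out = self.peptide_branch.params() + self.mhc_branch.params()
        if self.capsules is not None:
            out += self.capsules.params()
        if self.fusion_conv is not None:
            out += self.fusion_conv.params()
        return out + self.head.params()

    def layer_types(self) -> List[str]:
        layers: List[object] = list(self.peptide_branch.layers) + list(
            self.mhc_branch.layers
        )
        if self.capsules is not None:
            layers.append(self.capsules)
        if self.fusion_conv is not None:
            layers.append(self.fusion_conv)
        layers += list(self.head.layers) + [self.head.out]
        return [type(layer).__name__ for layer in layers]

    def set_all_weights(self, value: float = 0.0) -> None:
        for p in self.params():
            p.data[...] = value

    def state_arrays(self) -> Dict[str, np.ndarray]:
        return {f"param_{i}": p.data for i, p in enumerate(self.params())}

    def load_state_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            src = np.asarray(arrays[f"param_{i}"])
            if src.shape != p.data.shape:
                raise GeometryError(
                    f"checkpoint parameter {i} has shape {src.shape}, "
                    f"model expects {p.data.shape}"
                )
            p.data[...] = src


def assert_pooling_free(core: CapsNetCore) -> None:
    """Structural check that no pooling operation exists in the graph."""
    offenders = [t for t in core.layer_types() if "pool" in t.lower()]
    if offenders:
        raise AssertionError(f"pooling layers found in graph: {offenders}")
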