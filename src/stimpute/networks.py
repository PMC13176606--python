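"""The eight networks: two autoencoders, two latent translators, two discriminators.

Architecture (fixed across datasets):

* ST encoder: input -> 2048 -> 1024 -> 512 -> latent 256
* SC encoder: input -> 2048 -> 1024 -> 512 -> latent 512
* decoders mirror with hidden 512 -> 1024 -> 2048 -> input
* translator ST->SC: 256 -> [512, 512, 512, 1024, 1024] -> 512
* translator SC->ST: 512 -> [512, 256, 256, 128, 128] -> 256
* discriminators: latent -> [256, 128, 128, 64] -> 1 raw score

Hidden blocks are linear -> batch norm -> LeakyReLU(0.01) -> dropout(0.2);
output layers are linear with no normalization, activation, or dropout.
Decoder outputs are clamped at zero only at inference time, never inside a
loss, so gradients are not zeroed during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data import ExpressionMatrix, ValidationError
from .nn import MLP

LATENT_ST = 256
LATENT_SC = 512
ENCODER_HIDDEN = [2048, 1024, 512]
DECODER_HIDDEN = [512, 1024, 2048]
TRANS_ST2SC_HIDDEN = [512, 512, 512, 1024, 1024]
TRANS_SC2ST_HIDDEN = [512, 256, 256, 128, 128]
DISC_HIDDEN = [256, 128, 128, 64]

Domain = Literal["ST", "SC"]

_NET_NAMES = (
    "enc_st", "dec_st", "enc_sc", "dec_sc",
    "trans_st2sc", "trans_sc2st", "disc_st", "disc_sc",
)


@dataclass
class NetworkSpec:
    """Dimensions and regularization of one MLP."""

    in_dim: int
    hidden_dims: list[int]
    out_dim: int
    dropout_p: float = 0.2

    def __post_init__(self) -> None:
        if self.in_dim < 1 or self.out_dim < 1 or any(h < 1 for h in self.hidden_dims):
            raise ValidationError("all network dimensions must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValidationError("dropout_p must be in [0, 1)")

    def parameter_count(self) -> int:
        """Closed-form parameter count: linear weights + biases + 2 norm params per hidden unit."""
        dims = [self.in_dim] + list(self.hidden_dims) + [self.out_dim]
        linear = sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))
        norm = 2 * sum(self.hidden_dims)
        return linear + norm


@dataclass
class LatentEmbedding:
    """Per-cell latent vectors tagged with their domain and how they were produced."""

    vectors: np.ndarray
    domain: Domain
    provenance: Literal["encoded", "translated", "cycled"] = "encoded"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        expected = LATENT_ST if self.domain == "ST" else LATENT_SC
        if self.vectors.ndim != 2 or self.vectors.shape[1] != expected:
            raise ValidationError(
                f"{self.domain} embedding must have {expected} columns, "
                f"got shape {self.vectors.shape}"
            )


@dataclass
class ModelBundle:
    """All eight networks plus the configuration that produced them."""

    enc_st: MLP
    dec_st: MLP
    enc_sc: MLP
    dec_sc: MLP
    trans_st2sc: MLP
    trans_sc2st: MLP
    disc_st: MLP
    disc_sc: MLP
    config: dict = field(default_factory=dict)
    frozen_autoencoders: bool = False

    @property
    def st_in_dim(self) -> int:
        return self.enc_st.in_dim

    @property
    def sc_in_dim(self) -> int:
        return self.enc_sc.in_dim

    def networks(self) -> dict[str, MLP]:
        return {name: getattr(self, name) for name in _NET_NAMES}

    def state_arrays(self):
        arrays: dict[str, np.ndarray] = {}
        for name, net in self.networks().items():
            arrays.update(net.state_arrays(name))
        meta = {
            "config": self.config,
            "frozen_autoencoders": self.frozen_autoencoders,
            "st_in_dim": self.st_in_dim,
            "sc_in_dim": self.sc_in_dim,
            "dims": {
                name: {"in": net.in_dim, "hidden": net.hidden_dims, "out": net.out_dim}
                for name, net in self.networks().items()
            },
        }
        return arrays, meta

    @classmethod
    def from_state_arrays(cls, arrays, meta) -> "ModelBundle":
        bundle = build_bundle(meta["st_in_dim"], meta["sc_in_dim"], seed=0)
        bundle.config = meta.get("config", {})
        bundle.frozen_autoencoders = meta.get("frozen_autoencoders", False)
        for name, net in bundle.networks().items():
            net.load_state_arrays(name, arrays)
        if bundle.frozen_autoencoders:
            for name in ("enc_st", "dec_st", "enc_sc", "dec_sc"):
                getattr(bundle, name).trainable = False
        return bundle


def build_bundle(
    st_in_dim: int,
    sc_in_dim: int,
    seed: int,
    dropout_p: float = 0.2,
    dtype=np.float32,
) -> ModelBundle:
    """Construct the eight networks with reproducible seeded initialization."""
    if st_in_dim < 1 or sc_in_dim < 1:
        raise ValidationError("input dimensions must be >= 1")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    specs = bundle_specs(st_in_dim, sc_in_dim, dropout_p)
    nets = {
        name: MLP(sp.in_dim, sp.hidden_dims, sp.out_dim, rng, dropout_p=sp.dropout_p, dtype=dtype)
        for (name, sp), rng in zip(specs.items(), rngs)
    }
    return ModelBundle(
        **nets,
        config={"seed": int(seed), "dropout_p": dropout_p,
                "st_in_dim": int(st_in_dim), "sc_in_dim": int(sc_in_dim)},
    )


def bundle_specs(st_in_dim: int, sc_in_dim: int, dropout_p: float = 0.2) -> dict[str, NetworkSpec]:
    """The fixed layer widths of all eight networks, keyed by network name."""
    return {
        "enc_st": NetworkSpec(st_in_dim, list(ENCODER_HIDDEN), LATENT_ST, dropout_p),
        "dec_st": NetworkSpec(LATENT_ST, list(DECODER_HIDDEN), st_in_dim, dropout_p),
        "enc_sc": NetworkSpec(sc_in_dim, list(ENCODER_HIDDEN), LATENT_SC, dropout_p),
        "dec_sc": NetworkSpec(LATENT_SC, list(DECODER_HIDDEN), sc_in_dim, dropout_p),
        "trans_st2sc": NetworkSpec(LATENT_ST, list(TRANS_ST2SC_HIDDEN), LATENT_SC, dropout_p),
        "trans_sc2st": NetworkSpec(LATENT_SC, list(TRANS_SC2ST_HIDDEN), LATENT_ST, dropout_p),
        "disc_st": NetworkSpec(LATENT_ST, list(DISC_HIDDEN), 1, dropout_p),
        "disc_sc": NetworkSpec(LATENT_SC, list(DISC_HIDDEN), 1, dropout_p),
    }


def _as_array(x, expected_dim: int, what: str) -> np.ndarray:
    if isinstance(x, ExpressionMatrix):
        if x.stage != "normalized":
            raise ValidationError(f"{what} expects a normalized matrix, got stage={x.stage!r}")
        x = x.values
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[1] != expected_dim:
        raise ValidationError(f"{what} expects shape (*, {expected_dim}), got {x.shape}")
    return x


def encode(bundle: ModelBundle, x, domain: Domain) -> LatentEmbedding:
    """Deterministic eval-mode encoding of expression into the domain's latent space."""
    enc = bundle.enc_st if domain == "ST" else bundle.enc_sc
    arr = _as_array(x, enc.in_dim, f"{domain} encoder")
    return LatentEmbedding(enc(arr, training=False), domain=domain, provenance="encoded")


def decode(bundle: ModelBundle, z: LatentEmbedding, domain: Domain, clamp: bool = True) -> np.ndarray:
    """Eval-mode decoding back to the domain's gene space; floored at 0 at inference."""
    dec = bundle.dec_st if domain == "ST" else bundle.dec_sc
    if z.domain != domain:
        raise ValidationError(f"cannot decode a {z.domain} embedding with the {domain} decoder")
    out = dec(np.asarray(z.vectors), training=False)
    return np.maximum(out, 0.0) if clamp else out


def translate(bundle: ModelBundle, z: LatentEmbedding, direction: str) -> LatentEmbedding:
    """Eval-mode latent translation; flips the domain tag and tracks provenance."""
    if direction not in ("ST2SC", "SC2ST"):
        raise ValidationError(f"unknown direction {direction!r}")
    src, dst = ("ST", "SC") if direction == "ST2SC" else ("SC", "ST")
    if z.domain != src:
        raise ValidationError(f"direction {direction} requires a {src} embedding, got {z.domain}")
    net = bundle.trans_st2sc if direction == "ST2SC" else bundle.trans_sc2st
    provenance = "cycled" if z.provenance == "translated" else "translated"
    return LatentEmbedding(net(np.asarray(z.vectors), training=False), domain=dst,
                           provenance=provenance)


def discriminate(bundle: ModelBundle, z: LatentEmbedding, domain: Domain) -> np.ndarray:
    """Eval-mode discriminator scores: one unbounded real per cell."""
    if z.domain != domain:
        raise ValidationError(f"{domain} discriminator expects a {domain} embedding")
    disc = bundle.disc_st if domain == "ST" else bundle.disc_sc
    return disc(np.asarray(z.vectors), training=False)[:, 0]
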