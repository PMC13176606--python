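"""Training objectives: reconstruction, cycle, identity, adversarial and hinge losses.

The translator objective is a weighted sum

    L_trans = lambda_id * L_id + lambda_cyc * L_cyc + lambda_gan * L_gan

with defaults (1, 1, 0.1). The identity loss is one minus the per-cell
Pearson correlation between translated-then-decoded expression and the
source cell's expression, restricted to shared genes; the cycle loss is the
MSE of expression reconstructed after a latent round trip; discriminators
train on a margin (hinge) loss over raw scores.

Functions here are pure array computations (plus eval-mode convenience
wrappers over a ModelBundle); the training loop in ``training`` wires their
analytic gradients through the network caches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SharedGeneMap, ValidationError
from .networks import LatentEmbedding, ModelBundle


@dataclass
class LossWeights:
    lambda_id: float = 1.0
    lambda_cyc: float = 1.0
    lambda_gan: float = 0.1

    def __post_init__(self) -> None:
        if min(self.lambda_id, self.lambda_cyc, self.lambda_gan) < 0:
            raise ValidationError("loss weights must be >= 0")


@dataclass
class LossBreakdown:
    recon_st: float = 0.0
    recon_sc: float = 0.0
    cycle: float = 0.0
    identity: float = 0.0
    gan_translator: float = 0.0
    hinge_discriminator: float = 0.0
    total_translator: float = 0.0


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error over all entries."""
    x, x_hat = np.asarray(x), np.asarray(x_hat)
    if x.shape != x_hat.shape:
        raise ValidationError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def mse_grad(x_hat: np.ndarray, x: np.ndarray) -> np.ndarray:
    """d MSE(x_hat, x) / d x_hat."""
    return 2.0 * (x_hat - x) / x.size


def pearson_rows(a: np.ndarray, b: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with the matching row of ``b``.

    Rows where either vector has zero variance get correlation 0 (degenerate
    constant outputs are penalized, never NaN).
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac**2).sum(axis=1))
    nb = np.sqrt((bc**2).sum(axis=1))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ac * bc).sum(axis=1) / denom
    return np.where(denom > eps, rho, 0.0)


def pearson_rows_grad(a: np.ndarray, b: np.ndarray, eps: float = 1e-12):
    """Per-row Pearson rho(a_i, b_i) and its gradient with respect to ``a``.

    Gradient of rho w.r.t. a row a: (b_c / (|a_c||b_c|)) - rho * a_c / |a_c|^2,
    where subscript c denotes centering; both terms are mean-free so the
    centering projection is already absorbed. Zero-variance rows get rho 0
    and zero gradient.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac**2).sum(axis=1, keepdims=True))
    nb = np.sqrt((bc**2).sum(axis=1, keepdims=True))
    ok = (na > eps) & (nb > eps)
    na_s = np.where(ok, na, 1.0)
    nb_s = np.where(ok, nb, 1.0)
    rho = np.where(ok[:, 0], ((ac * bc).sum(axis=1, keepdims=True) / (na_s * nb_s))[:, 0], 0.0)
    grad = bc / (na_s * nb_s) - rho[:, None] * ac / na_s**2
    grad = np.where(ok, grad, 0.0)
    return rho, grad


def identity_loss_from_decoded(
    decoded_st2sc: np.ndarray,
    x_st: np.ndarray,
    decoded_sc2st: np.ndarray,
    x_sc: np.ndarray,
    shared: SharedGeneMap,
) -> float:
    """Identity loss given already-decoded cross-domain expression.

    ``decoded_st2sc`` lives in the SC gene space (one row per ST cell) and is
    compared against the ST cells' measured shared genes; symmetrically for
    the other direction. Only shared-gene columns enter the computation, so
    the gradient with respect to every non-shared column is exactly zero.
    """
    if len(shared) == 0:
        raise ValidationError("identity loss requires shared genes")
    rho_st = pearson_rows(decoded_st2sc[:, shared.sc_indices], x_st[:, shared.st_indices])
    rho_sc = pearson_rows(decoded_sc2st[:, shared.st_indices], x_sc[:, shared.sc_indices])
    return float((1.0 - rho_st.mean()) + (1.0 - rho_sc.mean()))


def identity_loss(bundle: ModelBundle, x_st, x_sc, shared: SharedGeneMap) -> float:
    """Eval-mode identity loss: encode, translate, decode, correlate on shared genes."""
    from . import networks as N

    x_st, x_sc = np.asarray(x_st), np.asarray(x_sc)
    z_st = N.encode(bundle, x_st, "ST")
    z_sc = N.encode(bundle, x_sc, "SC")
    dec_st2sc = N.decode(bundle, N.translate(bundle, z_st, "ST2SC"), "SC", clamp=False)
    dec_sc2st = N.decode(bundle, N.translate(bundle, z_sc, "SC2ST"), "ST", clamp=False)
    return identity_loss_from_decoded(dec_st2sc, x_st, dec_sc2st, x_sc, shared)


def cycle_loss(bundle: ModelBundle, x_st, x_sc) -> float:
    """Eval-mode cycle loss: MSE after translating to the other latent space and back."""
    from . import networks as N

    x_st, x_sc = np.asarray(x_st), np.asarray(x_sc)
    z_st = N.encode(bundle, x_st, "ST")
    z_sc = N.encode(bundle, x_sc, "SC")
    x_st_cyc = N.decode(
        bundle, N.translate(bundle, N.translate(bundle, z_st, "ST2SC"), "SC2ST"), "ST", clamp=False
    )
    x_sc_cyc = N.decode(
        bundle, N.translate(bundle, N.translate(bundle, z_sc, "SC2ST"), "ST2SC"), "SC", clamp=False
    )
    return reconstruction_loss(x_st_cyc, x_st) + reconstruction_loss(x_sc_cyc, x_sc)


def translator_gan_loss(bundle: ModelBundle, z_st: LatentEmbedding, z_sc: LatentEmbedding) -> float:
    """Adversarial translator loss: negated mean discriminator scores of translated embeddings."""
    from . import networks as N

    fake_st = N.translate(bundle, z_sc, "SC2ST")
    fake_sc = N.translate(bundle, z_st, "ST2SC")
    return float(
        -N.discriminate(bundle, fake_st, "ST").mean() - N.discriminate(bundle, fake_sc, "SC").mean()
    )


def hinge_real(scores: np.ndarray) -> float:
    """mean(max(0, 1 - score)) — real embeddings should score above +1."""
    return float(np.maximum(0.0, 1.0 - scores).mean())


def hinge_fake(scores: np.ndarray) -> float:
    """mean(max(0, 1 + score)) — translated embeddings should score below -1."""
    return float(np.maximum(0.0, 1.0 + scores).mean())


def hinge_real_grad(scores: np.ndarray) -> np.ndarray:
    return np.where(scores < 1.0, -1.0, 0.0) / scores.size


def hinge_fake_grad(scores: np.ndarray) -> np.ndarray:
    return np.where(scores > -1.0, 1.0, 0.0) / scores.size


def discriminator_hinge_loss(bundle: ModelBundle, z_st: LatentEmbedding, z_sc: LatentEmbedding) -> float:
    """Eval-mode hinge loss over both domains; translated embeddings are constants here."""
    from . import networks as N

    fake_st = N.translate(bundle, z_sc, "SC2ST")
    fake_sc = N.translate(bundle, z_st, "ST2SC")
    return (
        hinge_real(N.discriminate(bundle, z_st, "ST"))
        + hinge_fake(N.discriminate(bundle, fake_st, "ST"))
        + hinge_real(N.discriminate(bundle, z_sc, "SC"))
        + hinge_fake(N.discriminate(bundle, fake_sc, "SC"))
    )


def total_translator_loss(parts: LossBreakdown, w: LossWeights | None = None) -> float:
    """Weighted combination of identity, cycle, and adversarial terms."""
    w = w or LossWeights()
    return w.lambda_id * parts.identity + w.lambda_cyc * parts.cycle + w.lambda_gan * parts.gan_translator
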