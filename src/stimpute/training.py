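"""Two-stage training and the imputation inference path.

Stage 1 pretrains the two autoencoders independently on their own domain's
reconstruction loss. Stage 2 freezes them and trains the translators (cycle +
identity + adversarial terms) against discriminators updated on a hinge loss,
alternating one discriminator step and one translator step per batch.

Gradients are wired explicitly through the network caches from ``stimpute.nn``:
frozen networks contribute input gradients only, and translated embeddings are
treated as constants inside the discriminator loss, so the stage separation
contracts (no encoder/decoder drift, no translator gradient from the
discriminator update) hold by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .data import ExpressionMatrix, PairedDataset, ValidationError
from .networks import LatentEmbedding, ModelBundle
from .nn import MLP, Adam
from .objectives import (
    LossWeights,
    hinge_fake,
    hinge_fake_grad,
    hinge_real,
    hinge_real_grad,
    mse_grad,
    pearson_rows_grad,
    reconstruction_loss,
)

logger = logging.getLogger("stimpute")


class LeakageError(RuntimeError):
    """A held-out gene reached a training tensor."""


@dataclass
class TrainingConfig:
    """Optimization hyperparameters for both training stages."""

    ae_epochs: int = 100
    trans_epochs: int = 50
    batch_size: int = 512
    ae_lr: float = 1e-3
    trans_lr: float = 1e-3
    disc_lr: float = 5e-4
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ae_epochs < 1 or self.trans_epochs < 1:
            raise ValidationError("epoch counts must be >= 1")
        if self.batch_size < 2:
            raise ValidationError("batch_size must be >= 2 (batch statistics)")
        if min(self.ae_lr, self.trans_lr, self.disc_lr) <= 0:
            raise ValidationError("learning rates must be > 0")


@dataclass
class TrainingTrace:
    """Per-epoch loss records plus bookkeeping for audits and reproducibility."""

    records: list[dict] = field(default_factory=list)
    initial: dict = field(default_factory=dict)
    audit: list = field(default_factory=list)

    def extend(self, other: "TrainingTrace") -> "TrainingTrace":
        self.records.extend(other.records)
        self.initial.update(other.initial)
        self.audit.extend(other.audit)
        return self


class _Sampler:
    """Shuffled cycling batch sampler; never yields a batch smaller than 2."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.bs = batch_size
        self.rng = rng
        self._perm = rng.permutation(n)
        self._ptr = 0

    def next(self) -> np.ndarray:
        if self.n - self._ptr < 2:
            self._perm = self.rng.permutation(self.n)
            self._ptr = 0
        take = min(self.bs, self.n - self._ptr)
        idx = self._perm[self._ptr : self._ptr + take]
        self._ptr += take
        return idx


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator) -> Iterable[np.ndarray]:
    """One full shuffled pass; partial batches kept unless of size 1."""
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = perm[start : start + batch_size]
        if idx.size >= 2:
            yield idx


def _check_finite(value: float, stage: str, epoch: int, batch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in {stage} at epoch {epoch}, batch {batch}")


def _guard_genes(m: ExpressionMatrix, forbidden: Optional[Sequence[str]], where: str) -> None:
    if forbidden:
        hit = set(m.gene_names) & set(forbidden)
        if hit:
            raise LeakageError(f"held-out gene(s) {sorted(hit)[:5]} present in {where}")


def _train_autoencoder(
    enc: MLP,
    dec: MLP,
    values: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int,
    seed: int,
    tag: str,
) -> tuple[list[float], float]:
    """Minimize MSE(dec(enc(x)), x) with Adam; returns per-epoch mean losses."""
    rng_batch = np.random.default_rng(seed)
    rng_drop = np.random.default_rng(seed + 1)
    x_all = np.ascontiguousarray(values, dtype=enc.dtype)
    initial = reconstruction_loss(dec(enc(x_all)), x_all)
    opt = Adam([enc, dec], lr=lr)
    per_epoch: list[float] = []
    for epoch in range(epochs):
        losses = []
        for b, idx in enumerate(_epoch_batches(x_all.shape[0], batch_size, rng_batch)):
            x = x_all[idx]
            z, c_enc = enc.forward(x, training=True, rng=rng_drop)
            xh, c_dec = dec.forward(z, training=True, rng=rng_drop)
            loss = reconstruction_loss(xh, x)
            _check_finite(loss, f"autoencoder[{tag}]", epoch, b)
            enc.zero_grad()
            dec.zero_grad()
            gz = dec.backward(c_dec, mse_grad(xh, x))
            enc.backward(c_enc, gz)
            opt.step()
            losses.append(loss)
        per_epoch.append(float(np.mean(losses)))
    return per_epoch, float(initial)


def pretrain_autoencoders(
    bundle: ModelBundle,
    data: PairedDataset,
    cfg: TrainingConfig,
    forbidden_genes: Optional[Sequence[str]] = None,
    skip_sc: bool = False,
) -> TrainingTrace:
    """Stage 1: train each domain's autoencoder on its own data only.

    ``skip_sc`` supports reusing an SC autoencoder trained elsewhere (the SC
    matrix does not change across gene-holdout folds).
    """
    _guard_genes(data.st, forbidden_genes, "stage-1 ST input")
    if data.st.n_genes != bundle.st_in_dim or data.sc.n_genes != bundle.sc_in_dim:
        raise ValidationError("bundle input dimensions do not match the data")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in ss.generate_state(2) % (2**31 - 2)]
    trace = TrainingTrace()
    st_losses, st_init = _train_autoencoder(
        bundle.enc_st, bundle.dec_st, data.st.values, cfg.ae_epochs, cfg.ae_lr,
        cfg.batch_size, seeds[0], "ST",
    )
    trace.initial["recon_st"] = st_init
    if skip_sc:
        sc_losses = [float("nan")] * cfg.ae_epochs
    else:
        sc_losses, sc_init = _train_autoencoder(
            bundle.enc_sc, bundle.dec_sc, data.sc.values, cfg.ae_epochs, cfg.ae_lr,
            cfg.batch_size, seeds[1], "SC",
        )
        trace.initial["recon_sc"] = sc_init
    for e in range(cfg.ae_epochs):
        trace.records.append(
            {"stage": "ae", "epoch": e, "recon_st": st_losses[e], "recon_sc": sc_losses[e]}
        )
    trace.audit.append(("ae", tuple(data.st.gene_names)))
    return trace


def freeze_autoencoders(bundle: ModelBundle) -> ModelBundle:
    """Flag all encoder/decoder parameters non-trainable for stage 2."""
    for name in ("enc_st", "dec_st", "enc_sc", "dec_sc"):
        getattr(bundle, name).trainable = False
    bundle.frozen_autoencoders = True
    return bundle


def train_translators(
    bundle: ModelBundle,
    data: PairedDataset,
    cfg: TrainingConfig,
    forbidden_genes: Optional[Sequence[str]] = None,
    epoch_callback: Optional[Callable[[ModelBundle, int], dict]] = None,
) -> TrainingTrace:
    """Stage 2: adversarial translator training with frozen autoencoders.

    Per step: one discriminator update on the hinge loss (translated
    embeddings detached), then one translator update on the weighted
    identity + cycle + adversarial objective. An epoch is
    ceil(max(n_ST, n_SC) / batch) steps, cycling the smaller domain.
    """
    if not bundle.frozen_autoencoders:
        raise ValidationError("freeze_autoencoders must run before translator training")
    if len(data.shared) == 0:
        raise ValidationError("translator training requires shared genes (identity loss)")
    _guard_genes(data.st, forbidden_genes, "stage-2 ST input")
    shared_st = data.shared.st_indices
    shared_sc = data.shared.sc_indices

    enc_st, dec_st = bundle.enc_st, bundle.dec_st
    enc_sc, dec_sc = bundle.enc_sc, bundle.dec_sc
    t12, t21 = bundle.trans_st2sc, bundle.trans_sc2st
    d_st, d_sc = bundle.disc_st, bundle.disc_sc
    w = cfg.weights

    ss = np.random.SeedSequence(cfg.seed + 1)
    s = [int(v) for v in ss.generate_state(3) % (2**31 - 2)]
    samp_st = _Sampler(data.st.n_cells, cfg.batch_size, np.random.default_rng(s[0]))
    samp_sc = _Sampler(data.sc.n_cells, cfg.batch_size, np.random.default_rng(s[1]))
    rng_drop = np.random.default_rng(s[2])

    x_st_all = np.ascontiguousarray(data.st.values, dtype=t12.dtype)
    x_sc_all = np.ascontiguousarray(data.sc.values, dtype=t12.dtype)
    # frozen encoders are deterministic (eval mode), so embed every cell once
    z_st_all = enc_st(x_st_all)
    z_sc_all = enc_sc(x_sc_all)
    steps_per_epoch = int(np.ceil(max(data.st.n_cells, data.sc.n_cells) / cfg.batch_size))

    opt_trans = Adam([t12, t21], lr=cfg.trans_lr)
    opt_disc = Adam([d_st, d_sc], lr=cfg.disc_lr)
    trace = TrainingTrace()
    trace.audit.append(("trans", tuple(data.st.gene_names)))

    for epoch in range(cfg.trans_epochs):
        acc = {"cycle": [], "identity": [], "gan_translator": [], "hinge_discriminator": [],
               "total_translator": []}
        for step in range(steps_per_epoch):
            idx_st = samp_st.next()
            idx_sc = samp_sc.next()
            x_st, z_st = x_st_all[idx_st], z_st_all[idx_st]
            x_sc, z_sc = x_sc_all[idx_sc], z_sc_all[idx_sc]

            # --- discriminator update (translated embeddings are constants) ---
            fake_sc = t12(z_st, training=True, rng=rng_drop)
            fake_st = t21(z_sc, training=True, rng=rng_drop)
            d_st.zero_grad()
            d_sc.zero_grad()
            s_real_st, c1 = d_st.forward(z_st, training=True, rng=rng_drop)
            s_fake_st, c2 = d_st.forward(fake_st, training=True, rng=rng_drop)
            s_real_sc, c3 = d_sc.forward(z_sc, training=True, rng=rng_drop)
            s_fake_sc, c4 = d_sc.forward(fake_sc, training=True, rng=rng_drop)
            hinge = (
                hinge_real(s_real_st) + hinge_fake(s_fake_st)
                + hinge_real(s_real_sc) + hinge_fake(s_fake_sc)
            )
            _check_finite(hinge, "discriminator", epoch, step)
            d_st.backward(c1, hinge_real_grad(s_real_st))
            d_st.backward(c2, hinge_fake_grad(s_fake_st))
            d_sc.backward(c3, hinge_real_grad(s_real_sc))
            d_sc.backward(c4, hinge_fake_grad(s_fake_sc))
            opt_disc.step()

            # --- translator update ---
            t12.zero_grad()
            t21.zero_grad()
            cyc, ident, gan = 0.0, 0.0, 0.0
            for (z_src, x_src, t_fwd, t_bwd, dec_src, dec_dst, disc_dst,
                 idx_src, idx_dst) in (
                (z_st, x_st, t12, t21, dec_st, dec_sc, d_sc, shared_st, shared_sc),
                (z_sc, x_sc, t21, t12, dec_sc, dec_st, d_st, shared_sc, shared_st),
            ):
                z1, cT1 = t_fwd.forward(z_src, training=True, rng=rng_drop)
                # cycle: translate back and decode in the source domain
                zc, cT2 = t_bwd.forward(z1, training=True, rng=rng_drop)
                xc, cD1 = dec_src.forward(zc, training=False)
                cyc_term = reconstruction_loss(xc, x_src)
                g_zc = dec_src.backward(cD1, w.lambda_cyc * mse_grad(xc, x_src))
                g_z1 = t_bwd.backward(cT2, g_zc)
                # identity: decode in the target domain, correlate on shared genes
                xid, cD2 = dec_dst.forward(z1, training=False)
                rho, g_rho = pearson_rows_grad(xid[:, idx_dst], x_src[:, idx_src])
                id_term = float(1.0 - rho.mean())
                g_xid = np.zeros_like(xid)
                g_xid[:, idx_dst] = (-(w.lambda_id / len(rho)) * g_rho).astype(xid.dtype)
                g_z1 = g_z1 + dec_dst.backward(cD2, g_xid)
                # adversarial: raise the target discriminator's score
                s_fake, cC = disc_dst.forward(z1, training=True, rng=rng_drop)
                gan_term = float(-s_fake.mean())
                g_s = np.full_like(s_fake, -w.lambda_gan / s_fake.shape[0])
                g_z1 = g_z1 + disc_dst.backward(cC, g_s, param_grads=False)
                t_fwd.backward(cT1, g_z1)
                cyc += cyc_term
                ident += id_term
                gan += gan_term
            total = w.lambda_id * ident + w.lambda_cyc * cyc + w.lambda_gan * gan
            _check_finite(total, "translator", epoch, step)
            opt_trans.step()
            acc["cycle"].append(cyc)
            acc["identity"].append(ident)
            acc["gan_translator"].append(gan)
            acc["hinge_discriminator"].append(hinge)
            acc["total_translator"].append(total)
        record = {"stage": "trans", "epoch": epoch}
        record.update({k: float(np.mean(v)) for k, v in acc.items()})
        if epoch_callback is not None:
            record.update(epoch_callback(bundle, epoch))
        trace.records.append(record)
    return trace


def impute(bundle: ModelBundle, st: ExpressionMatrix) -> np.ndarray:
    """Predict SC-panel expression for every ST cell: D_SC(T_ST2SC(E_ST(x))).

    Runs entirely in eval mode (deterministic) and floors the output at zero.
    The ST matrix must carry exactly the gene columns the model was trained
    on, in the same order.
    """
    trained = bundle.config.get("st_genes")
    if trained is not None and list(st.gene_names) != list(trained):
        missing = sorted(set(trained) - set(st.gene_names))
        extra = sorted(set(st.gene_names) - set(trained))
        raise ValidationError(
            f"ST gene set differs from training: missing={missing[:5]}, extra={extra[:5]}"
        )
    if st.stage != "normalized":
        raise ValidationError(f"impute expects a normalized matrix, got stage={st.stage!r}")
    if st.n_genes != bundle.st_in_dim:
        raise ValidationError(f"expected {bundle.st_in_dim} ST genes, got {st.n_genes}")
    x = np.ascontiguousarray(st.values, dtype=bundle.enc_st.dtype)
    z = bundle.enc_st(x)
    z_sc = bundle.trans_st2sc(z)
    out = bundle.dec_sc(z_sc)
    return np.maximum(out.astype(np.float64), 0.0)


def translate_embeddings(bundle: ModelBundle, st: ExpressionMatrix) -> dict[str, LatentEmbedding]:
    """Encoded, translated and cycle-translated ST embeddings (for diagnostics)."""
    x = np.ascontiguousarray(st.values, dtype=bundle.enc_st.dtype)
    z = bundle.enc_st(x)
    z_tr = bundle.trans_st2sc(z)
    z_cyc = bundle.trans_sc2st(z_tr)
    return {
        "encoded": LatentEmbedding(z, "ST", "encoded"),
        "translated": LatentEmbedding(z_tr, "SC", "translated"),
        "cycled": LatentEmbedding(z_cyc, "ST", "cycled"),
    }
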