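"""Gene-holdout cross-validation and the overlap/sparsity ablation protocols.

Shared genes are partitioned into disjoint near-equal folds. In each fold the
held-out genes are removed from the ST matrix entirely — they appear in no
encoder input and no loss term — a fresh model is trained on the reduced ST
matrix plus the untouched SC reference, and the held-out genes are then
predicted and scored against their measured ST values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    MetricReport,
    PairedDataset,
    SharedGeneMap,
    ValidationError,
)
from .networks import build_bundle
from .preprocess import PreprocessConfig, preprocess_pair
from .training import (
    TrainingConfig,
    TrainingTrace,
    freeze_autoencoders,
    impute,
    pretrain_autoencoders,
    train_translators,
)

logger = logging.getLogger("stimpute")

OVERLAP_FRACTIONS = (0.10, 0.25, 0.50, 0.75, 1.00)
SPARSITY_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 0.90)


@dataclass
class FoldPlan:
    """Disjoint exhaustive partition of the shared genes into held-out folds."""

    n_folds: int
    folds: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        if len(self.folds) != self.n_folds:
            raise ValidationError("fold count mismatch")
        all_genes = [g for f in self.folds for g in f]
        if len(set(all_genes)) != len(all_genes):
            raise ValidationError("folds must be pairwise disjoint")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValidationError("fold sizes must differ by at most 1")


def make_fold_plan(shared: SharedGeneMap, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded uniform shuffle, then near-equal contiguous chunks.

    The remainder genes are distributed one per fold from the front, so for
    example 141 genes over 5 folds split as 29 + 28 + 28 + 28 + 28.
    """
    names = list(shared.shared_names)
    if len(names) < n_folds:
        raise ValidationError(f"need at least {n_folds} shared genes, have {len(names)}")
    rng = np.random.default_rng(seed)
    order = [names[i] for i in rng.permutation(len(names))]
    base, rem = divmod(len(names), n_folds)
    folds, start = [], 0
    for k in range(n_folds):
        size = base + (1 if k < rem else 0)
        folds.append(order[start : start + size])
        start += size
    return FoldPlan(n_folds=n_folds, folds=folds, seed=seed)


def _remap_shared(shared: SharedGeneMap, st_train: ExpressionMatrix, heldout: set[str]) -> SharedGeneMap:
    """Drop held-out genes from the shared map and remap ST indices onto the reduced matrix."""
    pos = {g: i for i, g in enumerate(st_train.gene_names)}
    names, st_idx, sc_idx = [], [], []
    for name, _, j in zip(shared.shared_names, shared.st_indices, shared.sc_indices):
        if name in heldout:
            continue
        names.append(name)
        st_idx.append(pos[name])
        sc_idx.append(int(j))
    return SharedGeneMap(names, np.array(st_idx, dtype=int), np.array(sc_idx, dtype=int))


def run_fold(
    data: PairedDataset,
    plan: FoldPlan,
    fold_index: int,
    cfg: TrainingConfig,
    pretrained_sc: dict | None = None,
    return_bundle: bool = False,
):
    """Train within one fold and evaluate on that fold's held-out genes.

    ``pretrained_sc`` optionally carries SC encoder/decoder weights trained
    once outside the fold loop; the SC matrix is identical in every fold, so
    this changes nothing about holdout hygiene.
    """
    heldout = list(plan.folds[fold_index])
    heldset = set(heldout)
    st_train = data.st.drop_genes(heldout)
    leaked = heldset & set(st_train.gene_names)
    if leaked:
        raise ValidationError(f"failed to remove held-out genes {sorted(leaked)[:5]}")
    shared_train = _remap_shared(data.shared, st_train, heldset)
    fold_data = PairedDataset(st=st_train, sc=data.sc, shared=shared_train,
                              st_coords=data.st_coords)

    fold_cfg = TrainingConfig(
        ae_epochs=cfg.ae_epochs, trans_epochs=cfg.trans_epochs, batch_size=cfg.batch_size,
        ae_lr=cfg.ae_lr, trans_lr=cfg.trans_lr, disc_lr=cfg.disc_lr, weights=cfg.weights,
        seed=int(np.random.SeedSequence([cfg.seed, fold_index]).generate_state(1)[0] % (2**31 - 2)),
    )
    bundle = build_bundle(st_train.n_genes, data.sc.n_genes, seed=fold_cfg.seed)
    bundle.config["st_genes"] = list(st_train.gene_names)
    bundle.config["sc_genes"] = list(data.sc.gene_names)
    skip_sc = pretrained_sc is not None
    if skip_sc:
        bundle.enc_sc.load_state_arrays("enc_sc", pretrained_sc)
        bundle.dec_sc.load_state_arrays("dec_sc", pretrained_sc)
    trace = pretrain_autoencoders(bundle, fold_data, fold_cfg, forbidden_genes=heldout,
                                  skip_sc=skip_sc)
    freeze_autoencoders(bundle)
    trace.extend(train_translators(bundle, fold_data, fold_cfg, forbidden_genes=heldout))

    imputed_sc = impute(bundle, st_train)  # ST cells x SC genes
    st_pos = {g: i for i, g in enumerate(data.st.gene_names)}
    sc_of = dict(zip(data.shared.shared_names, data.shared.sc_indices))
    measured = data.st.values[:, [st_pos[g] for g in heldout]]
    predicted = imputed_sc[:, [int(sc_of[g]) for g in heldout]]

    from .evaluation import evaluate_imputation

    report = evaluate_imputation(measured, predicted, heldout)
    report.diagnostics["fold_index"] = fold_index
    report.diagnostics["audit_gene_sets_clean"] = all(
        not (heldset & set(genes)) for _, genes in trace.audit
    )
    return (report, bundle) if return_bundle else report


def run_cv(
    data: PairedDataset,
    cfg: TrainingConfig,
    seed: int = 0,
    n_folds: int = 5,
    reuse_sc_autoencoder: bool = True,
    return_bundles: bool = False,
):
    """Full gene-holdout CV: every shared gene is held out and scored exactly once."""
    plan = make_fold_plan(data.shared, n_folds=n_folds, seed=seed)
    pretrained_sc = None
    if reuse_sc_autoencoder:
        sc_seed = int(np.random.SeedSequence([seed, n_folds, 7]).generate_state(1)[0] % (2**31 - 2))
        sc_bundle = build_bundle(1, data.sc.n_genes, seed=sc_seed)
        sc_cfg = TrainingConfig(
            ae_epochs=cfg.ae_epochs, trans_epochs=1, batch_size=cfg.batch_size,
            ae_lr=cfg.ae_lr, trans_lr=cfg.trans_lr, disc_lr=cfg.disc_lr,
            weights=cfg.weights, seed=sc_seed,
        )
        from .training import _train_autoencoder

        _train_autoencoder(
            sc_bundle.enc_sc, sc_bundle.dec_sc, data.sc.values, sc_cfg.ae_epochs,
            sc_cfg.ae_lr, sc_cfg.batch_size, sc_seed, "SC",
        )
        pretrained_sc = {}
        pretrained_sc.update(sc_bundle.enc_sc.state_arrays("enc_sc"))
        pretrained_sc.update(sc_bundle.dec_sc.state_arrays("dec_sc"))

    results = [run_fold(data, plan, k, cfg, pretrained_sc=pretrained_sc,
                        return_bundle=return_bundles)
               for k in range(plan.n_folds)]
    if return_bundles:
        reports = [r for r, _ in results]
        bundles = [b for _, b in results]
    else:
        reports = results
    per_gene = pd.concat([r.per_gene for r in reports])
    diagnostics = {
        "n_folds": plan.n_folds,
        "fold_sizes": [len(f) for f in plan.folds],
        "seed": seed,
        "audit_gene_sets_clean": all(r.diagnostics["audit_gene_sets_clean"] for r in reports),
        "excluded_genes": sorted(
            g for r in reports for g in r.diagnostics.get("excluded_genes", [])
        ),
    }
    report = MetricReport(per_gene, diagnostics=diagnostics)
    return (report, bundles, plan) if return_bundles else report


def baseline_mean_report(data: PairedDataset) -> MetricReport:
    """Per-gene-mean baseline: predict each shared gene as its constant SC mean."""
    sc_means = data.sc.values.mean(axis=0)
    measured = data.st.values[:, data.shared.st_indices]
    predicted = np.tile(sc_means[data.shared.sc_indices], (data.st.n_cells, 1))
    from .evaluation import evaluate_imputation

    return evaluate_imputation(measured, predicted, data.shared.shared_names)


def ablate_overlap(
    data: PairedDataset,
    cfg: TrainingConfig,
    fractions=OVERLAP_FRACTIONS,
    seed: int = 0,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Shrink the shared set available to training and re-run CV per fraction.

    Retained subsets are nested: one seeded shuffle of the shared genes is
    truncated at each fraction. Genes dropped from the shared set stay in the
    ST matrix as ordinary (non-anchored, never held-out) columns.
    """
    names = list(data.shared.shared_names)
    rng = np.random.default_rng(seed)
    order = [names[i] for i in rng.permutation(len(names))]
    rows = []
    for frac in fractions:
        retained = set(order[: int(round(frac * len(names)))])
        if len(retained) < n_folds:
            logger.warning("overlap fraction %.2f keeps %d < %d shared genes; skipped",
                           frac, len(retained), n_folds)
            continue
        sub = PairedDataset(
            st=data.st, sc=data.sc,
            shared=data.shared.restrict([g for g in names if g in retained]),
            st_coords=data.st_coords,
        )
        report = run_cv(sub, cfg, seed=seed, n_folds=n_folds)
        rows.append({"fraction": frac, "n_shared": len(retained), **report.averages})
    return pd.DataFrame(rows)


def mask_st_nonzeros(st: ExpressionMatrix, fraction: float, seed: int) -> ExpressionMatrix:
    """Zero a seeded random sample of the ST matrix's nonzero entries."""
    values = st.values.copy()
    nz = np.argwhere(values > 0)
    n_keep = int(round((1.0 - fraction) * len(nz)))
    rng = np.random.default_rng(seed)
    drop = rng.permutation(len(nz))[: len(nz) - n_keep]
    values[nz[drop, 0], nz[drop, 1]] = 0.0
    return ExpressionMatrix(values, list(st.gene_names), list(st.cell_ids), st.stage)


def ablate_sparsity(
    raw_data: PairedDataset,
    pre_cfg: PreprocessConfig,
    cfg: TrainingConfig,
    fractions=SPARSITY_FRACTIONS,
    seed: int = 0,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Mask ST nonzeros before preprocessing and re-run CV per sparsity level."""
    if raw_data.st.stage != "raw":
        raise ValidationError("sparsity ablation starts from raw data")
    rows = []
    for frac in fractions:
        masked = mask_st_nonzeros(raw_data.st, frac, seed) if frac > 0 else raw_data.st
        pair = PairedDataset(st=masked, sc=raw_data.sc, shared=raw_data.shared,
                             st_coords=raw_data.st_coords)
        processed = preprocess_pair(pair, pre_cfg)
        if len(processed.shared) < n_folds:
            logger.warning("sparsity %.2f leaves %d shared genes; skipped", frac,
                           len(processed.shared))
            continue
        report = run_cv(processed, cfg, seed=seed, n_folds=n_folds)
        rows.append({"fraction": frac, "n_shared": len(processed.shared), **report.averages})
    return pd.DataFrame(rows)
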