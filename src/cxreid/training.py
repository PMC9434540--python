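"""Losses, learning-rate schedules, cross-batch memory, training loops.

Verification: binary cross-entropy on pair scores, Adam on mini-batches of
32 pairs, early stopping on validation AUC with patience 5.

Retrieval: contrastive loss ``y d^2 + (1-y) max(0, m-d)^2`` over all pairs
enumerable within a batch plus a FIFO cross-batch memory of recent
embeddings, SGD with weight decay 1e-5 under the 1cycle learning-rate
policy: first the head alone (backbone frozen), then the full network for a
second cycle.
"""

from __future__ import annotations

import dataclasses
import pathlib
from collections import deque
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .nn import tensor as F
from .cohort import Cohort, DatasetSplit, load_image, prepare_model_input
from .models import RetrievalNet, VerificationNet
from .pairs import (MiningConfig, PairSet, assemble_epoch_pairs,
                    enumerate_online_pairs, mine_positive_pairs)

EPS = 1e-12


@dataclasses.dataclass
class TrainConfig:
    """Scalar hyperparameters; defaults are the full-scale reference values."""

    learning_rate: float = 1e-4        # verification Adam rate
    batch_size: int = 32
    patience: int = 5
    threshold: float = 0.5
    margin: float = 1.0
    weight_decay: float = 1e-5
    lr_min: float = 0.0063             # 1cycle lower bound
    lr_max: float = 0.1584             # 1cycle upper bound (LR-finder choice)
    epochs: int = 50                   # verification epoch cap
    epochs_head: int = 30              # retrieval phase 1
    epochs_full: int = 50              # retrieval phase 2
    xbm_capacity: int = 128            # last 4 batches of 32
    loss_reduction: str = "balanced"   # batch reduction of the pair losses
    l2_normalize_embeddings: bool = False
    input_side: int = 256
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr_min >= self.lr_max:
            raise ValueError("lr_min must be below lr_max")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


def desk_scale_config(seed: int = 0) -> TrainConfig:
    """Down-scaled preset for the tiny backbone at 64 px (CPU minutes).

    The 1cycle bounds are re-derived for the tiny network the same way the
    full-scale bounds were chosen (an LR range test); epoch counts shrink to
    keep a desk run in minutes. The cross-batch memory is disabled: its
    slow-drift premise fails with so few batches per epoch (the embedding
    model moves too fast for stale entries to stay informative), and retrieval
    embeddings are unit-normalized so the contrastive margin stays meaningful
    for a small freshly initialized network.
    """
    return TrainConfig(learning_rate=1e-3, lr_min=0.005, lr_max=0.05,
                       epochs=25, epochs_head=3, epochs_full=5,
                       xbm_capacity=0, l2_normalize_embeddings=True,
                       input_side=64, seed=seed)


# -- losses -------------------------------------------------------------------

def bce_loss(scores, labels) -> Tensor:
    """Mean binary cross-entropy; scores clamped away from {0, 1}."""
    s = scores if isinstance(scores, Tensor) else Tensor(np.asarray(scores, dtype=np.float64))
    y = np.asarray(labels, dtype=s.dtype)
    p = F.clip(s, EPS, 1.0 - EPS)
    ll = F.add(F.mul(F.log(p), y), F.mul(F.log(F.add(F.mul(p, -1.0), 1.0)), 1.0 - y))
    return F.mul(F.tensor_mean(ll), -1.0)


def contrastive_loss(z1, z2, labels, margin: float = 1.0,
                     reduction: str = "mean") -> Tensor:
    """Contrastive loss ``y d^2 + (1-y) max(0, m-d)^2`` (no 1/2 factor).

    ``z1``/``z2`` are (B, D) embedding batches; ``labels`` binary. The
    distance is raw Euclidean; at exactly zero distance the negative branch
    has zero subgradient. ``reduction='mean'`` averages over all pairs;
    ``'balanced'`` averages the positive and negative pair losses separately
    and sums the two means, so a scarce class (positives are a few percent
    of online-mined pairs) is not drowned out.
    """
    z1 = z1 if isinstance(z1, Tensor) else Tensor(np.atleast_2d(np.asarray(z1, dtype=np.float64)))
    z2 = z2 if isinstance(z2, Tensor) else Tensor(np.atleast_2d(np.asarray(z2, dtype=np.float64)))
    y = np.asarray(labels, dtype=z1.dtype).reshape(-1)
    diff = F.add(z1, F.mul(z2, -1.0))
    d2 = F.tensor_sum(F.mul(diff, diff), axis=-1)
    d = F.sqrt(F.maximum_const(d2, EPS))
    pos = F.mul(d2, y)
    hinge = F.maximum_const(F.add(F.mul(d, -1.0), margin), 0.0)
    neg = F.mul(F.mul(hinge, hinge), 1.0 - y)
    if reduction == "mean":
        return F.tensor_mean(F.add(pos, neg))
    if reduction == "balanced":
        n_pos = max(float(y.sum()), 1.0)
        n_neg = max(float((1.0 - y).sum()), 1.0)
        return F.add(F.mul(F.tensor_sum(pos), 1.0 / n_pos),
                     F.mul(F.tensor_sum(neg), 1.0 / n_neg))
    raise ValueError(f"unknown reduction {reduction!r}")


# -- learning-rate machinery --------------------------------------------------

def one_cycle_lr(step: int, total_steps: int, lr_min: float, lr_max: float,
                 pct_peak: float = 0.3) -> float:
    """Per-batch 1cycle rate: cosine rise to ``lr_max`` then cosine fall.

    The trace starts at ``lr_min``, peaks exactly at ``lr_max`` at
    ``pct_peak`` of the cycle, and returns to ``lr_min``.
    """
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps})")
    if total_steps == 1:
        return lr_max
    peak = max(1, int(round(pct_peak * (total_steps - 1))))
    peak = min(peak, total_steps - 1)
    if step <= peak:
        frac = step / peak
    else:
        frac = (total_steps - 1 - step) / (total_steps - 1 - peak)
    return lr_min + (lr_max - lr_min) * 0.5 * (1.0 - np.cos(np.pi * frac))


def lr_range_test(optimizer, batch_fn: Callable[[int], Tensor],
                  lr_lo: float, lr_hi: float, n_steps: int,
                  smoothing: float = 0.9) -> tuple[float, list[float], list[float]]:
    """Exponential LR sweep; returns (suggested lr_max, lr trace, loss trace).

    ``batch_fn(step)`` must run a forward pass and return the loss tensor;
    this routine backpropagates, steps the optimizer at the swept rate, and
    suggests the rate at the steepest descent of the smoothed loss.
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    lrs, losses = [], []
    smooth, debias = 0.0, 0.0
    for step in range(n_steps):
        lr = lr_lo * (lr_hi / lr_lo) ** (step / (n_steps - 1))
        optimizer.lr = lr
        loss = batch_fn(step)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        val = float(loss.item())
        smooth = smoothing * smooth + (1 - smoothing) * val
        debias = smoothing * debias + (1 - smoothing)
        lrs.append(lr)
        losses.append(smooth / debias)
    finite = [i for i, v in enumerate(losses) if np.isfinite(v)]
    if len(finite) < 2:
        raise RuntimeError("loss diverged at every learning rate in the sweep")
    slopes = np.diff(np.asarray(losses)[finite])
    best = int(np.argmin(slopes))            # most negative = steepest descent
    return lrs[finite[best + 1]], lrs, losses


class XBMemory:
    """FIFO store of recent (embedding, patient) snapshots for pair mining.

    Enqueued embeddings are detached copies: no gradient ever flows into a
    memory entry. Capacity 0 disables the memory (a strict no-op).
    """

    def __init__(self, capacity: int):
        if capacity < 0:
            raise ValueError("capacity must be non-negative")
        self.capacity = capacity
        self._queue: deque[tuple[np.ndarray, str]] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._queue)

    def update(self, embeddings: np.ndarray, labels: Sequence[str]) -> None:
        emb = np.asarray(embeddings)
        if len(emb) != len(labels):
            raise ValueError("embeddings and labels length mismatch")
        for e, lab in zip(emb, labels):
            self._queue.append((e.copy(), lab))

    def contents(self) -> tuple[np.ndarray, list[str]]:
        if not self._queue:
            return np.zeros((0, 0)), []
        return np.stack([e for e, _ in self._queue]), [l for _, l in self._queue]


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch trace of one training run."""

    epochs: list[dict] = dataclasses.field(default_factory=list)
    lr_trace: list[float] = dataclasses.field(default_factory=list)
    stopped_epoch: int | None = None
    best_epoch: int | None = None

    def log(self, **kwargs) -> None:
        self.epochs.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def to_csv(self, path: str | pathlib.Path) -> None:
        self.to_frame().to_csv(path, index=False)


class ImageBank:
    """Prepared model inputs for a cohort, cached in memory.

    Loading and resizing dominate desk-scale runtimes, so every image is
    prepared once and reused across epochs.
    """

    def __init__(self, cohort: Cohort, side: int,
                 loader: Callable | None = None):
        self.side = side
        loader = loader or load_image
        self._data = {r.image_id: prepare_model_input(loader(r), side)
                      for r in cohort}

    def __getitem__(self, image_id: str) -> np.ndarray:
        return self._data[image_id]

    def stack(self, image_ids: Sequence[str]) -> np.ndarray:
        return np.stack([self._data[i] for i in image_ids])


class EarlyStopping:
    """Maximize a validation metric; stop after ``patience`` flat epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch: int | None = None
        self._since_best = 0

    def update(self, epoch: int, metric: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if metric > self.best:
            self.best = metric
            self.best_epoch = epoch
            self._since_best = 0
            return False
        self._since_best += 1
        return self._since_best >= self.patience


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .verification_eval import roc_auc
    return roc_auc(scores, labels)


def score_pair_set(model: VerificationNet, pairs: PairSet, bank: ImageBank,
                   batch_size: int = 64) -> np.ndarray:
    """Similarity scores for a pair set (inference mode)."""
    scores = np.empty(len(pairs), dtype=np.float64)
    samples = pairs.samples
    with nn.no_grad():
        for lo in range(0, len(samples), batch_size):
            chunk = samples[lo:lo + batch_size]
            x1 = Tensor(bank.stack([s.first_id for s in chunk]))
            x2 = Tensor(bank.stack([s.second_id for s in chunk]))
            scores[lo:lo + len(chunk)] = model(x1, x2).numpy().ravel()
    return scores


def train_verifier(split: DatasetSplit, mining: MiningConfig, cfg: TrainConfig,
                   model: VerificationNet | None = None,
                   bank: ImageBank | None = None,
                   verbose: bool = False) -> tuple[VerificationNet, TrainHistory]:
    """Train the verification siamese network with offline-mined pairs."""
    positives = mine_positive_pairs(split.train)
    if positives.size == 0:
        raise ValueError("training cohort yields no positive pairs")
    if model is None:
        model = VerificationNet(input_side=cfg.input_side, seed=cfg.seed)
    if bank is None:
        merged = Cohort(list(split.train.records) + list(split.val.records))
        bank = ImageBank(merged, cfg.input_side)

    # fixed balanced validation pairs, mirroring the training constructor
    val_pos = mine_positive_pairs(split.val)
    n_val = 2 * min(val_pos.size, max(1, mining.target_size // 4))
    val_pairs = assemble_epoch_pairs(
        val_pos, split.val,
        MiningConfig(mode="FTS", target_size=n_val, seed=mining.seed + 1), epoch=0)
    val_labels = val_pairs.labels()

    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    history = TrainHistory()
    best_state = model.state_dict()
    rng = np.random.default_rng(cfg.seed)

    for epoch in range(cfg.epochs):
        epoch_pairs = assemble_epoch_pairs(positives, split.train, mining, epoch)
        order = rng.permutation(len(epoch_pairs))
        samples = [epoch_pairs.samples[i] for i in order]
        losses = []
        for lo in range(0, len(samples), cfg.batch_size):
            chunk = samples[lo:lo + cfg.batch_size]
            ids = [s.first_id for s in chunk] + [s.second_id for s in chunk]
            x = Tensor(bank.stack(ids))
            z = model.embed(x)
            z1 = F.take(z, np.arange(len(chunk)))
            z2 = F.take(z, np.arange(len(chunk)) + len(chunk))
            scores = model.score(z1, z2)
            loss = bce_loss(F.reshape(scores, (-1,)), [s.label for s in chunk])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        val_scores = score_pair_set(model, val_pairs, bank)
        val_auc = _auc(val_scores, val_labels)
        history.log(epoch=epoch, train_loss=float(np.mean(losses)),
                    val_auc=val_auc, lr=optimizer.lr)
        if verbose:
            print(f"[verify] epoch {epoch}: loss {np.mean(losses):.4f} "
                  f"val AUC {val_auc:.4f}")
        if val_auc > stopper.best:
            best_state = model.state_dict()
        if stopper.update(epoch, val_auc):
            history.stopped_epoch = epoch
            break
    history.best_epoch = stopper.best_epoch
    model.load_state_dict(best_state)
    return model, history


def _patient_batches(cohort: Cohort, batch_size: int,
                     rng: np.random.Generator) -> list[list[str]]:
    """Batches built patient-by-patient so same-identity pairs co-occur."""
    pids = list(cohort.patient_index)
    order = rng.permutation(len(pids))
    batches, current = [], []
    for k in order:
        for image_id in cohort.patient_index[pids[k]]:
            current.append(image_id)
            if len(current) == batch_size:
                batches.append(current)
                current = []
    if len(current) >= 2:
        batches.append(current)
    return batches


def precision_at_1_of(model: RetrievalNet, cohort: Cohort, bank: ImageBank,
                      batch_size: int = 64) -> float:
    from .retrieval_eval import GalleryIndex, precision_at_1, rank_all
    ids = [r.image_id for r in cohort]
    emb = embed_cohort(model, ids, bank, batch_size)
    gallery = GalleryIndex(ids, emb, [cohort[i].patient_id for i in ids])
    rrs = rank_all(gallery)
    return precision_at_1(rrs) if rrs else float("nan")


def embed_cohort(model: RetrievalNet, image_ids: Sequence[str], bank: ImageBank,
                 batch_size: int = 64) -> np.ndarray:
    out = np.empty((len(image_ids), 128), dtype=np.float64)
    with nn.no_grad():
        for lo in range(0, len(image_ids), batch_size):
            chunk = image_ids[lo:lo + batch_size]
            out[lo:lo + len(chunk)] = model(Tensor(bank.stack(chunk))).numpy()
    return out


def train_retriever(split: DatasetSplit, cfg: TrainConfig,
                    model: RetrievalNet | None = None,
                    bank: ImageBank | None = None,
                    verbose: bool = False) -> tuple[RetrievalNet, TrainHistory]:
    """Two-phase contrastive training of the retrieval siamese network.

    Phase 1 trains the pooling/FC head for ``epochs_head`` epochs with the
    backbone frozen under one 1cycle schedule; phase 2 trains everything for
    ``epochs_full`` epochs under a second 1cycle. Single-image patients are
    discarded from the training cohort (online mining needs positives).
    """
    train_cohort = split.train.subset(split.train.multi_image_patients())
    if train_cohort.n_patients() < 2:
        raise ValueError("online mining needs >= 2 multi-image patients in training")
    if model is None:
        model = RetrievalNet(seed=cfg.seed,
                             l2_normalize=cfg.l2_normalize_embeddings)
    if bank is None:
        merged = Cohort(list(train_cohort.records) + list(split.val.records))
        bank = ImageBank(merged, cfg.input_side)

    rng = np.random.default_rng(cfg.seed)
    memory = XBMemory(cfg.xbm_capacity)
    history = TrainHistory()

    phases = [("head", cfg.epochs_head, list(model.head_parameters())),
              ("full", cfg.epochs_full, list(model.parameters()))]
    for phase_name, n_epochs, params in phases:
        if n_epochs == 0:
            continue
        epoch_batches = [_patient_batches(train_cohort, cfg.batch_size, rng)
                         for _ in range(n_epochs)]
        total_steps = sum(len(b) for b in epoch_batches)
        optimizer = nn.SGD(params, lr=cfg.lr_min, momentum=0.9,
                           weight_decay=cfg.weight_decay)
        step = 0
        for epoch, batches in enumerate(epoch_batches):
            losses = []
            for batch_ids in batches:
                optimizer.lr = one_cycle_lr(step, total_steps, cfg.lr_min, cfg.lr_max)
                history.lr_trace.append(optimizer.lr)
                labels = [train_cohort[i].patient_id for i in batch_ids]
                emb = model(Tensor(bank.stack(batch_ids)))
                mem_emb, mem_labels = memory.contents()
                pair_idx = enumerate_online_pairs(labels, mem_labels)
                if pair_idx:
                    if mem_labels:
                        allemb = F.concat([emb, Tensor(mem_emb.astype(emb.dtype))], axis=0)
                    else:
                        allemb = emb
                    ii = np.array([p[0][0] for p in pair_idx])
                    jj = np.array([p[0][1] for p in pair_idx])
                    yy = np.array([p[1] for p in pair_idx])
                    loss = contrastive_loss(F.take(allemb, ii), F.take(allemb, jj),
                                            yy, cfg.margin,
                                            reduction=cfg.loss_reduction)
                    optimizer.zero_grad()
                    loss.backward()
                    optimizer.step()
                    losses.append(loss.item())
                memory.update(emb.numpy(), labels)
                step += 1
            val_p1 = precision_at_1_of(model, split.val, bank) if len(split.val) else float("nan")
            history.log(phase=phase_name, epoch=epoch,
                        train_loss=float(np.mean(losses)) if losses else float("nan"),
                        val_precision_at_1=val_p1)
            if verbose:
                print(f"[retrieve/{phase_name}] epoch {epoch}: "
                      f"loss {history.epochs[-1]['train_loss']:.4f} "
                      f"val P@1 {val_p1:.4f}")
    return model, history
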