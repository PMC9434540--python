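"""Image-pair construction for siamese training.

Offline mining (verification): every same-patient combination becomes a
positive pair; negatives are drawn at random across patients, either once for
the whole run (fixed training set, FTS) or freshly per epoch (randomized
negative pairs, RNP). Online mining (retrieval): pairs are enumerated inside
each mini-batch, optionally against a cross-batch memory of recent
embeddings.
"""

from __future__ import annotations

import dataclasses
import itertools
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort


@dataclasses.dataclass(frozen=True)
class PairSample:
    """An unordered image pair with its same-patient label.

    ``label`` is 1 exactly when both images belong to one patient. Ids are
    stored in lexicographic order so each unordered pair has one canonical
    representation.
    """

    first_id: str
    second_id: str
    label: int

    def __post_init__(self):
        if self.first_id == self.second_id:
            raise ValueError(f"pair references one image twice: {self.first_id!r}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.second_id < self.first_id:
            a, b = self.second_id, self.first_id
            object.__setattr__(self, "first_id", a)
            object.__setattr__(self, "second_id", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.first_id, self.second_id)


class PairSet:
    """A duplicate-free collection of :class:`PairSample`."""

    def __init__(self, samples: Sequence[PairSample]):
        self.samples = list(samples)
        keys = {s.key for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("duplicate unordered pairs in PairSet")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def size(self) -> int:
        return len(self.samples)

    def count_positive(self) -> int:
        return sum(s.label for s in self.samples)

    def count_negative(self) -> int:
        return len(self.samples) - self.count_positive()

    def is_balanced(self) -> bool:
        return self.count_positive() == self.count_negative()

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)


@dataclasses.dataclass(frozen=True)
class MiningConfig:
    """Offline-mining configuration.

    ``mode='FTS'`` freezes one balanced pair set for every epoch;
    ``mode='RNP'`` redraws the negative half each epoch. ``target_size`` is
    the balanced set size N_s (positives and negatives each N_s/2).
    """

    mode: str = "RNP"
    target_size: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("FTS", "RNP"):
            raise ValueError("mode must be 'FTS' or 'RNP'")
        if self.target_size % 2:
            raise ValueError("target_size must be even for balanced sets")


def mine_positive_pairs(cohort: Cohort) -> PairSet:
    """All same-patient combinations; single-image patients contribute none."""
    samples = []
    for ids in cohort.patient_index.values():
        for a, b in itertools.combinations(sorted(ids), 2):
            samples.append(PairSample(a, b, 1))
    return PairSet(samples)


def _n_cross_pairs(cohort: Cohort) -> int:
    sizes = np.array([len(v) for v in cohort.patient_index.values()])
    total = sizes.sum()
    return int((total * total - (sizes * sizes).sum()) // 2)


def sample_negative_pairs(cohort: Cohort, count: int, rng_seed: int) -> PairSet:
    """Draw ``count`` distinct cross-patient pairs uniformly at random."""
    if cohort.n_patients() < 2:
        raise ValueError("need at least 2 patients for negative pairs")
    available = _n_cross_pairs(cohort)
    if count > available:
        raise ValueError(f"requested {count} negative pairs but only {available} exist")
    rng = np.random.default_rng(rng_seed)
    ids = [r.image_id for r in cohort.records]
    owner = {r.image_id: r.patient_id for r in cohort.records}
    chosen: dict[tuple[str, str], PairSample] = {}
    # rejection sampling with dedup; falls back to full enumeration when the
    # request covers most of the universe
    if count > 0.6 * available:
        all_pairs = [PairSample(a, b, 0)
                     for a, b in itertools.combinations(sorted(ids), 2)
                     if owner[a] != owner[b]]
        idx = rng.choice(len(all_pairs), size=count, replace=False)
        return PairSet([all_pairs[i] for i in sorted(idx)])
    n = len(ids)
    while len(chosen) < count:
        need = count - len(chosen)
        ii = rng.integers(0, n, size=2 * need + 8)
        jj = rng.integers(0, n, size=2 * need + 8)
        for i, j in zip(ii, jj):
            if len(chosen) >= count:
                break
            a, b = ids[i], ids[j]
            if a == b or owner[a] == owner[b]:
                continue
            s = PairSample(a, b, 0)
            if s.key not in chosen:
                chosen[s.key] = s
    return PairSet(list(chosen.values()))


def _epoch_seed(seed: int, epoch: int) -> int:
    return int(np.random.SeedSequence([seed, epoch]).generate_state(1)[0] % (2 ** 31))


def assemble_epoch_pairs(positives: PairSet, cohort: Cohort,
                         config: MiningConfig, epoch: int) -> PairSet:
    """Balanced pair set of size N_s for one epoch.

    Positives are fixed across epochs (subsampled once by ``config.seed`` if
    more than N_s/2 exist). FTS negatives depend on ``config.seed`` only;
    RNP negatives depend on (seed, epoch).
    """
    half = config.target_size // 2
    if positives.size < half:
        raise ValueError(
            f"need {half} positive pairs, cohort provides {positives.size}")
    if positives.size > half:
        rng = np.random.default_rng(config.seed)
        idx = sorted(rng.choice(positives.size, size=half, replace=False))
        pos = [positives.samples[i] for i in idx]
    else:
        pos = list(positives.samples)
    neg_seed = config.seed if config.mode == "FTS" else _epoch_seed(config.seed, epoch)
    neg = sample_negative_pairs(cohort, half, neg_seed)
    return PairSet(pos + list(neg.samples))


def enumerate_online_pairs(batch_labels: Sequence[str],
                           memory_labels: Sequence[str] = ()
                           ) -> list[tuple[tuple[int, int], int]]:
    """All intra-batch combinations plus batch x memory pairs.

    Returns ``((i, j), y)`` index pairs. For memory pairs, ``j`` indexes the
    memory list and is offset by the batch length.
    """
    if not batch_labels:
        raise ValueError("batch must be non-empty")
    b = len(batch_labels)
    out = []
    for i, j in itertools.combinations(range(b), 2):
        out.append(((i, j), int(batch_labels[i] == batch_labels[j])))
    for i in range(b):
        for k, lab in enumerate(memory_labels):
            out.append(((i, b + k), int(batch_labels[i] == lab)))
    return out


def write_pair_manifest(pairs: PairSet, csv_path: str | pathlib.Path) -> None:
    pd.DataFrame([{"first_id": s.first_id, "second_id": s.second_id,
                   "label": s.label} for s in pairs]).to_csv(csv_path, index=False)


def read_pair_manifest(csv_path: str | pathlib.Path) -> PairSet:
    df = pd.read_csv(csv_path, dtype={"first_id": str, "second_id": str, "label": int})
    return PairSet([PairSample(r.first_id, r.second_id, int(r.label))
                    for r in df.itertuples(index=False)])
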