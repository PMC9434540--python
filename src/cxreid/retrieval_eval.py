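"""Retrieval-side evaluation: gallery ranking and mAP@R / R-Precision / P@1.

Every image is used as a query against all remaining images; the gallery is
sorted by ascending Euclidean distance between 128-d embeddings (ties broken
by image id). For a query with R relevant items:

* R-Precision = r / R, with r the relevant count within the top R ranks;
* AP@R = (1/R) * sum_{i=1..R} P@i * rel@i over the first R ranks;
* Precision@1 = the fraction of queries whose rank-1 item is relevant.

Queries with R = 0 (single-image patients in the evaluation cohort) carry no
retrievable identity and are excluded from all three metrics; the exclusion
count is reported.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cohort import Cohort


@dataclasses.dataclass
class GalleryIndex:
    ids: list[str]
    embeddings: np.ndarray           # (n, d)
    patient_ids: list[str]

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if not (len(self.ids) == len(self.embeddings) == len(self.patient_ids)):
            raise ValueError("gallery fields not aligned")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("non-finite embeddings")

    def __len__(self) -> int:
        return len(self.ids)


@dataclasses.dataclass
class RankedRetrieval:
    query_id: str
    ranked_ids: list[str]
    relevance: np.ndarray            # binary, aligned to ranked_ids
    distances: np.ndarray | None = None

    def __post_init__(self):
        self.relevance = np.asarray(self.relevance, dtype=np.int64)
        if self.query_id in self.ranked_ids:
            raise ValueError("query must not appear in its own ranking")
        if len(self.relevance) != len(self.ranked_ids):
            raise ValueError("relevance not aligned to ranking")
        if self.distances is not None:
            self.distances = np.asarray(self.distances, dtype=np.float64)
            if len(self.distances) != len(self.ranked_ids):
                raise ValueError("distances not aligned to ranking")

    @property
    def n_relevant(self) -> int:
        return int(self.relevance.sum())


def rank_by_distance(query_embedding: np.ndarray, gallery: GalleryIndex,
                     query_id: str, l2_normalize: bool = False) -> RankedRetrieval:
    """Rank the gallery (minus the query itself) by embedding distance."""
    mask = [i for i, gid in enumerate(gallery.ids) if gid != query_id]
    if not mask:
        raise ValueError("gallery holds no non-query entries")
    emb = gallery.embeddings[mask]
    q = np.asarray(query_embedding, dtype=np.float64).reshape(1, -1)
    if l2_normalize:
        emb = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        q = q / np.linalg.norm(q)
    dists = cdist(q, emb)[0]
    ids = [gallery.ids[i] for i in mask]
    order = sorted(range(len(ids)), key=lambda k: (dists[k], ids[k]))
    query_patient = None
    for i, gid in enumerate(gallery.ids):
        if gid == query_id:
            query_patient = gallery.patient_ids[i]
            break
    rel = np.array([int(gallery.patient_ids[mask[k]] == query_patient)
                    for k in order])
    return RankedRetrieval(query_id, [ids[k] for k in order], rel,
                           distances=dists[order])


def rank_all(gallery: GalleryIndex, l2_normalize: bool = False,
             keep_r0: bool = False) -> list[RankedRetrieval]:
    """Every-image-as-query ranking; drops R=0 queries unless ``keep_r0``."""
    emb = gallery.embeddings
    if l2_normalize:
        emb = emb / np.linalg.norm(emb, axis=1, keepdims=True)
    dists = cdist(emb, emb)
    out = []
    pid = np.asarray(gallery.patient_ids)
    for qi in range(len(gallery)):
        others = [i for i in range(len(gallery)) if gallery.ids[i] != gallery.ids[qi]]
        order = sorted(others, key=lambda k: (dists[qi, k], gallery.ids[k]))
        rel = (pid[order] == pid[qi]).astype(np.int64)
        rr = RankedRetrieval(gallery.ids[qi], [gallery.ids[k] for k in order],
                             rel, distances=dists[qi, order])
        if rr.n_relevant > 0 or keep_r0:
            out.append(rr)
    return out


def r_precision(rr: RankedRetrieval) -> float:
    """Relevant fraction within the top R ranks."""
    r = rr.n_relevant
    if r < 1:
        raise ValueError("query has no relevant gallery items")
    return float(rr.relevance[:r].sum() / r)


def average_precision_at_r(rr: RankedRetrieval, first_r_ranks: bool = True) -> float:
    """AP@R: mean of P@i * rel@i.

    With ``first_r_ranks`` (default) the sum runs over ranks 1..R, so
    relevant items retrieved beyond rank R contribute nothing; the
    alternative reading sums over the ranks of the first R relevant items.
    """
    r = rr.n_relevant
    if r < 1:
        raise ValueError("query has no relevant gallery items")
    rel = rr.relevance
    cum = np.cumsum(rel)
    prec = cum / np.arange(1, len(rel) + 1)
    if first_r_ranks:
        return float((prec[:r] * rel[:r]).sum() / r)
    ranks = np.nonzero(rel)[0][:r]
    return float(prec[ranks].sum() / r)


def mean_ap_at_r(rrs: Sequence[RankedRetrieval], first_r_ranks: bool = True) -> float:
    if not rrs:
        raise ValueError("no queries retained")
    return float(np.mean([average_precision_at_r(rr, first_r_ranks) for rr in rrs]))


def precision_at_1(rrs: Sequence[RankedRetrieval]) -> float:
    if not rrs:
        raise ValueError("no queries retained")
    return float(np.mean([rr.relevance[0] for rr in rrs]))


@dataclasses.dataclass
class RetrievalReport:
    map_at_r: float
    r_precision: float
    precision_at_1: float
    n_queries: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {"map_at_r": round(self.map_at_r, 4),
                "r_precision": round(self.r_precision, 4),
                "precision_at_1": round(self.precision_at_1, 4),
                "n_queries": self.n_queries, "n_excluded": self.n_excluded}

    def to_json(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def report_from_rankings(rrs: Sequence[RankedRetrieval], n_excluded: int = 0
                         ) -> RetrievalReport:
    return RetrievalReport(
        map_at_r=mean_ap_at_r(rrs),
        r_precision=float(np.mean([r_precision(rr) for rr in rrs])),
        precision_at_1=precision_at_1(rrs),
        n_queries=len(rrs), n_excluded=n_excluded)


def evaluate_retrieval(model, cohort: Cohort, input_side: int,
                       bank=None, l2_normalize: bool = False) -> RetrievalReport:
    """Embed a cohort and compute the three retrieval metrics.

    ``model`` maps a prepared (B,3,S,S) batch to (B,128) embeddings.
    """
    from .training import ImageBank, embed_cohort
    if not cohort.multi_image_patients():
        raise ValueError("cohort has no multi-image patients to retrieve")
    if bank is None:
        bank = ImageBank(cohort, input_side)
    ids = [r.image_id for r in cohort]
    emb = embed_cohort(model, ids, bank)
    gallery = GalleryIndex(ids, emb, [cohort[i].patient_id for i in ids])
    rrs = rank_all(gallery, l2_normalize=l2_normalize)
    return report_from_rankings(rrs, n_excluded=len(ids) - len(rrs))


def write_rankings(rrs: Sequence[RankedRetrieval], csv_path: str | pathlib.Path
                   ) -> None:
    rows = []
    for rr in rrs:
        dists = rr.distances if rr.distances is not None \
            else [float("nan")] * len(rr.ranked_ids)
        for rank, (gid, rel, d) in enumerate(
                zip(rr.ranked_ids, rr.relevance, dists), start=1):
            rows.append({"query_id": rr.query_id, "rank": rank,
                         "gallery_id": gid, "distance": d, "relevant": int(rel)})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
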