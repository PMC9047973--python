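"""Gallery/probe identification and its evaluation protocols.

An enrolled *gallery* maps identity ids to the embeddings of their
chips.  A *probe* is a folder of chips of one (possibly unknown)
individual.  Every probe chip is compared to every chip of every
gallery individual by cosine similarity; the per-pair scores are
aggregated (arithmetic mean by default) into one score per gallery
individual, and candidates are ranked by descending score.

Closed-set identification assumes the probe's identity is enrolled and
reports rank-k accuracy.  Open-set identification admits imposters: a
probe whose best score falls below a threshold is rejected.  The
confusion counts are

* TP — genuine probe, best score >= threshold, truth within top k;
* FN — genuine probe otherwise (rejected, or truth ranked too low);
* FP — imposter probe with best score >= threshold;
* TN — imposter probe rejected;

with TPR = TP/(TP+FN), FPR = FP/(FP+TN), accuracy = (TP+TN)/N,
precision = TP/(TP+FP), F-score the harmonic mean of precision and
TPR, and baseline = (FP+TN)/N (the accuracy of rejecting everything).

Cross-validation follows the growing-database protocol: identities
with at least as many chips as folds are split per-identity into k
sections; each fold enrolls k-1 sections and probes with the held-out
one.  In the open protocol, identities too small for the filter are
pooled as imposter probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Gallery",
    "ProbeResult",
    "OpenSetMetrics",
    "pair_similarity",
    "individual_similarity",
    "rank_candidates",
    "closed_set_accuracy",
    "open_set_evaluate",
    "enroll_or_merge",
    "split_identity_folds",
    "cross_validate",
    "compare_models",
]

METRIC_FIELDS = ("TPR", "FPR", "FNR", "TNR", "baseline", "accuracy",
                 "precision", "f_score")


@dataclass
class Gallery:
    """Enrolled individuals: identity id -> list of unit embeddings."""

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    id_counter: int = 0

    def enroll(self, identity: str, embeddings: np.ndarray) -> None:
        embeddings = np.atleast_2d(np.asarray(embeddings))
        if identity in self.entries:
            self.entries[identity] = np.vstack(
                [self.entries[identity], embeddings])
        else:
            self.entries[identity] = embeddings

    def next_id(self, nickname: str = "") -> str:
        while True:
            candidate = f"{self.id_counter:03d}"
            self.id_counter += 1
            if nickname:
                candidate = f"{candidate}_{nickname}"
            if candidate not in self.entries:
                return candidate

    def __len__(self):
        return len(self.entries)


@dataclass
class ProbeResult:
    probe_id: str
    ranked: list[tuple[str, float]]  # (gallery_id, similarity) descending
    truth: str | None = None  # gallery id, or "imposter", or None

    @property
    def top_score(self) -> float:
        return self.ranked[0][1]

    def truth_rank(self) -> int | None:
        """1-based rank of the truth among candidates, None if absent."""
        for i, (gid, _) in enumerate(self.ranked):
            if gid == self.truth:
                return i + 1
        return None


@dataclass
class OpenSetMetrics:
    TPR: float
    FPR: float
    FNR: float
    TNR: float
    baseline: float
    accuracy: float
    precision: float
    f_score: float
    threshold: float = 0.0
    rank: int = 1
    counts: dict = field(default_factory=dict)


def pair_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two unit embeddings (their dot product)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("embeddings must be finite")
    return float(np.clip(np.dot(a, b), -1.0, 1.0))


def individual_similarity(probe_embeddings: np.ndarray,
                          gallery_embeddings: np.ndarray,
                          aggregate: str = "mean") -> float:
    """Aggregate all pairwise chip similarities between two individuals.

    Every probe chip is compared to every gallery chip; the pair scores
    are combined by the arithmetic mean (default) or the maximum.
    """
    p = np.atleast_2d(np.asarray(probe_embeddings, dtype=float))
    g = np.atleast_2d(np.asarray(gallery_embeddings, dtype=float))
    if p.size == 0 or g.size == 0:
        raise ValueError("both probe and gallery need at least one embedding")
    scores = np.clip(p @ g.T, -1.0, 1.0)
    if aggregate == "mean":
        return float(scores.mean())
    if aggregate == "max":
        return float(scores.max())
    raise ValueError(f"unknown aggregation {aggregate!r}")


def rank_candidates(probe_embeddings: np.ndarray, gallery: Gallery,
                    top_k: int = 5, probe_id: str = "probe",
                    truth: str | None = None,
                    aggregate: str = "mean") -> ProbeResult:
    """Rank gallery individuals against one probe folder.

    Ties are broken by ascending gallery id, making the ranking
    deterministic.
    """
    if not gallery.entries:
        raise ValueError("cannot rank against an empty gallery")
    scored = [(gid, individual_similarity(probe_embeddings, emb, aggregate))
              for gid, emb in gallery.entries.items()]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return ProbeResult(probe_id=probe_id, ranked=scored[:top_k], truth=truth)


def closed_set_accuracy(results: list[ProbeResult], k: int) -> float:
    """Fraction of probes whose truth appears within the top-k candidates."""
    if not results:
        raise ValueError("no probe results")
    hits = 0
    for r in results:
        if r.truth is None or r.truth == "imposter":
            raise ValueError(
                f"probe {r.probe_id!r} has no enrolled truth; "
                "closed-set accuracy requires every truth in the gallery")
        rank = r.truth_rank()
        hits += rank is not None and rank <= k
    return hits / len(results)


def open_set_evaluate(results: list[ProbeResult], threshold: float,
                      k: int = 1) -> OpenSetMetrics:
    """Confusion counts and derived rates at one threshold and rank."""
    tp = fn = fp = tn = 0
    for r in results:
        accepted = r.top_score >= threshold
        if r.truth == "imposter":
            fp += accepted
            tn += not accepted
        else:
            rank = r.truth_rank()
            if accepted and rank is not None and rank <= k:
                tp += 1
            else:
                fn += 1
    n_genuine, n_imposter = tp + fn, fp + tn
    total = n_genuine + n_imposter
    if total == 0:
        raise ValueError("no probe results")

    def rate(num, den):
        return num / den if den else float("nan")

    if n_genuine == 0 or n_imposter == 0:
        logger.warning("open-set evaluation without both genuine and "
                       "imposter probes; some rates are undefined (NaN)")
    tpr = rate(tp, n_genuine)
    precision = rate(tp, tp + fp) if (tp + fp) else float("nan")
    f_score = (2 * precision * tpr / (precision + tpr)
               if precision + tpr > 0 and math.isfinite(precision + tpr)
               else (0.0 if (tp + fp) and n_genuine else float("nan")))
    return OpenSetMetrics(
        TPR=tpr, FPR=rate(fp, n_imposter), FNR=rate(fn, n_genuine),
        TNR=rate(tn, n_imposter), baseline=(fp + tn) / total,
        accuracy=(tp + tn) / total, precision=precision, f_score=f_score,
        threshold=threshold, rank=k,
        counts={"TP": tp, "FP": fp, "FN": fn, "TN": tn})


def enroll_or_merge(gallery: Gallery, probe_embeddings: np.ndarray,
                    threshold: float = 0.5, nickname: str = "",
                    aggregate: str = "mean") -> tuple[Gallery, dict]:
    """Grow the database with one probe folder.

    If the best gallery individual scores at or above the threshold
    (``>=``: a probe exactly at threshold merges), the probe's chips
    join that identity; otherwise a new zero-padded id is created.
    Returns (gallery, decision record with top-5 scores).
    """
    probe_embeddings = np.atleast_2d(np.asarray(probe_embeddings))
    if not gallery.entries:
        new_id = gallery.next_id(nickname)
        gallery.enroll(new_id, probe_embeddings)
        return gallery, {"decision": "new", "identity": new_id, "top5": []}
    result = rank_candidates(probe_embeddings, gallery, top_k=5,
                             aggregate=aggregate)
    best_id, best_score = result.ranked[0]
    if best_score >= threshold:
        gallery.enroll(best_id, probe_embeddings)
        decision = {"decision": "merge", "identity": best_id,
                    "score": best_score, "top5": result.ranked}
    else:
        new_id = gallery.next_id(nickname)
        gallery.enroll(new_id, probe_embeddings)
        decision = {"decision": "new", "identity": new_id,
                    "score": best_score, "top5": result.ranked}
    logger.info("enroll_or_merge: %s -> %s", decision["decision"],
                decision["identity"])
    return gallery, decision


def split_identity_folds(chips_by_identity: dict[str, list], k_folds: int,
                         seed: int = 0, min_photos: int | None = None
                         ) -> tuple[list[dict[str, list]], dict[str, list]]:
    """Per-identity k-fold sections for the cross-validation protocol.

    Identities with at least ``min_photos`` chips (default: k_folds)
    are split into k sections of near-equal size (shuffled from the
    seed).  Returns (folds, smalls): ``folds[f]`` maps identity ->
    chip list of its f-th section; ``smalls`` holds the filtered-out
    identities (open-set imposters).
    """
    if min_photos is None:
        min_photos = k_folds
    rng = np.random.default_rng(seed)
    folds: list[dict[str, list]] = [{} for _ in range(k_folds)]
    smalls: dict[str, list] = {}
    for identity in sorted(chips_by_identity):
        chips = list(chips_by_identity[identity])
        if len(chips) < min_photos:
            smalls[identity] = chips
            continue
        perm = rng.permutation(len(chips))
        for j, idx in enumerate(perm):
            folds[j % k_folds].setdefault(identity, []).append(chips[idx])
    return folds, smalls


def cross_validate(chips_by_identity: dict[str, list], k_folds: int = 5,
                   protocol: str = "closed", seed: int = 0,
                   train_fn=None, threshold: float = 0.5,
                   rank_ks: tuple[int, ...] = (1, 5),
                   min_photos: int | None = None,
                   aggregate: str = "mean") -> dict:
    """K-fold evaluation of the recognition stage.

    ``train_fn(train_chips_by_identity, seed) -> embed_fn`` builds an
    embedding function ``embed_fn(list_of_chips) -> (N, 512) array``
    for each fold; by default it trains the embedding CNN with its
    default configuration.  Per fold, the k-1 training sections of each
    identity are enrolled as the gallery and the held-out section of
    each identity forms one genuine probe folder; in the open protocol,
    every identity below the photo filter probes as an imposter.

    Returns {"folds": [per-fold metric dict], "mean": ..., "sd": ...}
    with sample (n-1) standard deviations across folds.
    """
    if protocol not in ("closed", "open"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if train_fn is None:
        train_fn = _default_train_fn
    folds, smalls = split_identity_folds(chips_by_identity, k_folds, seed,
                                         min_photos)
    if not folds[0]:
        raise ValueError(
            f"no identity has >= {min_photos or k_folds} chips; "
            "nothing to cross-validate")
    per_fold = []
    for f in range(k_folds):
        train_chips: dict[str, list] = {}
        for j in range(k_folds):
            if j == f:
                continue
            for identity, chips in folds[j].items():
                train_chips.setdefault(identity, []).extend(chips)
        embed_fn = train_fn(train_chips, seed + f)
        gallery = Gallery()
        for identity in sorted(train_chips):
            gallery.enroll(identity, embed_fn(train_chips[identity]))
        results = []
        for identity in sorted(folds[f]):
            emb = embed_fn(folds[f][identity])
            results.append(rank_candidates(
                emb, gallery, top_k=len(gallery), probe_id=identity,
                truth=identity, aggregate=aggregate))
        if protocol == "closed":
            row = {f"rank{k}": closed_set_accuracy(results, k)
                   for k in rank_ks}
        else:
            for identity in sorted(smalls):
                emb = embed_fn(smalls[identity])
                results.append(rank_candidates(
                    emb, gallery, top_k=len(gallery), probe_id=identity,
                    truth="imposter", aggregate=aggregate))
            row = {}
            for k in rank_ks:
                metrics = open_set_evaluate(results, threshold, k)
                for name in METRIC_FIELDS:
                    row[f"rank{k}_{name}"] = getattr(metrics, name)
        per_fold.append(row)
        logger.info("fold %d/%d: %s", f + 1, k_folds, row)
    keys = per_fold[0].keys()
    mean = {k: float(np.mean([row[k] for row in per_fold])) for k in keys}
    sd = {k: float(np.std([row[k] for row in per_fold], ddof=1)) for k in keys}
    return {"folds": per_fold, "mean": mean, "sd": sd,
            "protocol": protocol, "k_folds": k_folds}


def _default_train_fn(train_chips_by_identity, seed):
    from .recognition import (EmbedderConfig, build_embedder, embed_chips,
                              train_embedder)
    config = EmbedderConfig(seed=seed)
    model = build_embedder(config)
    train_embedder(model, train_chips_by_identity, config)
    return lambda chips: embed_chips(model, chips)


def compare_models(table_a: OpenSetMetrics, table_b: OpenSetMetrics) -> dict:
    """Per-metric difference A - B of two open-set metric tables."""
    if table_a.rank != table_b.rank:
        raise ValueError(
            f"cannot compare metrics at different ranks "
            f"({table_a.rank} vs {table_b.rank})")
    return {name: getattr(table_a, name) - getattr(table_b, name)
            for name in METRIC_FIELDS}
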