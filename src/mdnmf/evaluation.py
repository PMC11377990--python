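"""Cross-validation protocols, ranking metrics and case-study modes.

All protocols hold out *known* associations, retrain the whole pipeline on
the masked matrix — including the GIP kernels and Laplacians, which change
when associations are removed — and rank the held-out pairs against the
candidate set, defined as every pair that is 0 in the ORIGINAL matrix
(held-out positives are never counted as candidates).  One AUC/AUPR is
computed per repetition by pooling the held-out scores of all folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import DegenerateInputError, ParameterError
from .io import AssociationData
from .model import MicrobeDiseaseNMF

__all__ = [
    "CvReport",
    "auc",
    "aupr",
    "global_loocv",
    "kfold_cv",
    "rank_candidates_for_disease",
    "ablation_suite",
    "ABLATION_MODES",
]

ABLATION_MODES = {
    "full": {},
    "abs_svd_init": {"init": "abs_svd"},
    "no_graph_m": {"lambda_m": 0.0},
    "no_graph_d": {"lambda_d": 0.0},
    "no_l21": {"lambda_l": 0.0},
    "no_inertia": {"inertia": "none"},
}


@dataclass
class CvReport:
    """Per-repetition AUC/AUPR values with seeds and summary statistics."""

    scheme: str
    n_repeats: int
    seed: int
    auc_values: list[float] = field(default_factory=list)
    aupr_values: list[float] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_values, ddof=1)) if len(self.auc_values) > 1 else 0.0

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.aupr_values))

    @property
    def sd_aupr(self) -> float:
        return float(np.std(self.aupr_values, ddof=1)) if len(self.aupr_values) > 1 else 0.0


def auc(pos_scores, neg_scores) -> float:
    """Rank-based (Mann-Whitney) AUC: P(pos > neg) with ties counted half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ParameterError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def aupr(pos_scores, neg_scores) -> float:
    """Area under the precision-recall curve (step-wise average precision).

    Thresholds sweep the unique scores in descending order; tied scores
    enter as one group, so the all-tied case gives the prevalence
    p / (p + n).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ParameterError("both score lists must be non-empty")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # group boundaries: last index of each tied block
    boundary = np.flatnonzero(np.diff(scores) != 0)
    last = np.append(boundary, scores.size - 1)
    tp = np.cumsum(labels)[last]
    total = last + 1.0
    precision = tp / total
    recall = tp / pos.size
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def _default_score_fn(model_kwargs):
    kwargs = dict(model_kwargs or {})

    def score(masked: AssociationData) -> np.ndarray:
        return MicrobeDiseaseNMF(masked, **kwargs).fit().scores

    return score


def global_loocv(
    data: AssociationData,
    model_kwargs: dict | None = None,
    *,
    score_fn=None,
    fast: bool = False,
    fold_callback=None,
) -> CvReport:
    """Global leave-one-out over known associations.

    Each known pair is removed in turn, the pipeline retrained on the masked
    matrix (similarities recomputed), and the held-out pair's score pooled
    against the scores of all original-zero pairs from the same run.

    ``fast=True`` trains a single model on the unmasked matrix — a smoke-test
    shortcut whose positives were seen in training; never protocol-faithful.
    """
    pairs = data.known_pairs()
    if len(pairs) < 2:
        raise DegenerateInputError("global LOOCV needs at least 2 known associations")
    score_fn = score_fn or _default_score_fn(model_kwargs)
    neg_mask = data.A == 0
    report = CvReport(scheme="global_loocv", n_repeats=1, seed=0)

    if fast:
        scores = score_fn(data)
        pos = [scores[i, j] for i, j in pairs]
        neg = scores[neg_mask].tolist()
    else:
        pos: list[float] = []
        neg: list[float] = []
        for i, j in pairs:
            masked = data.masked([(i, j)])
            if masked.A.sum() == 0:
                raise DegenerateInputError("masked matrix is all-zero")
            if fold_callback is not None:
                fold_callback(masked, [(i, j)])
            scores = score_fn(masked)
            pos.append(float(scores[i, j]))
            neg.extend(scores[neg_mask].tolist())
    report.auc_values.append(auc(pos, neg))
    report.aupr_values.append(aupr(pos, neg))
    return report


def _fold_split(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle 0..n-1 and split into n_folds near-equal parts."""
    return [np.sort(part) for part in np.array_split(rng.permutation(n), n_folds)]


def kfold_cv(
    data: AssociationData,
    model_kwargs: dict | None = None,
    *,
    n_folds: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
    score_fn=None,
    fold_callback=None,
) -> CvReport:
    """Repeated k-fold cross-validation over known associations.

    Per repetition the known pairs are shuffled with seed ``seed + repeat``
    and split into ``n_folds`` near-equal parts; each part is masked in turn,
    the pipeline retrained on the masked matrix, and the held-out scores
    pooled with the candidate (original-zero) scores of the same fold model.
    One AUC/AUPR per repetition; the report carries mean and sd over
    repetitions.
    """
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    pairs = data.known_pairs()
    if len(pairs) < n_folds:
        raise ParameterError(f"need >= {n_folds} known associations, have {len(pairs)}")
    score_fn = score_fn or _default_score_fn(model_kwargs)
    neg_mask = data.A == 0
    report = CvReport(scheme="kfold", n_repeats=n_repeats, seed=seed)
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed + rep)
        folds = _fold_split(len(pairs), n_folds, rng)
        pos: list[float] = []
        neg: list[float] = []
        for fold in folds:
            held = [pairs[t] for t in fold]
            masked = data.masked(held)
            if fold_callback is not None:
                fold_callback(masked, held)
            scores = score_fn(masked)
            pos.extend(float(scores[i, j]) for i, j in held)
            neg.extend(scores[neg_mask].tolist())
        report.auc_values.append(auc(pos, neg))
        report.aupr_values.append(aupr(pos, neg))
    return report


def rank_candidates_for_disease(
    data: AssociationData,
    disease: str,
    model_kwargs: dict | None = None,
    *,
    top_k: int = 10,
    zero_out: bool = False,
) -> list[tuple[str, float]]:
    """Top-k candidate microbes for one disease.

    With ``zero_out`` the disease's column is blanked before similarity
    computation and training (the new-disease setting: its GIP profile is
    all-zero but the kernels remain defined) and all microbes compete;
    otherwise microbes already associated with the disease are excluded.
    Ties break towards the lower microbe index.
    """
    if disease not in data.disease_index:
        raise ParameterError(f"unknown disease: {disease!r}")
    j = data.disease_index[disease]
    train = data
    if zero_out:
        train = data.masked([(i, j) for i in np.flatnonzero(data.A[:, j])])
    results = MicrobeDiseaseNMF(train, **dict(model_kwargs or {})).fit()
    return results.rank_microbes(disease, top_k=top_k, exclude_known=not zero_out)


def ablation_suite(
    data: AssociationData,
    modes=("full", "abs_svd_init", "no_graph_m", "no_graph_d", "no_l21", "no_inertia"),
    model_kwargs: dict | None = None,
    *,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
) -> dict[str, CvReport]:
    """Run k-fold CV once per ablation mode with identical seeds (paired folds)."""
    base = dict(model_kwargs or {})
    out: dict[str, CvReport] = {}
    for mode in modes:
        if mode not in ABLATION_MODES:
            raise ParameterError(f"unknown ablation mode: {mode!r}")
        kwargs = {**base, **ABLATION_MODES[mode]}
        out[mode] = kfold_cv(
            data, kwargs, n_folds=n_folds, n_repeats=n_repeats, seed=seed
        )
    return out
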