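"""Multiple-instance learning of an adaptive-cosine-estimator target.

Bags are whole broccoli samples (their pixel spectra are the instances),
labeled positive when the sample's glucosinolate concentration reaches a
threshold. The fit learns a discriminative target signature in background-
whitened space by alternating max-scoring instance selection in positive
bags with a closed-form signature update; pixel confidences are whitened
cosine similarities to the target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DegenerateDataError,
    FeatureVector,
    InvalidParameterError,
    SpectraMatrix,
)

__all__ = [
    "Bag",
    "MiaceParams",
    "WhitenTransform",
    "TargetSignature",
    "make_bags",
    "fit_whitening",
    "ace_score",
    "ace_scores",
    "miace_fit",
    "confidence_feature",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 50.0


@dataclass(frozen=True)
class MiaceParams:
    threshold: float = DEFAULT_THRESHOLD
    regularization: Optional[float] = None  # None -> 1e-6 * trace / B
    max_iter: int = 50
    seed: int = 0


@dataclass
class Bag:
    """All pixel spectra of one sample plus its bag-level label."""

    instances: SpectraMatrix
    label: int
    sample_id: str = ""

    def __post_init__(self):
        if self.instances.n_spectra < 1:
            raise InvalidParameterError("bag must contain at least one instance")
        if self.label not in (0, 1):
            raise InvalidParameterError("bag label must be 0 or 1")


@dataclass
class WhitenTransform:
    """Background mean and eigendecomposed covariance: x -> D^-1/2 U'(x - mu)."""

    mean: np.ndarray
    eigvecs: np.ndarray
    eigvals: np.ndarray
    regularization: float = 0.0

    def __post_init__(self):
        if np.any(self.eigvals + self.regularization <= 0):
            raise DegenerateDataError(
                "background covariance is singular; increase regularization"
            )

    def whiten(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        scaled = (x - self.mean) @ self.eigvecs
        return scaled / np.sqrt(self.eigvals + self.regularization)


@dataclass
class TargetSignature:
    """Unit-norm target in whitened coordinates plus reporting extras."""

    t: np.ndarray
    objective: float = np.nan
    background: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).ravel()
        norm = np.linalg.norm(self.t)
        if abs(norm - 1.0) > 1e-9:
            raise InvalidParameterError("target must be unit norm in whitened space")


def make_bags(samples: Sequence[Tuple[SpectraMatrix, float]],
              threshold: float = DEFAULT_THRESHOLD,
              sample_ids: Optional[Sequence[str]] = None) -> List[Bag]:
    """Label bags positive (less fresh) iff concentration >= threshold."""
    if not np.isfinite(threshold):
        raise InvalidParameterError("threshold must be finite")
    bags = []
    for i, (spectra, conc) in enumerate(samples):
        sid = sample_ids[i] if sample_ids is not None else f"bag{i}"
        bags.append(Bag(instances=spectra, label=int(conc >= threshold),
                        sample_id=sid))
    return bags


def fit_whitening(negative_bags: Sequence[Bag],
                  regularization: Optional[float] = None) -> WhitenTransform:
    """Whitening from the pooled instances of all negative bags."""
    negatives = [b for b in negative_bags if b.label == 0]
    if not negatives:
        raise InvalidParameterError("need at least one negative bag")
    x = np.vstack([b.instances.values for b in negatives])
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / max(x.shape[0] - 1, 1)
    if regularization is None:
        regularization = 1e-6 * np.trace(cov) / cov.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.any(eigvals + regularization <= 1e-15 * max(np.max(eigvals), 1.0)):
        raise DegenerateDataError(
            "singular background covariance; provide regularization > 0"
        )
    return WhitenTransform(mean=mean, eigvecs=eigvecs, eigvals=eigvals,
                           regularization=float(regularization))


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    zero = norms.ravel() == 0
    if np.any(zero):
        warnings.warn("zero whitened vector scored as 0", stacklevel=3)
        norms = np.where(norms == 0, 1.0, norms)
    out = x / norms
    out[zero] = 0.0
    return out


def ace_scores(x: np.ndarray, t: TargetSignature, w: WhitenTransform
               ) -> np.ndarray:
    """Whitened cosine similarity between each row of x and the target."""
    t_hat = t.t / np.linalg.norm(t.t)
    x_hat = _unit_rows(w.whiten(x))
    return x_hat @ t_hat


def ace_score(x: np.ndarray, t: TargetSignature, w: WhitenTransform) -> float:
    """Confidence in [-1, 1] for a single spectrum."""
    return float(ace_scores(np.atleast_2d(x), t, w)[0])


def _objective(t_hat: np.ndarray, pos_hat: List[np.ndarray],
               neg_hat: np.ndarray) -> Tuple[float, List[int]]:
    pos_scores = [ph @ t_hat for ph in pos_hat]
    picks = [int(np.argmax(s)) for s in pos_scores]
    pos_term = float(np.mean([s[k] for s, k in zip(pos_scores, picks)]))
    neg_term = float(np.mean(neg_hat @ t_hat)) if neg_hat.size else 0.0
    return pos_term - neg_term, picks


def miace_fit(bags: Sequence[Bag], params: Optional[MiaceParams] = None
              ) -> Tuple[TargetSignature, WhitenTransform]:
    """Learn the discriminative target signature from labeled bags.

    Maximizes mean over positive bags of the best instance score minus the
    mean score of all negative instances, alternating instance selection
    with the closed-form update
    t ~ mean(selected positives, unit-whitened) - mean(negatives,
    unit-whitened), until the selected-instance set repeats.
    """
    p = params or MiaceParams()
    positives = [b for b in bags if b.label == 1]
    negatives = [b for b in bags if b.label == 0]
    if not positives:
        raise InvalidParameterError("need at least one positive bag")
    if not negatives:
        raise InvalidParameterError("need at least one negative bag")

    w = fit_whitening(negatives, p.regularization)
    pos_hat = [_unit_rows(w.whiten(b.instances.values)) for b in positives]
    neg_hat = _unit_rows(w.whiten(
        np.vstack([b.instances.values for b in negatives])))
    neg_mean_hat = neg_hat.mean(axis=0)

    # initialize with the positive instance that scores the best objective
    best_obj, best_t = -np.inf, None
    for ph in pos_hat:
        # objective of every candidate instance in this bag, vectorized:
        # mean over bags of the max instance score, minus the negative mean
        pos_term = np.mean([(q @ ph.T).max(axis=0) for q in pos_hat], axis=0)
        obj_per_cand = pos_term - neg_mean_hat @ ph.T
        j = int(np.argmax(obj_per_cand))
        if obj_per_cand[j] > best_obj:
            best_obj = float(obj_per_cand[j])
            best_t = ph[j].copy()
    t_hat = best_t / np.linalg.norm(best_t)

    seen = set()
    obj, picks = _objective(t_hat, pos_hat, neg_hat)
    history = [obj]
    for _ in range(p.max_iter):
        key = tuple(picks)
        if key in seen:
            break
        seen.add(key)
        selected = np.vstack([ph[k] for ph, k in zip(pos_hat, picks)])
        new_t = selected.mean(axis=0) - neg_mean_hat
        norm = np.linalg.norm(new_t)
        if norm < 1e-12:
            log.warning("non-discriminative bags: target update collapsed to 0")
            break
        new_t /= norm
        new_obj, new_picks = _objective(new_t, pos_hat, neg_hat)
        if new_obj < obj - 1e-12:
            break
        t_hat, obj, picks = new_t, new_obj, new_picks
        history.append(obj)

    background = np.vstack(
        [b.instances.values for b in negatives]).mean(axis=0)
    sig = TargetSignature(t=t_hat, objective=obj, background=background)
    sig.objective_history = history
    if abs(obj) < 1e-6:
        log.warning("objective ~ 0: bags look non-discriminative")
    return sig, w


def confidence_feature(sample: SpectraMatrix, t: TargetSignature,
                       w: WhitenTransform, sample_id: str = "") -> FeatureVector:
    """Single-value feature: mean confidence over the sample's pixels."""
    if sample.n_spectra < 1:
        raise InvalidParameterError("cannot score an empty sample")
    scores = ace_scores(sample.values, t, w)
    return FeatureVector(values=np.array([scores.mean()]), sample_id=sample_id)
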