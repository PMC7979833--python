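"""Expected red-shift gain and candidate ranking.

A candidate's predictive distribution f(x) is the set of Gibbs draws
μ^(t) + β^(t)ᵀx.  Its red-shift gain against the subfamily base wavelength
λ_base is max(f(x) − λ_base, 0), and the screening criterion is the
posterior-mean gain estimated by the truncated-mean Monte-Carlo average

    E[gain] ≈ (1/T) Σ_t max(μ^(t) + β^(t)ᵀx − λ_base, 0).

Because the truncation is convex, E[gain] rewards both a long predictive
mean (exploitation) and a wide predictive spread (exploration), which is
what makes it a useful acquisition criterion for choosing which genes to
synthesize next.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .blasso import PosteriorSamples
from .encoding import EncodedSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateScore:
    """Predictive summary and expected gain for one candidate."""

    id: str
    subfamily: str | None
    lambda_base: float
    pred_mean: float
    pred_sd: float
    expected_gain: float
    prob_positive_gain: float
    mc_standard_error: float
    matches_training: bool = False


@dataclass(frozen=True)
class ScreeningResult:
    """Ranked candidates plus the strictly-above-threshold selection."""

    ranked: tuple[CandidateScore, ...]
    selected: tuple[CandidateScore, ...]
    unscored: tuple[str, ...]
    threshold: float


def predictive_draws(posterior: PosteriorSamples, x: EncodedSample) -> np.ndarray:
    """Per-draw predictions μ^(t) + β^(t)ᵀx for a standardized candidate.

    If the posterior carries a standardizer, the candidate must have been
    transformed with the identical one (hash check).
    """
    if posterior.standardizer is not None:
        if x.standardizer_hash != posterior.standardizer.hash:
            raise ValueError(
                f"candidate {x.id!r} was not standardized with the training "
                "standardizer (hash mismatch)"
            )
    if len(x.x) != posterior.n_features:
        raise ValueError(
            f"candidate {x.id!r}: feature length {len(x.x)} != "
            f"{posterior.n_features}"
        )
    return posterior.mu + posterior.beta @ x.x


def expected_gain(
    draws: np.ndarray, lambda_base: float
) -> tuple[float, float, float]:
    """Truncated-mean gain estimator from predictive draws.

    Returns ``(expected_gain, prob_positive_gain, mc_standard_error)`` where
    the estimator averages max(draw − λ_base, 0), the probability is the
    fraction of draws exceeding λ_base, and the MC standard error is the
    sample SD of the truncated values over √T.
    """
    draws = np.asarray(draws, dtype=float)
    T = draws.size
    if T < 1:
        raise ValueError("need at least one predictive draw")
    trunc = np.maximum(draws - lambda_base, 0.0)
    eg = float(trunc.mean())
    prob = float(np.mean(draws > lambda_base))
    se = float(trunc.std(ddof=1) / np.sqrt(T)) if T > 1 else 0.0
    return eg, prob, se


def score_candidates(
    posterior: PosteriorSamples,
    candidates: Sequence[EncodedSample],
    base_wavelengths: Mapping[str, float],
    training_pocket_strings: set[str] | None = None,
) -> tuple[list[CandidateScore], list[str]]:
    """Score every candidate with a known subfamily base wavelength.

    Candidates whose subfamily has no entry in ``base_wavelengths`` are
    returned in the second (unscored) list with a logged warning.
    Candidates whose pocket string occurs in the training set are flagged
    (``matches_training``) so the caller can exclude already-characterized
    sequences, as one would when screening for genuinely new genes.
    """
    scores: list[CandidateScore] = []
    unscored: list[str] = []
    for cand in candidates:
        lb = base_wavelengths.get(cand.subfamily) if cand.subfamily else None
        if lb is None:
            logger.warning(
                "candidate %s: unknown subfamily %r, no base wavelength — skipped",
                cand.id, cand.subfamily,
            )
            unscored.append(cand.id)
            continue
        draws = predictive_draws(posterior, cand)
        eg, prob, se = expected_gain(draws, lb)
        dup = bool(
            training_pocket_strings
            and cand.pocket_string is not None
            and cand.pocket_string in training_pocket_strings
        )
        scores.append(
            CandidateScore(
                id=cand.id,
                subfamily=cand.subfamily,
                lambda_base=lb,
                pred_mean=float(draws.mean()),
                pred_sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                expected_gain=eg,
                prob_positive_gain=prob,
                mc_standard_error=se,
                matches_training=dup,
            )
        )
    return scores, unscored


def rank_candidates(
    scores: Sequence[CandidateScore],
    threshold: float = 10.0,
    subfamily_whitelist: Sequence[str] | None = None,
    unscored: Sequence[str] = (),
) -> ScreeningResult:
    """Sort by expected gain (descending, ties broken by id ascending) and
    select the candidates with expected gain strictly above ``threshold`` nm.

    ``subfamily_whitelist`` optionally restricts the selection to given
    subfamilies (e.g. the light-driven ion-pump ones) before the cut.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    ranked = tuple(sorted(scores, key=lambda s: (-s.expected_gain, s.id)))
    pool = ranked
    if subfamily_whitelist is not None:
        allowed = set(subfamily_whitelist)
        pool = tuple(s for s in ranked if s.subfamily in allowed)
    selected = tuple(s for s in pool if s.expected_gain > threshold)
    return ScreeningResult(
        ranked=ranked,
        selected=selected,
        unscored=tuple(unscored),
        threshold=threshold,
    )


def result_to_frame(result: ScreeningResult):
    """Ranking table with a ``selected`` flag, ready to write as TSV."""
    import pandas as pd

    sel_ids = {s.id for s in result.selected}
    rows = [
        {
            "id": s.id,
            "subfamily": s.subfamily,
            "lambda_base": s.lambda_base,
            "pred_mean": s.pred_mean,
            "pred_sd": s.pred_sd,
            "expected_gain": s.expected_gain,
            "prob_positive_gain": s.prob_positive_gain,
            "mc_se": s.mc_standard_error,
            "matches_training": s.matches_training,
            "selected": s.id in sel_ids,
        }
        for s in result.ranked
    ]
    return pd.DataFrame(rows)
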