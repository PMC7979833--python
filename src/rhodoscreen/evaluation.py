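"""Statistical evaluation of a completed screen.

Given per-candidate observed λmax values and their subfamily base
wavelengths, this module counts red/blue/unchanged outcomes, summarizes
observed truncated gains max(λmax − λ_base, 0), and tests whether the
red-shift success rate beats the 50% expected under random gene choice
with an exact binomial test.  A PCA projection of encoded feature vectors
is provided as a reporting diagnostic of how candidates spread relative to
the training data in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import EncodedSample


@dataclass(frozen=True)
class ScreenOutcome:
    """One experimentally characterized candidate."""

    id: str
    subfamily: str | None
    lambda_base: float
    observed_lambda: float
    expected_gain_at_selection: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_base) and np.isfinite(self.observed_lambda)):
            raise ValueError(f"outcome {self.id!r}: non-finite wavelength")

    @property
    def observed_gain(self) -> float:
        return max(self.observed_lambda - self.lambda_base, 0.0)


@dataclass(frozen=True)
class ScreenSummary:
    n_total: int
    n_red_shifted: int
    n_blue_shifted: int
    n_unchanged: int
    n_gain_ge: dict[float, int]
    mean_observed_gain: float
    mean_expected_gain: float | None
    max_observed_lambda: float
    binomial_p: float


def binomial_test_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact binomial p-value: the total probability of outcomes no more
    likely than the observed count (for p0 = 0.5 this equals twice the
    smaller tail, capped at 1).  Computed from exact binomial pmf values;
    no normal approximation."""
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability p0 must lie in (0, 1), got {p0}")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    # relative slack guards against ties broken by floating-point noise
    p = float(pmf[pmf <= pmf[k] * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


def binomial_test_one_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail p-value P[X >= k] under Binomial(n, p0)."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability p0 must lie in (0, 1), got {p0}")
    return float(min(stats.binom.sf(k - 1, n, p0), 1.0))


def summarize_screen(
    outcomes: Sequence[ScreenOutcome],
    thresholds: Sequence[float] = (20.0,),
    p0: float = 0.5,
) -> ScreenSummary:
    """Counts, gain means and the exact binomial p-value for a screen.

    Red-shifted means observed strictly above base; unchanged outcomes count
    as failures in the binomial test (n is not reduced).  Gain thresholds use
    >= semantics on the truncated observed gain.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    diffs = np.array([o.observed_lambda - o.lambda_base for o in outcomes])
    gains = np.maximum(diffs, 0.0)
    n = len(outcomes)
    n_red = int(np.sum(diffs > 0))
    n_blue = int(np.sum(diffs < 0))
    n_unchanged = n - n_red - n_blue
    egains = [o.expected_gain_at_selection for o in outcomes]
    mean_eg = (
        float(np.mean([e for e in egains if e is not None]))
        if any(e is not None for e in egains)
        else None
    )
    return ScreenSummary(
        n_total=n,
        n_red_shifted=n_red,
        n_blue_shifted=n_blue,
        n_unchanged=n_unchanged,
        n_gain_ge={float(t): int(np.sum(gains >= t)) for t in thresholds},
        mean_observed_gain=float(gains.mean()),
        mean_expected_gain=mean_eg,
        max_observed_lambda=float(max(o.observed_lambda for o in outcomes)),
        binomial_p=binomial_test_two_sided(n_red, n, p0),
    )


def read_outcomes(path: str | Path) -> list[ScreenOutcome]:
    """Read an outcomes table (id, subfamily, lambda_base, observed_lambda,
    optional expected_gain)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, row in df.iterrows():
        eg = row.get("expected_gain")
        out.append(
            ScreenOutcome(
                id=str(row["id"]),
                subfamily=str(row["subfamily"]) if "subfamily" in df.columns else None,
                lambda_base=float(row["lambda_base"]),
                observed_lambda=float(row["observed_lambda"]),
                expected_gain_at_selection=None if pd.isna(eg) else float(eg),
            )
        )
    return out


def round_half_even(x: float, decimals: int = 1) -> float:
    """One-decimal reporting convention for gain means (banker's rounding)."""
    return float(np.round(x, decimals))


def pca_projection(
    samples: Sequence[EncodedSample], n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of encoded samples.

    Returns ``(coordinates, explained_variance_ratios)``.  Component signs
    follow a fixed convention: the largest-magnitude loading of each
    component is made positive, so projections are reproducible across
    library versions.
    """
    from sklearn.decomposition import PCA

    if len(samples) < max(3, n_components):
        raise ValueError(
            f"need at least {max(3, n_components)} samples for a "
            f"{n_components}-component projection"
        )
    X = np.stack([s.x for s in samples])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    for j, comp in enumerate(pca.components_):
        lead = np.argmax(np.abs(comp))
        if comp[lead] < 0:
            coords[:, j] *= -1.0
    return coords, pca.explained_variance_ratio_
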