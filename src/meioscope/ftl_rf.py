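"""Map distance from fluorescent-seed counts.

In a two-color seed reporter system, two linked fluorescent cassettes
delimit a genomic interval; single-fluorescent seeds are recombinants.  With
``n_g`` green-only and ``n_r`` red-only seeds out of ``n_total``, the map
distance in centimorgans is

    RF = 100 * (1 - sqrt(1 - 2 * (n_g + n_r) / n_total)).

Double-fluorescent and non-fluorescent seeds enter only through the total.
The estimator's domain ends where the single-fluorescent fraction reaches
1/2 (RF = 50 cM); beyond that the closed form is undefined and an error is
raised rather than clamping.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .models import SeedCounts

__all__ = ["recombination_frequency", "rf_bootstrap_ci"]


def recombination_frequency(counts: SeedCounts) -> float:
    """Map distance (cM) from fluorescent-seed counts via the closed form."""
    frac = 2.0 * (counts.n_green + counts.n_red) / counts.n_total
    if frac > 1.0:
        raise ValueError("estimator undefined (single-fluorescent fraction > 1/2)")
    return 100.0 * (1.0 - math.sqrt(1.0 - frac))


def rf_bootstrap_ci(
    counts: SeedCounts,
    iters: int = 1000,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the map distance.

    Seed classes (green-only, red-only, other) are resampled multinomially.
    Resamples whose single-fluorescent fraction exceeds 1/2 are clamped to
    RF = 100 (they occur only near the domain boundary).
    """
    if iters < 100:
        warnings.warn(f"iters={iters} < 100 gives an unstable interval", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(0)
    n = counts.n_total
    p = [
        counts.n_green / n,
        counts.n_red / n,
        1.0 - (counts.n_green + counts.n_red) / n,
    ]
    draws = rng.multinomial(n, p, size=iters)
    frac = 2.0 * (draws[:, 0] + draws[:, 1]) / n
    rf = 100.0 * (1.0 - np.sqrt(np.clip(1.0 - frac, 0.0, None)))
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(rf, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high)
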