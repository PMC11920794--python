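"""Cis-double-crossover distances, gamma fits, bootstrap, and CoC profiles.

A *cis*-double crossover (cis-DCO) is a parental-heterozygous-parental
genotype run (P1-H-P1 or P2-H-P2) along one chromosome of one F2 individual;
its length is the distance between the midpoints of the two flanking
genotype transitions.  Because the flanking parental states must match,
such a run corresponds to two consecutive crossovers on a single transmitted
chromatid, so the distances carry the signature of crossover interference.

The expected (no-interference) distances are built per chromosome by drawing
two sets of ``n_sample`` crossover midpoints with replacement from all
identified crossovers and pairing each first-set midpoint with a uniformly
chosen second-set midpoint.  Gamma distributions are fitted to observed and
expected distances by maximum likelihood; interference strength is the gamma
shape.  Significance uses a Mann-Whitney U test on bootstrap distributions
of the fitted shape.  The coefficient of coincidence (CoC) divides the
binned observed distance frequencies by expected frequencies rescaled to the
same total: CoC ~ 1 means independent crossovers, < 1 positive interference,
> 1 clustering (negative interference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .models import CoCProfile, GammaFit

logger = logging.getLogger(__name__)

__all__ = [
    "extract_cis_dcos",
    "crossover_midpoints",
    "sample_expected_distances",
    "expected_null_distances",
    "fit_gamma",
    "bootstrap_shape",
    "compare_shape_distributions",
    "compare_distance_sets",
    "compute_coc",
    "analyze_interference",
    "InterferenceReport",
]

SHAPE_CAP = 1e6


# ---------------------------------------------------------------------------
# cis-DCO extraction and the randomized null


def extract_cis_dcos(segments: pd.DataFrame) -> pd.DataFrame:
    """Distances between the transitions of every P-H-P segment triple.

    Only matching-parental triples (P1-H-P1, P2-H-P2) are counted; P1-H-P2
    runs and H-P-H runs are not cis-DCOs.  Returns a table (individual,
    chrom, t1, t2, distance) where t1/t2 are the two transition midpoints.
    """
    rows = []
    if len(segments):
        for (ind, chrom), grp in segments.groupby(["individual", "chrom"], sort=False):
            g = grp.sort_values("start").reset_index(drop=True)
            for j in range(len(g) - 2):
                s1, s2, s3 = g.loc[j], g.loc[j + 1], g.loc[j + 2]
                if s2["state"] != "H":
                    continue
                if s1["state"] != s3["state"] or s1["state"] not in ("P1", "P2"):
                    continue
                t1 = (s1["end"] + s2["start"]) / 2.0
                t2 = (s2["end"] + s3["start"]) / 2.0
                rows.append((ind, chrom, t1, t2, t2 - t1))
    return pd.DataFrame(rows, columns=["individual", "chrom", "t1", "t2", "distance"])


def crossover_midpoints(events: pd.DataFrame) -> dict[str, np.ndarray]:
    """All identified crossover midpoints per chromosome."""
    return {
        chrom: grp["midpoint"].to_numpy(dtype=float)
        for chrom, grp in events.groupby("chrom", sort=False)
    }


def sample_expected_distances(
    midpoints: np.ndarray, n_sample: int = 400, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Expected inter-crossover distances for one chromosome.

    Two sets of ``n_sample`` midpoints are drawn with replacement; each
    first-set midpoint is paired with a uniformly chosen second-set midpoint
    and the absolute distance recorded (zero distances from self-pairing are
    retained).  Chromosomes with fewer than two distinct midpoints are
    skipped with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    midpoints = np.asarray(midpoints, dtype=float)
    if np.unique(midpoints).size < 2:
        warnings.warn("fewer than 2 distinct midpoints; chromosome skipped", stacklevel=2)
        return np.empty(0)
    set1 = rng.choice(midpoints, size=n_sample, replace=True)
    set2 = rng.choice(midpoints, size=n_sample, replace=True)
    pick = rng.integers(0, n_sample, size=n_sample)
    return np.abs(set1 - set2[pick])


def expected_null_distances(
    events: pd.DataFrame, n_sample: int = 400, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Pooled expected distances over all chromosomes of one genotype."""
    if rng is None:
        rng = np.random.default_rng(0)
    parts = [
        sample_expected_distances(mids, n_sample, rng)
        for mids in crossover_midpoints(events).values()
    ]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# gamma fitting


def _prepare_positive(x: np.ndarray) -> np.ndarray:
    """Replace zero distances by half the smallest positive one (logged)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("distances must be >= 0")
    if (x == 0).any():
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("all distances are zero; gamma fit undefined")
        n_zero = int((x == 0).sum())
        logger.info("replacing %d zero distances by half the minimum positive", n_zero)
        x = np.where(x == 0, positive.min() / 2.0, x)
    return x


def _shape_from_spread(s):
    """Gamma MLE shape from s = log(mean) - mean(log): Newton iteration on
    log(a) - digamma(a) = s, started from the standard closed-form
    approximation.  Vectorized; degenerate s <= 0 maps to the shape cap."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    a = np.empty_like(s)
    degenerate = s <= 0
    ok = ~degenerate
    a[degenerate] = SHAPE_CAP
    if ok.any():
        sv = s[ok]
        av = (3.0 - sv + np.sqrt((sv - 3.0) ** 2 + 24.0 * sv)) / (12.0 * sv)
        for _ in range(40):
            f = np.log(av) - special.digamma(av) - sv
            fprime = 1.0 / av - special.polygamma(1, av)
            step = f / fprime
            av_new = av - step
            av_new = np.where(av_new <= 0, av / 2.0, av_new)
            if np.max(np.abs(av_new - av) / av) < 1e-12:
                av = av_new
                break
            av = av_new
        a[ok] = np.minimum(av, SHAPE_CAP)
    return a


def fit_gamma(distances: np.ndarray) -> GammaFit:
    """Two-parameter gamma MLE (no location shift) of a distance sample.

    Zero distances are replaced by half the smallest positive distance.
    Requires n >= 10.  A degenerate (constant) sample drives the shape to
    infinity; it is capped at 1e6 with a warning.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 10:
        raise ValueError(f"insufficient data for gamma fit (n={x.size} < 10)")
    x = _prepare_positive(x)
    mean = x.mean()
    s = np.log(mean) - np.mean(np.log(x))
    shape = float(_shape_from_spread(s)[0])
    if shape >= SHAPE_CAP:
        warnings.warn("degenerate sample: gamma shape capped at 1e6", stacklevel=2)
    rate = shape / mean
    loglik = float(stats.gamma.logpdf(x, a=shape, scale=1.0 / rate).sum())
    return GammaFit(shape=shape, rate=rate, loglik=loglik, n=int(x.size))


def bootstrap_shape(
    distances: np.ndarray,
    iters: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap distribution of the gamma shape.

    Each iteration refits the gamma MLE to a resample (with replacement) of
    the distances.  Errors in more than 10% of refits abort."""
    if rng is None:
        rng = np.random.default_rng(0)
    x = _prepare_positive(np.asarray(distances, dtype=float))
    if x.size < 10:
        raise ValueError(f"insufficient data for bootstrap (n={x.size} < 10)")
    idx = rng.integers(0, x.size, size=(iters, x.size))
    resamples = x[idx]
    means = resamples.mean(axis=1)
    s = np.log(means) - np.mean(np.log(resamples), axis=1)
    shapes = _shape_from_spread(s)
    bad = ~np.isfinite(shapes)
    if bad.mean() > 0.10:
        raise RuntimeError(f"{int(bad.sum())}/{iters} bootstrap refits failed")
    return shapes[~bad]


# ---------------------------------------------------------------------------
# tests between distributions


def compare_shape_distributions(
    boot_obs: np.ndarray, boot_exp: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Mann-Whitney U p-value between two bootstrap shape distributions."""
    a = np.asarray(boot_obs, dtype=float)
    b = np.asarray(boot_exp, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("bootstrap shape vectors must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("identical constant shape vectors; p = 1", stacklevel=2)
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)


def compare_distance_sets(
    dist_a: np.ndarray, dist_b: np.ndarray, paired: bool = False
) -> float:
    """Rank-based two-sided comparison of two distance sets.

    Default is the unpaired Mann-Whitney U test; with ``paired=True`` the
    Wilcoxon signed-rank test is applied to equal-length samples (e.g.
    binned frequencies).
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("distance sets must be non-empty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length sets")
        if np.all(a == b):
            warnings.warn("identical paired sets; p = 1", stacklevel=2)
            return 1.0
        return float(stats.wilcoxon(a, b).pvalue)
    if a.size == 1 and b.size == 1:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# coefficient of coincidence


def compute_coc(
    observed: np.ndarray,
    expected: np.ndarray,
    bin_width: float = 3.5e6,
) -> CoCProfile:
    """Binned CoC profile from observed and expected distance samples.

    Both samples are binned on contiguous ``bin_width`` bins from zero;
    expected counts are rescaled so that their total equals the observed
    total, and CoC per bin is observed / rescaled expected (NaN where the
    expected count is zero).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observed distance set")
    if exp.size == 0:
        raise ValueError("empty expected distance set")
    top = max(obs.max(), exp.max())
    n_bins = max(1, int(np.ceil(top / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    obs_counts, _ = np.histogram(obs, bins=edges)
    exp_counts, _ = np.histogram(exp, bins=edges)
    exp_scaled = exp_counts * (obs_counts.sum() / exp_counts.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        coc = np.where(exp_scaled > 0, obs_counts / exp_scaled, np.nan)
    table = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "observed": obs_counts,
            "expected": exp_scaled,
            "coc": coc,
        }
    )
    return CoCProfile(table=table, bin_width=float(bin_width))


# ---------------------------------------------------------------------------
# one-call pipeline


@dataclass
class InterferenceReport:
    """Bundle of the full cis-DCO interference analysis for one genotype."""

    observed: np.ndarray
    expected: np.ndarray
    fit_observed: GammaFit
    fit_expected: GammaFit
    p_shape: float
    p_shape_greater: float
    coc: CoCProfile
    median_observed: float
    median_expected: float


def analyze_interference(
    segments: pd.DataFrame,
    events: pd.DataFrame,
    n_sample: int = 400,
    boot_iters: int = 1000,
    bin_width: float = 3.5e6,
    rng: np.random.Generator | None = None,
) -> InterferenceReport:
    """Run the complete interference analysis for one genotype.

    Extracts observed cis-DCO distances from segments, builds the randomized
    expected null from event midpoints, fits gamma distributions with
    bootstrap shape distributions, compares them by Mann-Whitney U, and
    computes the CoC profile.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    obs = extract_cis_dcos(segments)["distance"].to_numpy()
    exp = expected_null_distances(events, n_sample=n_sample, rng=rng)
    fit_obs = fit_gamma(obs)
    fit_exp = fit_gamma(exp)
    fit_obs.bootstrap_shapes = bootstrap_shape(obs, iters=boot_iters, rng=rng)
    fit_exp.bootstrap_shapes = bootstrap_shape(exp, iters=boot_iters, rng=rng)
    p = compare_shape_distributions(fit_obs.bootstrap_shapes, fit_exp.bootstrap_shapes)
    p_greater = compare_shape_distributions(
        fit_obs.bootstrap_shapes, fit_exp.bootstrap_shapes, alternative="greater"
    )
    coc = compute_coc(obs, exp, bin_width=bin_width)
    return InterferenceReport(
        observed=obs,
        expected=exp,
        fit_observed=fit_obs,
        fit_expected=fit_exp,
        p_shape=p,
        p_shape_greater=p_greater,
        coc=coc,
        median_observed=float(np.median(obs)),
        median_expected=float(np.median(exp)),
    )
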