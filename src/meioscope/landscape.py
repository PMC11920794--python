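"""Windowed crossover landscapes and their summaries.

Crossover midpoints are binned into fixed-origin windows (default 300 kb,
last window truncated at the chromosome end) and expressed as crossovers per
F2 individual per window.  Profiles can be averaged along proportionally
scaled chromosome arms (telomere = 0, centromere = 1), compared across
genotypes by Spearman rank correlation, and summarized as per-window
mutant/wild-type ratios grouped into chromosome arms versus pericentromeres.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import ChromosomeModel

__all__ = [
    "window_frequency",
    "scale_arms",
    "correlation_matrix",
    "regional_reduction",
]


def window_frequency(
    events: pd.DataFrame,
    n_individuals: int,
    chrom_models: list[ChromosomeModel],
    window: int = 300_000,
) -> pd.DataFrame:
    """Per-window crossover frequency (events per individual).

    Windows tile every chromosome from position 0; the last, partial window
    is retained.  Windows with no events are present with frequency 0, so
    the sum of ``freq * n_individuals`` over all windows equals the total
    event count.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    frames = []
    for ch in chrom_models:
        starts = np.arange(0, ch.length, window)
        ends = np.minimum(starts + window, ch.length)
        counts = np.zeros(starts.size)
        if len(events):
            mids = events.loc[events["chrom"] == ch.name, "midpoint"].to_numpy()
            if mids.size:
                idx = np.minimum((mids // window).astype(int), starts.size - 1)
                np.add.at(counts, idx, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": ch.name,
                    "start": starts,
                    "end": ends,
                    "freq": counts / n_individuals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def scale_arms(
    profile: pd.DataFrame,
    chrom_models: list[ChromosomeModel],
    n_bins: int = 20,
) -> pd.DataFrame:
    """Average a landscape along proportionally scaled arms (TEL -> CEN).

    Each window is assigned by its midpoint to the left arm ([0, centromere))
    or right arm and mapped to a proportional coordinate in [0, 1] with 0 at
    the telomere and 1 at the centromere; windows of all arms of all
    chromosomes are then averaged within ``n_bins`` equal bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    coords, values = [], []
    for ch in chrom_models:
        sub = profile[profile["chrom"] == ch.name]
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        freq = sub["freq"].to_numpy()
        left = mid < ch.centromere_mid
        coords.append(mid[left] / ch.centromere_mid)
        values.append(freq[left])
        right_len = ch.length - ch.centromere_mid
        coords.append((ch.length - mid[~left]) / right_len)
        values.append(freq[~left])
    coord = np.concatenate(coords)
    value = np.concatenate(values)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum(np.digitize(coord, edges) - 1, n_bins - 1)
    mean_freq = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_freq[b] = value[sel].mean()
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "mean_freq": mean_freq}
    )


def correlation_matrix(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between landscape profiles.

    All profiles must be defined on identical windows.  Constant profiles
    yield NaN entries; the diagonal is 1.
    """
    labels = list(profiles)
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles")
    ref = profiles[labels[0]][["chrom", "start", "end"]].reset_index(drop=True)
    vectors = {}
    for label in labels:
        p = profiles[label].reset_index(drop=True)
        if not p[["chrom", "start", "end"]].equals(ref):
            raise ValueError(f"profile {label!r} is not on the same windows")
        vectors[label] = p["freq"].to_numpy()
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if np.all(vectors[a] == vectors[a][0]) or np.all(vectors[b] == vectors[b][0]):
                rho = np.nan
            else:
                rho = stats.spearmanr(vectors[a], vectors[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def _in_pericentromere(mid: np.ndarray, ch: ChromosomeModel) -> np.ndarray:
    mask = np.zeros(mid.size, dtype=bool)
    for lo, hi in ch.pericentromere:
        mask |= (mid >= lo) & (mid < hi)
    return mask


def regional_reduction(
    profile_mut: pd.DataFrame,
    profile_wt: pd.DataFrame,
    chrom_models: list[ChromosomeModel],
) -> tuple[pd.DataFrame, dict]:
    """Per-window mutant/wild-type frequency ratios, grouped by region.

    Windows are grouped by whether their midpoint falls inside a supplied
    pericentromere interval.  Windows with zero wild-type frequency give NaN
    ratios.  Returns the per-window table and a summary with group medians
    and a one-sided rank-test p-value for pericentromere ratios being lower
    than arm ratios.
    """
    if not any(ch.pericentromere for ch in chrom_models):
        raise ValueError("pericentromere annotation required for regional grouping")
    mut = profile_mut.reset_index(drop=True)
    wt = profile_wt.reset_index(drop=True)
    if not mut[["chrom", "start", "end"]].equals(wt[["chrom", "start", "end"]]):
        raise ValueError("profiles are not on identical windows")
    mid = (mut["start"].to_numpy() + mut["end"].to_numpy()) / 2.0
    by_name = {ch.name: ch for ch in chrom_models}
    peri = np.zeros(len(mut), dtype=bool)
    for chrom, grp in mut.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        peri[idx] = _in_pericentromere(mid[idx], by_name[chrom])
    wt_freq = wt["freq"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(wt_freq > 0, mut["freq"].to_numpy() / wt_freq, np.nan)
    table = pd.DataFrame(
        {
            "chrom": mut["chrom"],
            "start": mut["start"],
            "end": mut["end"],
            "ratio": ratio,
            "region": np.where(peri, "pericentromere", "arm"),
        }
    )
    arm = ratio[~peri & np.isfinite(ratio)]
    per = ratio[peri & np.isfinite(ratio)]
    if arm.size and per.size:
        p = float(stats.mannwhitneyu(per, arm, alternative="less").pvalue)
    else:
        p = float("nan")
    summary = {
        "arm_median": float(np.median(arm)) if arm.size else float("nan"),
        "pericentromere_median": float(np.median(per)) if per.size else float("nan"),
        "p_pericentromere_lower": p,
        "n_arm_windows": int(arm.size),
        "n_pericentromere_windows": int(per.size),
    }
    return table, summary
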