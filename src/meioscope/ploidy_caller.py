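"""Per-chromosome copy-number classification from windowed sequencing depth.

Each chromosome's mean window depth is divided by a sample-level disomic
baseline to give a copy ratio (~0.5 for monosomy, ~1.0 for disomy, ~1.5 for
trisomy).  The baseline is the length-weighted mean depth over all
chromosomes, re-estimated iteratively while excluding chromosomes whose
provisional ratio falls outside the disomic band, so that an aneuploid
chromosome cannot inflate its own reference.  Classification uses fixed,
strict thresholds: ratio > 1.2 is trisomy, ratio < 0.8 is monosomy.  Arms
(split at the centromere midpoint) are classified with the same thresholds;
"partial trisomy" is reported when exactly one arm is trisomic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import ChromosomeModel

__all__ = [
    "classify_ploidy",
    "normalize_ploidy",
    "call_ploidy",
    "detect_partial_trisomy",
]

TRISOMY_THRESHOLD = 1.2
MONOSOMY_THRESHOLD = 0.8

PLOIDY_COLUMNS = [
    "individual",
    "chrom",
    "ratio",
    "class",
    "left_arm_ratio",
    "left_arm_class",
    "right_arm_ratio",
    "right_arm_class",
    "partial_trisomy",
]


def classify_ploidy(
    ratio: float,
    trisomy: float = TRISOMY_THRESHOLD,
    monosomy: float = MONOSOMY_THRESHOLD,
) -> str:
    """Copy-number class from a depth ratio (strict thresholds)."""
    if np.isnan(ratio):
        raise ValueError("ploidy ratio is NaN")
    if ratio < 0:
        raise ValueError("ploidy ratio must be >= 0")
    if ratio > trisomy:
        return "trisomy"
    if ratio < monosomy:
        return "monosomy"
    return "disomy"


def _one_individual(track: pd.DataFrame, chrom_models: list[ChromosomeModel]):
    """Mean depth and length per chromosome for one individual's track."""
    by_chrom = track.groupby("chrom", sort=False)["depth"].mean()
    depths, lengths, names = [], [], []
    for ch in chrom_models:
        if ch.name not in by_chrom.index:
            raise ValueError(f"no coverage windows for {ch.name}")
        depths.append(float(by_chrom[ch.name]))
        lengths.append(float(ch.length))
        names.append(ch.name)
    return np.array(depths), np.array(lengths), names


def normalize_ploidy(
    track: pd.DataFrame,
    chrom_models: list[ChromosomeModel],
    trisomy: float = TRISOMY_THRESHOLD,
    monosomy: float = MONOSOMY_THRESHOLD,
    max_iter: int = 5,
) -> tuple[dict[str, float], float]:
    """Per-chromosome depth ratios for a single individual's coverage track.

    The disomic baseline is the length-weighted mean depth, iteratively
    re-estimated over chromosomes whose provisional ratio lies inside
    [monosomy, trisomy].  If every chromosome is excluded, the plain
    length-weighted mean is used with a warning.  Returns the ratio mapping
    and the baseline depth it was computed against.
    """
    depths, lengths, names = _one_individual(track, chrom_models)
    baseline = float(np.average(depths, weights=lengths))
    if baseline <= 0:
        raise ValueError("zero overall depth; cannot normalize")
    for _ in range(max_iter):
        ratios = depths / baseline
        included = (ratios >= monosomy) & (ratios <= trisomy)
        if not included.any():
            warnings.warn(
                "all chromosomes outside the disomic band; falling back to the "
                "plain length-weighted mean depth",
                stacklevel=2,
            )
            baseline = float(np.average(depths, weights=lengths))
            break
        new_baseline = float(np.average(depths[included], weights=lengths[included]))
        if new_baseline == baseline:
            break
        baseline = new_baseline
    return dict(zip(names, depths / baseline)), baseline


def _arm_ratios(
    track: pd.DataFrame, ch: ChromosomeModel, baseline: float
) -> tuple[float, float]:
    """Left/right arm depth ratios; windows are assigned to the arm holding
    their midpoint."""
    sub = track[track["chrom"] == ch.name]
    mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
    left = sub["depth"].to_numpy()[mid < ch.centromere_mid]
    right = sub["depth"].to_numpy()[mid >= ch.centromere_mid]
    out = []
    for arm, depths in (("left", left), ("right", right)):
        if depths.size == 0:
            warnings.warn(f"{ch.name} {arm} arm has no coverage windows", stacklevel=3)
            out.append(float("nan"))
        else:
            out.append(float(depths.mean() / baseline))
    return out[0], out[1]


def call_ploidy(
    track: pd.DataFrame,
    chrom_models: list[ChromosomeModel],
    trisomy: float = TRISOMY_THRESHOLD,
    monosomy: float = MONOSOMY_THRESHOLD,
) -> pd.DataFrame:
    """Whole-chromosome and arm-level ploidy calls for every individual.

    ``track`` is a long coverage table (individual, chrom, start, end,
    depth).  Returns one row per individual-chromosome with the copy ratio,
    class, per-arm ratios/classes, and a partial-trisomy flag (exactly one
    trisomic arm).
    """
    rows = []
    for ind, sub in track.groupby("individual", sort=False):
        ratios, baseline = normalize_ploidy(sub, chrom_models, trisomy, monosomy)
        for ch in chrom_models:
            ratio = ratios[ch.name]
            cls = classify_ploidy(ratio, trisomy, monosomy)
            lr, rr = _arm_ratios(sub, ch, baseline)
            lc = classify_ploidy(lr, trisomy, monosomy) if np.isfinite(lr) else None
            rc = classify_ploidy(rr, trisomy, monosomy) if np.isfinite(rr) else None
            partial = (lc == "trisomy") != (rc == "trisomy")
            rows.append((ind, ch.name, ratio, cls, lr, lc, rr, rc, partial))
    return pd.DataFrame(rows, columns=PLOIDY_COLUMNS)


def detect_partial_trisomy(
    track: pd.DataFrame,
    chrom_models: list[ChromosomeModel],
    trisomy: float = TRISOMY_THRESHOLD,
    monosomy: float = MONOSOMY_THRESHOLD,
) -> pd.DataFrame:
    """Arm-level ploidy table (subset of :func:`call_ploidy` columns) for
    individuals-chromosomes where exactly one arm is trisomic."""
    calls = call_ploidy(track, chrom_models, trisomy, monosomy)
    return calls[calls["partial_trisomy"]].reset_index(drop=True)
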