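"""Genotype segmentation and crossover calling.

Each individual's per-marker genotype calls are segmented into runs of
P1 / H / P2 by a deterministic sliding-window majority vote, and one
crossover event is emitted at every boundary between adjacent segments.
This caller is a defined, reproducible stand-in for HMM-based breakpoint
pipelines: a centered window of ``window_markers`` informative markers votes
on each marker's state; votes below the ``purity`` threshold inherit the
last confident state; runs shorter than ``min_segment_markers`` are absorbed
into the flanking state with more supporting markers (ties go left).

Crossover positions are reported as the midpoint of the interval between the
last marker of the left segment and the first marker of the right segment.
Direct P1<->P2 transitions (two crossovers inside one marker gap) are
flagged rather than resolved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import MISSING, STATE_NAMES, GenotypeMatrix

__all__ = ["segment_genotypes", "call_crossovers", "exclude_aneuploids"]

SEGMENT_COLUMNS = ["individual", "chrom", "start", "end", "state", "n_markers"]
EVENT_COLUMNS = ["individual", "chrom", "start", "end", "midpoint", "transition", "flagged"]


def _vote_states(codes: np.ndarray, window_markers: int, purity: float) -> np.ndarray:
    """Provisional state per marker from a centered majority vote.

    Windows are truncated at chromosome ends.  The provisional state is the
    window majority (argmax); markers whose majority fraction falls below
    ``purity`` are low-confidence and take the state of the *nearest*
    confident marker (ties toward the left), so transition boundaries are
    not biased in either direction.  If no marker is confident, the plain
    majority states are used as-is.
    """
    n = codes.size
    half = window_markers // 2
    onehot = np.zeros((3, n))
    onehot[codes, np.arange(n)] = 1.0
    cum = np.concatenate([np.zeros((3, 1)), np.cumsum(onehot, axis=1)], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    counts = cum[:, hi] - cum[:, lo]
    total = counts.sum(axis=0)
    maj = counts.argmax(axis=0)
    frac = counts.max(axis=0) / total
    confident = frac >= purity
    if not confident.any() or confident.all():
        return maj
    idx = np.arange(n)
    left = np.where(confident, idx, -1)
    np.maximum.accumulate(left, out=left)  # nearest confident at or before i
    right = np.where(confident, idx, n)
    np.minimum.accumulate(right[::-1], out=right[::-1])  # nearest at or after i
    use_left = (left >= 0) & ((right >= n) | (idx - left <= right - idx))
    fill = np.where(use_left, left, right)
    return maj[fill]


def _rescue_raw_runs(codes: np.ndarray, states: np.ndarray, min_markers: int) -> np.ndarray:
    """Let long runs of identical raw calls override the smoothed states.

    The majority window cannot represent genuine segments shorter than about
    half its width, so a run of at least ``min_markers`` *identical* raw
    calls reclaims its state (at a few percent genotype error, that many
    consecutive identical mis-calls is vanishingly unlikely).  This makes
    ``min_segment_markers`` the caller's actual resolution limit.
    """
    out = states.copy()
    for state, s, e in _run_lengths(codes):
        if e - s >= min_markers and np.any(out[s:e] != state):
            out[s:e] = state
    return out


def _run_lengths(states: np.ndarray) -> list[list[int]]:
    """Run-length encode as mutable [state, start, end) triples."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [[int(states[s]), int(s), int(e)] for s, e in zip(starts, ends)]


def _merge_equal(runs: list[list[int]]) -> list[list[int]]:
    out: list[list[int]] = []
    for r in runs:
        if out and out[-1][0] == r[0]:
            out[-1][2] = r[2]
        else:
            out.append(list(r))
    return out


def _absorb_short_runs(runs: list[list[int]], min_markers: int) -> list[list[int]]:
    """Iteratively absorb runs shorter than ``min_markers`` into the flanking
    run with more supporting markers (ties -> left); shortest, leftmost first."""
    runs = _merge_equal(runs)
    while len(runs) > 1:
        lengths = [e - s for _, s, e in runs]
        short = [j for j, ln in enumerate(lengths) if ln < min_markers]
        if not short:
            break
        j = min(short, key=lambda j: (lengths[j], j))
        if j == 0:
            runs[0][0] = runs[1][0]
        elif j == len(runs) - 1:
            runs[j][0] = runs[j - 1][0]
        else:
            left_len, right_len = lengths[j - 1], lengths[j + 1]
            runs[j][0] = runs[j - 1][0] if left_len >= right_len else runs[j + 1][0]
        runs = _merge_equal(runs)
    return runs


def segment_genotypes(
    matrix: GenotypeMatrix,
    window_markers: int = 15,
    purity: float = 0.8,
    min_segment_markers: int = 5,
) -> pd.DataFrame:
    """Segment every individual-chromosome into alternating genotype runs.

    Missing calls are skipped (not imputed).  Chromosomes with fewer than
    ``window_markers`` informative markers for an individual produce no
    segments (a single summary warning is issued).

    Returns a table with one row per segment: individual, chrom, start
    (first marker pos), end (last marker pos), state, n_markers.
    """
    if window_markers <= 0 or min_segment_markers <= 0:
        raise ValueError("window and segment sizes must be positive")
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")

    rows: list[tuple] = []
    n_skipped = 0
    slices = matrix.chrom_slices()
    for i, ind in enumerate(matrix.individuals):
        for chrom, sl in slices.items():
            codes = matrix.geno[i, sl]
            pos = matrix.markers["pos"].to_numpy()[sl]
            keep = codes != MISSING
            c, p = codes[keep], pos[keep]
            if c.size < window_markers:
                n_skipped += 1
                continue
            states = _vote_states(c, window_markers, purity)
            states = _rescue_raw_runs(c, states, min_segment_markers)
            for state, s, e in _absorb_short_runs(_run_lengths(states), min_segment_markers):
                rows.append((ind, chrom, int(p[s]), int(p[e - 1]), STATE_NAMES[state], e - s))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} individual-chromosomes had too few informative markers "
            f"(< {window_markers}) and produced no segments",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_crossovers(segments: pd.DataFrame) -> pd.DataFrame:
    """Emit one crossover event per adjacent segment pair.

    The event interval runs from the last marker of the left segment to the
    first marker of the right segment; the reported position is the interval
    midpoint.  P1<->P2 transitions are flagged ("double-in-gap") and must not
    enter cis-DCO analyses.
    """
    rows: list[tuple] = []
    if len(segments):
        for (ind, chrom), grp in segments.groupby(["individual", "chrom"], sort=False):
            g = grp.sort_values("start")
            left = g.iloc[:-1]
            right = g.iloc[1:]
            for (_, a), (_, b) in zip(left.iterrows(), right.iterrows()):
                start, end = int(a["end"]), int(b["start"])
                if end <= start:
                    raise ValueError(
                        f"overlapping segments for {ind} {chrom} at {start}"
                    )
                flagged = {a["state"], b["state"]} == {"P1", "P2"}
                rows.append(
                    (
                        ind,
                        chrom,
                        start,
                        end,
                        (start + end) / 2.0,
                        f"{a['state']}>{b['state']}",
                        flagged,
                    )
                )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def exclude_aneuploids(events: pd.DataFrame, ploidy_calls: pd.DataFrame) -> pd.DataFrame:
    """Drop all events of individuals with any non-disomic chromosome call.

    Every individual present in ``events`` must have ploidy calls; a missing
    individual raises."""
    if len(events) == 0:
        return events.copy()
    called = set(ploidy_calls["individual"])
    missing = sorted(set(events["individual"]) - called)
    if missing:
        raise ValueError(f"no ploidy call for individuals: {missing[:5]}")
    aneuploid = set(
        ploidy_calls.loc[ploidy_calls["class"] != "disomy", "individual"]
    )
    return events[~events["individual"].isin(aneuploid)].reset_index(drop=True)
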