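"""Comparison of called crossovers against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import TrueMeiosisRecord

__all__ = ["match_positions", "caller_performance", "CallerPerformance"]


def match_positions(
    true_pos: np.ndarray,
    called_pos: np.ndarray,
    tol: float,
    capacity: np.ndarray | None = None,
) -> tuple[int, list[float], int]:
    """Greedy in-order matching of sorted position lists within ``tol``.

    Each called position may absorb up to ``capacity`` true positions
    (default 1; a flagged double-in-gap event stands for two crossovers and
    gets capacity 2).  Returns (number of true positions matched, absolute
    errors of matches, number of called positions with no match at all).
    """
    order_t = np.argsort(np.asarray(true_pos, dtype=float))
    t = np.asarray(true_pos, dtype=float)[order_t]
    order_c = np.argsort(np.asarray(called_pos, dtype=float))
    c = np.asarray(called_pos, dtype=float)[order_c]
    cap = (
        np.ones(c.size, dtype=int)
        if capacity is None
        else np.asarray(capacity, dtype=int)[order_c]
    )
    used = np.zeros(c.size, dtype=int)
    i = j = 0
    errors: list[float] = []
    while i < t.size and j < c.size:
        d = c[j] - t[i]
        if abs(d) <= tol and used[j] < cap[j]:
            errors.append(abs(d))
            used[j] += 1
            i += 1
        elif d < 0 or used[j] >= cap[j]:
            j += 1
        else:
            i += 1
    return len(errors), errors, int((used == 0).sum())


@dataclass
class CallerPerformance:
    n_true: int
    n_called: int
    n_matched: int
    n_false: int
    n_chromosome_tracks: int
    midpoint_errors: np.ndarray

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def false_positives_per_track(self) -> float:
        return self.n_false / self.n_chromosome_tracks


def caller_performance(
    record: TrueMeiosisRecord, events: pd.DataFrame, tol: float
) -> CallerPerformance:
    """Recall, false-positive rate, and midpoint errors of called events.

    Truth per individual-chromosome is the union of the transmitted
    chromatids' breakpoints; only disomic chromosomes are evaluated (on
    aneuploid chromosomes the genotype signal does not expose the
    breakpoints).  A called event matches a true crossover when their
    positions agree within ``tol`` bp (one-to-one).
    """
    by_track: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    if len(events):
        for (ind, chrom), grp in events.groupby(["individual", "chrom"], sort=False):
            by_track[(ind, chrom)] = (
                grp["midpoint"].to_numpy(dtype=float),
                np.where(grp["flagged"].to_numpy(dtype=bool), 2, 1),
            )

    n_true = n_called = n_matched = n_false = n_tracks = 0
    errors: list[float] = []
    for ind in record.individuals:
        for ch in record.chromosomes:
            key = (ind, ch.name)
            if record.copy_number[key] != 2:
                continue
            n_tracks += 1
            truth = np.concatenate(record.crossovers[key]) if record.crossovers[key] else np.empty(0)
            called, cap = by_track.get(key, (np.empty(0), np.empty(0, dtype=int)))
            n_true += truth.size
            n_called += called.size
            m, errs, false = match_positions(truth, called, tol, capacity=cap)
            n_matched += m
            n_false += false
            errors.extend(errs)
    return CallerPerformance(
        n_true=n_true,
        n_called=n_called,
        n_matched=n_matched,
        n_false=n_false,
        n_chromosome_tracks=n_tracks,
        midpoint_errors=np.asarray(errors),
    )
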