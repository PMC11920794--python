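"""Forward simulator of F2 genotyping-by-sequencing populations.

Each F2 individual is the union of two gametes produced by two independent
meioses of an F1 hybrid.  Per chromosome and meiosis, crossovers are placed
on the bivalent in physical coordinates: interfering class I events follow a
stationary gamma renewal process with shape ``nu`` (``nu = 1`` is Poisson),
non-interfering class II events follow a homogeneous Poisson process.  Each
crossover is assigned to one chromatid of each homolog uniformly (no
chromatid interference) and the transmitted gamete is one of the four
chromatids, sampled uniformly.  The obligate crossover is deliberately NOT
enforced: a bivalent without any crossover may missegregate with probability
``obligate_escape_p``, which is what generates monosomic/trisomic offspring.

The simulator also produces per-window sequencing-depth tracks that reflect
chromosome copy number, and fluorescent-seed counts for a reporter interval
of known genetic size, so that every downstream analysis stage can be tested
against known ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import (
    H,
    ChromosomeModel,
    GenotypeMatrix,
    SeedCounts,
    SimConfig,
    TrueMeiosisRecord,
)

__all__ = [
    "place_class1",
    "place_class2",
    "make_marker_map",
    "simulate_f2_population",
    "simulate_coverage",
    "simulate_seed_counts",
    "gamete_alleles",
    "genotype_from_gametes",
]


def place_class1(
    chrom: ChromosomeModel, class1_mean: float, nu: float, rng: np.random.Generator
) -> np.ndarray:
    """Place interfering (class I) crossovers on one bivalent.

    Positions are drawn from a *stationary* gamma renewal process on
    ``[0, length]`` with shape ``nu`` and mean inter-event distance
    ``length / class1_mean``, so the expected event count over the chromosome
    equals ``class1_mean``.  Stationarity is obtained by drawing the interval
    that covers the origin from the length-biased distribution (gamma with
    shape ``nu + 1``) and placing the origin uniformly within it; without
    this, the process start would mimic extra interference against the
    chromosome end.
    """
    if chrom.length <= 0:
        raise ValueError("chromosome length must be positive")
    if class1_mean < 0:
        raise ValueError("class1_mean must be >= 0")
    if nu <= 0:
        raise ValueError("nu must be > 0")
    if class1_mean == 0:
        return np.empty(0)
    mean_gap = chrom.length / class1_mean
    scale = mean_gap / nu
    pos: list[float] = []
    # forward recurrence time from the origin under the equilibrium law
    x = rng.uniform() * rng.gamma(nu + 1.0, scale)
    while x < chrom.length:
        pos.append(x)
        x += rng.gamma(nu, scale)
    return np.asarray(pos)


def place_class2(
    chrom: ChromosomeModel,
    class2_mean: float,
    rng: np.random.Generator,
    terminal_fraction: float | None = None,
) -> np.ndarray:
    """Place non-interfering (class II) crossovers: Poisson count, uniform
    positions.  With ``terminal_fraction`` set, positions are confined to the
    two chromosome ends (each end covering ``terminal_fraction / 2`` of the
    chromosome)."""
    if class2_mean < 0:
        raise ValueError("class2_mean must be >= 0")
    k = rng.poisson(class2_mean)
    if k == 0:
        return np.empty(0)
    u = rng.uniform(size=k)
    if terminal_fraction is None:
        pos = u * chrom.length
    else:
        half = terminal_fraction / 2.0
        w = half * chrom.length
        left = u < 0.5
        pos = np.where(left, 2 * u * w, chrom.length - w + (2 * u - 1) * w)
    return np.sort(pos)


def make_marker_map(
    chromosomes: list[ChromosomeModel], spacing: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Random biallelic marker map with the given mean spacing (bp).

    Marker ``i`` sits at ``(i + U) * spacing`` with independent uniform
    jitter, giving the requested mean density without the long marker
    deserts of a purely Poisson map (dense parental SNP lists have fairly
    even coverage).  Positions are 1-based, unique and sorted within each
    chromosome.
    """
    frames = []
    for ch in chromosomes:
        n = max(2, int(ch.length // spacing))
        pos = ((np.arange(n) + rng.uniform(size=n)) * spacing).astype(np.int64) + 1
        pos = np.unique(np.clip(pos, 1, ch.length))
        frames.append(pd.DataFrame({"chrom": ch.name, "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def _sample_gamete(
    bivalent_pos: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Assign bivalent crossovers to chromatids and transmit one chromatid.

    Each crossover joins one of the two chromatids of each homolog, chosen
    uniformly and independently (no chromatid interference).  Returns the
    breakpoints carried by the transmitted chromatid and its starting parent
    allele (0 = P1 homolog, 1 = P2 homolog); ancestry toggles at every
    breakpoint.
    """
    k = bivalent_pos.size
    a = rng.integers(0, 2, size=k)  # chromatid of homolog 1 involved in each CO
    b = rng.integers(0, 2, size=k)  # chromatid of homolog 2
    g = rng.integers(0, 4)  # transmitted chromatid
    if g < 2:
        involved = a == g
        parent = 0
    else:
        involved = b == (g - 2)
        parent = 1
    return bivalent_pos[involved], parent


def gamete_alleles(breakpoints: np.ndarray, parent: int, positions: np.ndarray) -> np.ndarray:
    """Allele (0 = P1, 1 = P2) carried by a gamete at each marker position."""
    crossings = np.searchsorted(breakpoints, positions, side="right")
    return (parent + crossings) % 2


def genotype_from_gametes(
    gamete1: tuple[np.ndarray, int],
    gamete2: tuple[np.ndarray, int],
    positions: np.ndarray,
) -> np.ndarray:
    """Disomic F2 genotype codes (P1/H/P2) as the allele sum of two gametes."""
    a1 = gamete_alleles(*gamete1, positions=positions)
    a2 = gamete_alleles(*gamete2, positions=positions)
    return (a1 + a2).astype(np.int8)


def simulate_f2_population(
    config: SimConfig,
    n_individuals: int,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TrueMeiosisRecord]:
    """Simulate an F2 population and its ground-truth meiosis record.

    Copy-number bookkeeping: a missegregating zero-crossover bivalent yields
    an individual chromosome copy number of 1 or 3 with equal odds.  Trisomic
    chromosomes carry both parental homologs (the nondisjoined gamete holds a
    chromatid of each), so their genotype calls are heterozygous throughout;
    monosomic chromosomes are hemizygous and are rendered as the homozygous
    parental state of the single transmitted chromatid.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    markers = make_marker_map(config.chromosomes, config.marker_spacing, rng)
    if markers.empty:
        raise ValueError("empty marker map")

    n_m = len(markers)
    individuals = [f"F2_{i:04d}" for i in range(n_individuals)]
    geno = np.empty((n_individuals, n_m), dtype=np.int8)
    crossovers: dict[tuple[str, str], list[np.ndarray]] = {}
    copy_number: dict[tuple[str, str], int] = {}

    chrom_pos = {
        ch.name: markers.loc[markers["chrom"] == ch.name, "pos"].to_numpy()
        for ch in config.chromosomes
    }
    chrom_offsets = {}
    off = 0
    for ch in config.chromosomes:
        chrom_offsets[ch.name] = off
        off += chrom_pos[ch.name].size

    for i, ind in enumerate(individuals):
        for ch in config.chromosomes:
            pos = chrom_pos[ch.name]
            sl = slice(chrom_offsets[ch.name], chrom_offsets[ch.name] + pos.size)
            gametes = []
            misseg = []
            for _ in range(2):
                biv = np.sort(
                    np.concatenate(
                        [
                            place_class1(ch, config.class1_mean, config.nu, rng),
                            place_class2(
                                ch, config.class2_mean, rng, config.terminal_fraction
                            ),
                        ]
                    )
                )
                gametes.append(_sample_gamete(biv, rng))
                misseg.append(
                    biv.size == 0
                    and config.obligate_escape_p > 0
                    and rng.random() < config.obligate_escape_p
                )
            if any(misseg):
                copy = 1 if rng.random() < 0.5 else 3
            else:
                copy = 2
            if copy == 2:
                code = genotype_from_gametes(gametes[0], gametes[1], pos)
            elif copy == 1:
                # keep the gamete of a non-missegregating meiosis when there is one
                j = misseg.index(False) if False in misseg else int(rng.integers(0, 2))
                code = (2 * gamete_alleles(*gametes[j], positions=pos)).astype(np.int8)
            else:
                # the nondisjoined gamete carries one chromatid of each homolog
                code = np.full(pos.size, H, dtype=np.int8)
            geno[i, sl] = code
            crossovers[(ind, ch.name)] = [g[0] for g in gametes]
            copy_number[(ind, ch.name)] = copy

    if config.geno_error_p > 0:
        flip = rng.random(geno.shape) < config.geno_error_p
        shift = rng.integers(1, 3, size=geno.shape)
        geno = np.where(flip, (geno + shift) % 3, geno).astype(np.int8)

    qual = rng.normal(200.0, 30.0, size=geno.shape).clip(min=1.0)
    cov = rng.gamma(4.0, 1.25, size=geno.shape)  # mean 5x, GBS-like spread
    read_counts = rng.integers(120_000, 260_000, size=n_individuals)

    matrix = GenotypeMatrix(markers, individuals, geno, qual, cov, read_counts)
    record = TrueMeiosisRecord(
        list(config.chromosomes), individuals, crossovers, copy_number
    )
    return matrix, record


def simulate_coverage(
    record: TrueMeiosisRecord,
    window_bp: int = 100_000,
    base_depth: float = 20.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Windowed sequencing-depth tracks reflecting chromosome copy number.

    Depth per window is ``base_depth * copy / 2`` plus Gaussian noise,
    truncated at zero.  Returns a long table (individual, chrom, start, end,
    depth) with half-open 0-based windows tiling each chromosome (last window
    truncated).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if base_depth <= 0:
        raise ValueError("base_depth must be > 0")
    if rng is None:
        rng = np.random.default_rng(0)

    windows = {}
    for ch in record.chromosomes:
        starts = np.arange(0, ch.length, window_bp)
        ends = np.minimum(starts + window_bp, ch.length)
        windows[ch.name] = (starts, ends)

    frames = []
    for ind in record.individuals:
        for ch in record.chromosomes:
            starts, ends = windows[ch.name]
            copy = record.copy_number[(ind, ch.name)]
            depth = base_depth * copy / 2.0 + rng.normal(0.0, noise_sd, size=starts.size)
            frames.append(
                pd.DataFrame(
                    {
                        "individual": ind,
                        "chrom": ch.name,
                        "start": starts,
                        "end": ends,
                        "depth": np.clip(depth, 0.0, None),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_seed_counts(
    rf_cm: float, n_total: int, rng: np.random.Generator | None = None
) -> SeedCounts:
    """Draw fluorescent-seed counts for a reporter interval of ``rf_cm``.

    Inverts the map-distance estimator: with recombination frequency
    ``r = rf_cm / 100``, the combined probability of a green-only or red-only
    seed is ``(1 - (1 - r)^2) / 2``, split equally between the two colors.
    """
    if not 0.0 <= rf_cm < 100.0:
        raise ValueError("rf_cm must be in [0, 100)")
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if rng is None:
        rng = np.random.default_rng(0)
    r = rf_cm / 100.0
    p_single = (1.0 - (1.0 - r) ** 2) / 2.0
    n_g, n_r, _ = rng.multinomial(n_total, [p_single / 2, p_single / 2, 1.0 - p_single])
    return SeedCounts(int(n_g), int(n_r), int(n_total))
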