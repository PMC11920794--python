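"""Shared data structures for F2 crossover-map analysis.

Genotype calls use a three-state alphabet along each chromosome of an F2
individual derived from a cross of two inbred accessions (P1 x P2):

* ``P1`` -- homozygous for the first parent,
* ``H``  -- heterozygous,
* ``P2`` -- homozygous for the second parent,

plus ``NA`` for markers with no usable call.  Internally the states are the
integer codes 0/1/2 and -1, chosen so that the genotype of a disomic
individual is simply the sum of the two gametic alleles (0 = P1 allele,
1 = P2 allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

P1, H, P2, MISSING = 0, 1, 2, -1
STATE_NAMES = {P1: "P1", H: "H", P2: "P2", MISSING: "NA"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}


@dataclass(frozen=True)
class ChromosomeModel:
    """Physical model of one chromosome.

    Parameters
    ----------
    name : str
        Chromosome label (e.g. ``"Chr1"``).
    length : int
        Chromosome length in bp.
    centromere_mid : int
        Midpoint of the centromere in bp; splits the chromosome into a left
        and a right arm.
    pericentromere : tuple of (start, end) pairs
        Pericentromeric intervals in bp (may be empty).  These are an external
        annotation (operationally defined by elevated DNA methylation) and are
        required only by the landscape arm-vs-pericentromere summaries.
    """

    name: str
    length: int
    centromere_mid: int
    pericentromere: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: chromosome length must be positive")
        if not 0 < self.centromere_mid < self.length:
            raise ValueError(f"{self.name}: centromere_mid must lie inside (0, length)")
        for lo, hi in self.pericentromere:
            if not 0 <= lo < hi <= self.length:
                raise ValueError(
                    f"{self.name}: pericentromere interval ({lo}, {hi}) outside chromosome"
                )


def arabidopsis_chromosomes(pericen_halfwidth: int = 2_500_000) -> list[ChromosomeModel]:
    """Approximate TAIR10 chromosome models for *Arabidopsis thaliana*.

    Pericentromeres are modelled as symmetric windows of ``pericen_halfwidth``
    bp around the centromere midpoint, clipped to the chromosome; real
    annotations (methylation-defined) can be supplied instead wherever a
    :class:`ChromosomeModel` is accepted.
    """
    raw = [
        ("Chr1", 30_427_671, 15_086_000),
        ("Chr2", 19_698_289, 3_607_000),
        ("Chr3", 23_459_830, 13_587_000),
        ("Chr4", 18_585_056, 3_956_000),
        ("Chr5", 26_975_502, 11_725_000),
    ]
    out = []
    for name, length, cen in raw:
        lo = max(0, cen - pericen_halfwidth)
        hi = min(length, cen + pericen_halfwidth)
        out.append(ChromosomeModel(name, length, cen, ((lo, hi),)))
    return out


@dataclass
class SimConfig:
    """Parameters of the F2 meiosis simulator.

    The two crossover classes mirror the two pathways of plant meiosis:
    class I events interfere (gamma renewal placement with shape ``nu``) and
    class II events do not (Poisson placement).  ``nu = 1`` reduces class I
    placement to a homogeneous Poisson process.

    Attributes
    ----------
    chromosomes : list of ChromosomeModel
    class1_mean : float
        Expected interfering (class I) crossovers per bivalent per chromosome.
    nu : float
        Gamma shape of class I inter-crossover distances; larger = stronger
        interference.
    class2_mean : float
        Expected non-interfering (class II) crossovers per bivalent.
    obligate_escape_p : float
        Probability that a bivalent with zero crossovers missegregates,
        producing a monosomic or trisomic offspring chromosome.
    geno_error_p : float
        Per-marker probability of an i.i.d. genotype mis-call.
    marker_spacing : float
        Mean distance between markers in bp.
    terminal_fraction : float or None
        If set, class II crossovers are confined to the two chromosome ends,
        which together cover this fraction of the chromosome (half per end).
        Emulates mutants whose crossovers concentrate at chromosome ends.
    seed : int
        RNG seed (mandatory; the simulator is fully reproducible).
    """

    chromosomes: list[ChromosomeModel]
    class1_mean: float = 1.8
    nu: float = 5.0
    class2_mean: float = 0.2
    obligate_escape_p: float = 0.0
    geno_error_p: float = 0.02
    marker_spacing: float = 50_000.0
    terminal_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        if self.class1_mean < 0 or self.class2_mean < 0:
            raise ValueError("crossover means must be >= 0")
        if self.nu <= 0:
            raise ValueError("interference shape nu must be > 0")
        for name in ("obligate_escape_p", "geno_error_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be > 0")
        if self.terminal_fraction is not None and not 0.0 < self.terminal_fraction < 1.0:
            raise ValueError("terminal_fraction must be in (0, 1)")


@dataclass
class GenotypeMatrix:
    """Per-individual, per-marker genotype calls with quality metadata.

    ``geno``, ``qual`` and ``cov`` are (n_individuals, n_markers) arrays;
    markers are sorted by chromosome (in the order of first appearance) and
    position (1-based bp).  ``read_counts`` holds the number of informative
    (SNP-associated) reads per individual, used for library-level filtering.
    """

    markers: pd.DataFrame  # columns: chrom, pos
    individuals: list[str]
    geno: np.ndarray  # int8, codes P1/H/P2/MISSING
    qual: np.ndarray
    cov: np.ndarray
    read_counts: np.ndarray

    def __post_init__(self) -> None:
        n_ind, n_m = len(self.individuals), len(self.markers)
        for name in ("geno", "qual", "cov"):
            a = getattr(self, name)
            if a.shape != (n_ind, n_m):
                raise ValueError(f"{name} has shape {a.shape}, expected {(n_ind, n_m)}")
        if len(self.read_counts) != n_ind:
            raise ValueError("read_counts length must match individuals")
        bad = ~np.isin(self.geno, (P1, H, P2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside the 4-state alphabet")
        if (self.cov < 0).any():
            raise ValueError("coverage must be >= 0")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous marker index slice for each chromosome."""
        out: dict[str, slice] = {}
        chroms = self.markers["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers.copy(),
            list(self.individuals),
            self.geno.copy(),
            self.qual.copy(),
            self.cov.copy(),
            self.read_counts.copy(),
        )


@dataclass
class TrueMeiosisRecord:
    """Ground truth of a simulated F2 population.

    ``crossovers[(individual, chrom)]`` is a list of arrays, one per inherited
    chromatid, each holding the true crossover midpoints (bp, strictly
    increasing).  ``copy_number[(individual, chrom)]`` is 1, 2 or 3.
    """

    chromosomes: list[ChromosomeModel]
    individuals: list[str]
    crossovers: dict[tuple[str, str], list[np.ndarray]]
    copy_number: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for key, cn in self.copy_number.items():
            if cn not in (1, 2, 3):
                raise ValueError(f"copy number {cn} for {key} not in {{1, 2, 3}}")


@dataclass(frozen=True)
class SeedCounts:
    """Fluorescent-seed counts from a two-reporter interval.

    ``n_green``/``n_red`` are single-fluorescent seed counts; ``n_total`` is
    the total number of scored seeds (double- and non-fluorescent seeds enter
    only through the total).
    """

    n_green: int
    n_red: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        if self.n_green < 0 or self.n_red < 0:
            raise ValueError("seed counts must be >= 0")
        if self.n_green + self.n_red > self.n_total:
            raise ValueError("single-fluorescent seeds exceed total")


@dataclass
class GammaFit:
    """Maximum-likelihood gamma fit of an inter-crossover distance sample."""

    shape: float
    rate: float
    loglik: float
    n: int
    bootstrap_shapes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError("gamma shape must be finite and positive")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValueError("gamma rate must be finite and positive")


@dataclass
class CoCProfile:
    """Binned coefficient-of-coincidence profile.

    ``table`` has one row per distance bin: ``bin_start``, ``bin_end``,
    ``observed`` (count), ``expected`` (count rescaled so totals match) and
    ``coc`` = observed / expected (NaN where expected is 0).
    """

    table: pd.DataFrame
    bin_width: float

    def mean_coc(self, min_expected: float = 20.0) -> float:
        """Mean CoC over bins with at least ``min_expected`` expected events."""
        t = self.table
        sel = t["expected"] >= min_expected
        if not sel.any():
            return float("nan")
        return float(t.loc[sel, "coc"].mean())
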