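"""Reading, writing, and filtering of genotype, crossover, and coverage tables.

File conventions
----------------
* Genotype and marker tables are TSV with a header line; marker positions are
  1-based inclusive.
* Crossover events are exported as BED3+ (0-based, half-open): columns
  ``chrom``, ``start``, ``end``, ``individual``, ``midpoint``, ``transition``,
  ``flagged``.
* Coverage tracks are bedGraph-like TSV with an extra leading ``individual``
  column: ``individual``, ``chrom``, ``start``, ``end``, ``depth``.

Filtering follows the source study's printed thresholds with *strict*
inequalities: marker calls are kept only with mapping quality > 100 and
coverage > 2.5x; libraries (individuals) with < 50,000 SNP-associated reads
are dropped.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .models import MISSING, STATE_CODES, STATE_NAMES, ChromosomeModel, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_snps",
    "filter_libraries",
    "genotypes_to_frame",
    "genotypes_from_frame",
    "write_genotypes",
    "read_genotypes",
    "write_marker_map",
    "read_marker_map",
    "write_events_bed",
    "read_events_bed",
    "write_coverage",
    "read_coverage",
    "write_chromosomes",
    "read_chromosomes",
]


# ---------------------------------------------------------------------------
# filtering


def filter_snps(
    matrix: GenotypeMatrix, min_qual: float = 100.0, min_cov: float = 2.5
) -> GenotypeMatrix:
    """Set marker calls failing the quality/coverage thresholds to missing.

    A call is retained only when quality > ``min_qual`` AND coverage >
    ``min_cov`` (both strictly).  Already-missing calls stay missing.
    """
    if not np.isfinite(min_qual) or not np.isfinite(min_cov):
        raise ValueError("thresholds must be finite")
    if matrix.n_individuals == 0 or matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    out = matrix.copy()
    keep = (out.qual > min_qual) & (out.cov > min_cov)
    removed = int(((~keep) & (out.geno != MISSING)).sum())
    out.geno = np.where(keep, out.geno, MISSING).astype(np.int8)
    logger.info(
        "filter_snps: %d calls set to missing (qual<=%.6g or cov<=%.6g)",
        removed,
        min_qual,
        min_cov,
    )
    return out


def filter_libraries(matrix: GenotypeMatrix, min_reads: int = 50_000) -> GenotypeMatrix:
    """Drop individuals (libraries) with fewer than ``min_reads`` informative
    reads.  The boundary itself is kept (only strictly-below is excluded)."""
    keep = matrix.read_counts >= min_reads
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_libraries: dropped %d libraries with <%d reads", dropped, min_reads)
    if not keep.any():
        warnings.warn("all libraries fall below the read-count threshold", stacklevel=2)
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        matrix.markers.copy(),
        [matrix.individuals[i] for i in idx],
        matrix.geno[idx].copy(),
        matrix.qual[idx].copy(),
        matrix.cov[idx].copy(),
        matrix.read_counts[idx].copy(),
    )


# ---------------------------------------------------------------------------
# genotype matrix TSV (long format)


def genotypes_to_frame(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Long-format table: individual, chrom, pos, genotype, qual, cov,
    informative_reads."""
    n_ind, n_m = matrix.n_individuals, matrix.n_markers
    geno_names = np.array([STATE_NAMES[c] for c in (-1, 0, 1, 2)])
    return pd.DataFrame(
        {
            "individual": np.repeat(matrix.individuals, n_m),
            "chrom": np.tile(matrix.markers["chrom"].to_numpy(), n_ind),
            "pos": np.tile(matrix.markers["pos"].to_numpy(), n_ind),
            "genotype": geno_names[matrix.geno.ravel() + 1],
            "qual": np.round(matrix.qual.ravel(), 6),
            "cov": np.round(matrix.cov.ravel(), 6),
            "informative_reads": np.repeat(matrix.read_counts, n_m),
        }
    )


def genotypes_from_frame(frame: pd.DataFrame) -> GenotypeMatrix:
    required = {"individual", "chrom", "pos", "genotype", "qual", "cov", "informative_reads"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"genotype table missing columns: {sorted(missing_cols)}")
    bad = ~frame["genotype"].isin(STATE_CODES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"invalid genotype state at data row {row + 1}")

    individuals = list(dict.fromkeys(frame["individual"]))
    first = frame[frame["individual"] == individuals[0]]
    markers = first[["chrom", "pos"]].reset_index(drop=True)
    n_ind, n_m = len(individuals), len(markers)
    if len(frame) != n_ind * n_m:
        raise ValueError("genotype table is ragged: individuals cover different markers")

    codes = frame["genotype"].map(STATE_CODES).to_numpy(dtype=np.int8).reshape(n_ind, n_m)
    qual = frame["qual"].to_numpy(dtype=float).reshape(n_ind, n_m)
    cov = frame["cov"].to_numpy(dtype=float).reshape(n_ind, n_m)
    reads = (
        frame["informative_reads"].to_numpy(dtype=np.int64).reshape(n_ind, n_m)[:, 0]
    )
    return GenotypeMatrix(markers, individuals, codes, qual, cov, reads)


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    genotypes_to_frame(matrix).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    return genotypes_from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# marker map TSV


def write_marker_map(markers: pd.DataFrame, path) -> None:
    markers[["chrom", "pos"]].to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    markers = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"} <= set(markers.columns):
        raise ValueError("marker map must have columns chrom, pos")
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"marker positions not strictly increasing on {chrom}")
    return markers


# ---------------------------------------------------------------------------
# crossover events BED3+


def write_events_bed(events: pd.DataFrame, path) -> None:
    """Write crossover events as BED3+ (internal 1-based inclusive intervals
    become 0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": events["chrom"],
            "start": events["start"].astype(np.int64) - 1,
            "end": events["end"].astype(np.int64),
            "individual": events["individual"],
            "midpoint": np.round(events["midpoint"], 1),
            "transition": events["transition"],
            "flagged": events["flagged"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_events_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "individual", "midpoint", "transition", "flagged"}
    if not required <= set(bed.columns):
        raise ValueError(f"events BED missing columns: {sorted(required - set(bed.columns))}")
    bad = (bed["end"] <= bed["start"]).to_numpy()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"BED interval end <= start at data row {row + 1}")
    return pd.DataFrame(
        {
            "individual": bed["individual"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(np.int64) + 1,
            "end": bed["end"].astype(np.int64),
            "midpoint": bed["midpoint"].astype(float),
            "transition": bed["transition"],
            "flagged": bed["flagged"].astype(bool),
        }
    )


# ---------------------------------------------------------------------------
# coverage bedGraph-like TSV


def write_coverage(track: pd.DataFrame, path) -> None:
    out = track[["individual", "chrom", "start", "end", "depth"]].copy()
    out["depth"] = np.round(out["depth"], 6)
    out.to_csv(path, sep="\t", index=False)


def read_coverage(path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t")
    required = {"individual", "chrom", "start", "end", "depth"}
    if not required <= set(track.columns):
        raise ValueError(f"coverage table missing columns: {sorted(required - set(track.columns))}")
    bad = (track["end"] <= track["start"]).to_numpy()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"coverage window end <= start at data row {row + 1}")
    if (track["depth"] < 0).any():
        raise ValueError("coverage depth must be >= 0")
    return track


# ---------------------------------------------------------------------------
# chromosome annotation TSV


def write_chromosomes(chromosomes: list[ChromosomeModel], path) -> None:
    rows = []
    for ch in chromosomes:
        peri = ";".join(f"{lo}-{hi}" for lo, hi in ch.pericentromere)
        rows.append((ch.name, ch.length, ch.centromere_mid, peri))
    pd.DataFrame(
        rows, columns=["name", "length", "centromere_mid", "pericentromeres"]
    ).to_csv(path, sep="\t", index=False)


def read_chromosomes(path) -> list[ChromosomeModel]:
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"name", "length", "centromere_mid", "pericentromeres"}
    if not required <= set(table.columns):
        raise ValueError(
            f"chromosome table missing columns: {sorted(required - set(table.columns))}"
        )
    out = []
    for _, row in table.iterrows():
        peri = []
        if str(row["pericentromeres"]).strip():
            for part in str(row["pericentromeres"]).split(";"):
                lo, hi = part.split("-")
                peri.append((int(lo), int(hi)))
        out.append(
            ChromosomeModel(
                str(row["name"]),
                int(row["length"]),
                int(row["centromere_mid"]),
                tuple(peri),
            )
        )
    return out
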