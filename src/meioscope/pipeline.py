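"""Pipeline orchestration: config validation and stage chaining.

A run config is a YAML mapping with a mandatory ``seed`` and optional
per-stage parameter sections.  Stages execute in dependency order
(simulate -> filter -> call -> ploidy -> interference -> landscape -> rf);
each stage failure aborts with a stage-tagged error.  The run writes every
intermediate table as TSV plus a machine-readable JSON manifest listing each
output file with its row count and SHA-256 digest, along with a hash of the
resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import genotype_io
from .crossover_caller import call_crossovers, exclude_aneuploids, segment_genotypes
from .interference_stats import analyze_interference
from .landscape import scale_arms, window_frequency, regional_reduction
from .models import ChromosomeModel, SimConfig, arabidopsis_chromosomes
from .ploidy_caller import call_ploidy
from .ftl_rf import recombination_frequency, rf_bootstrap_ci
from .sim_meiosis import simulate_coverage, simulate_f2_population, simulate_seed_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_TOP_KEYS = {
    "seed",
    "n_individuals",
    "chromosomes",
    "sim",
    "filter",
    "call",
    "ploidy",
    "interference",
    "landscape",
    "rf",
}
_SECTION_KEYS = {
    "sim": {
        "class1_mean",
        "nu",
        "class2_mean",
        "obligate_escape_p",
        "geno_error_p",
        "marker_spacing",
        "terminal_fraction",
        "base_depth",
        "noise_sd",
        "coverage_window",
    },
    "filter": {"min_qual", "min_cov", "min_lib_reads"},
    "call": {"window_markers", "purity", "min_segment_markers"},
    "ploidy": {"trisomy", "monosomy"},
    "interference": {"n_sample", "boot_iters", "bin_width"},
    "landscape": {"window", "n_bins"},
    "rf": {"rf_cm", "n_total", "ci_iters"},
}


def _check_keys(config: dict) -> None:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        extra = set(config.get(section, {})) - allowed
        if extra:
            raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")


def load_config(path) -> dict:
    """Load and validate a YAML run config (unknown keys rejected, seed
    mandatory)."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("config must be a YAML mapping")
    _check_keys(config)
    if "seed" not in config:
        raise ValueError("config must set an explicit seed")
    return config


def _chromosomes_from_config(config: dict) -> list[ChromosomeModel]:
    chrom_spec = config.get("chromosomes", "arabidopsis")
    if chrom_spec == "arabidopsis":
        return arabidopsis_chromosomes()
    out = []
    for entry in chrom_spec:
        out.append(
            ChromosomeModel(
                entry["name"],
                int(entry["length"]),
                int(entry["centromere_mid"]),
                tuple(tuple(p) for p in entry.get("pericentromere", [])),
            )
        )
    return out


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _row_count(path: Path) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)  # minus header


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full pipeline under ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_keys(config)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    files: dict[str, Path] = {}
    results: dict = {}

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        chroms = _chromosomes_from_config(config)
        sim_cfg = config.get("sim", {})
        cov_keys = {"base_depth", "noise_sd", "coverage_window"}
        sim = SimConfig(
            chromosomes=chroms,
            seed=seed,
            **{k: v for k, v in sim_cfg.items() if k not in cov_keys},
        )
        n_individuals = int(config.get("n_individuals", 200))
        matrix, record = simulate_f2_population(sim, n_individuals, rng=rng)
        base_depth = float(sim_cfg.get("base_depth", 20.0))
        noise_sd = float(sim_cfg.get("noise_sd", 2.0))
        coverage_window = int(sim_cfg.get("coverage_window", 100_000))
        coverage = simulate_coverage(
            record, window_bp=coverage_window, base_depth=base_depth,
            noise_sd=noise_sd, rng=rng,
        )
        files["genotypes"] = out / "genotypes.tsv"
        genotype_io.write_genotypes(matrix, files["genotypes"])
        files["markers"] = out / "markers.tsv"
        genotype_io.write_marker_map(matrix.markers, files["markers"])
        files["coverage"] = out / "coverage.tsv"
        genotype_io.write_coverage(coverage, files["coverage"])
        files["chromosomes"] = out / "chromosomes.tsv"
        genotype_io.write_chromosomes(chroms, files["chromosomes"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise PipelineError(stage, str(exc)) from exc

    # --- filter -------------------------------------------------------
    stage = "filter"
    try:
        f = config.get("filter", {})
        matrix = genotype_io.filter_snps(
            matrix, min_qual=f.get("min_qual", 100.0), min_cov=f.get("min_cov", 2.5)
        )
        matrix = genotype_io.filter_libraries(
            matrix, min_reads=f.get("min_lib_reads", 50_000)
        )
        files["genotypes_filtered"] = out / "genotypes.filtered.tsv"
        genotype_io.write_genotypes(matrix, files["genotypes_filtered"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- call ---------------------------------------------------------
    stage = "call"
    try:
        c = config.get("call", {})
        segments = segment_genotypes(
            matrix,
            window_markers=c.get("window_markers", 15),
            purity=c.get("purity", 0.8),
            min_segment_markers=c.get("min_segment_markers", 5),
        )
        events = call_crossovers(segments)
        files["segments"] = out / "segments.tsv"
        segments.to_csv(files["segments"], sep="\t", index=False)
        files["events"] = out / "events.bed"
        genotype_io.write_events_bed(events, files["events"])
        summary = (
            events.groupby(["individual", "chrom"], sort=False)
            .size()
            .rename("n_CO")
            .reset_index()
        )
        files["co_summary"] = out / "co_summary.tsv"
        summary.to_csv(files["co_summary"], sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- ploidy -------------------------------------------------------
    stage = "ploidy"
    try:
        p = config.get("ploidy", {})
        ploidy = call_ploidy(
            coverage, chroms, trisomy=p.get("trisomy", 1.2), monosomy=p.get("monosomy", 0.8)
        )
        files["ploidy"] = out / "ploidy.tsv"
        ploidy.to_csv(files["ploidy"], sep="\t", index=False, float_format="%.6g")
        events = exclude_aneuploids(events, ploidy)
        files["events_euploid"] = out / "events.euploid.bed"
        genotype_io.write_events_bed(events, files["events_euploid"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- interference -------------------------------------------------
    stage = "interference"
    try:
        i = config.get("interference", {})
        report = analyze_interference(
            segments[segments["individual"].isin(events["individual"].unique())]
            if len(events)
            else segments,
            events,
            n_sample=i.get("n_sample", 400),
            boot_iters=i.get("boot_iters", 1000),
            bin_width=i.get("bin_width", 3.5e6),
            rng=rng,
        )
        files["coc"] = out / "coc.tsv"
        report.coc.table.to_csv(files["coc"], sep="\t", index=False, float_format="%.6g")
        files["gamma_fit"] = out / "gamma_fit.json"
        boot_obs = report.fit_observed.bootstrap_shapes
        boot_exp = report.fit_expected.bootstrap_shapes
        gamma_json = {
            "observed": {
                "shape": report.fit_observed.shape,
                "rate": report.fit_observed.rate,
                "n": report.fit_observed.n,
                "bootstrap_quantiles": np.percentile(boot_obs, [2.5, 50, 97.5]).tolist(),
            },
            "expected": {
                "shape": report.fit_expected.shape,
                "rate": report.fit_expected.rate,
                "n": report.fit_expected.n,
                "bootstrap_quantiles": np.percentile(boot_exp, [2.5, 50, 97.5]).tolist(),
            },
            "p_shape": report.p_shape,
            "median_observed": report.median_observed,
            "median_expected": report.median_expected,
        }
        files["gamma_fit"].write_text(json.dumps(gamma_json, indent=2, sort_keys=True))
        results["interference"] = gamma_json
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- landscape ----------------------------------------------------
    stage = "landscape"
    try:
        l = config.get("landscape", {})
        if not any(ch.pericentromere for ch in chroms):
            raise ValueError(
                "pericentromere annotation required by the landscape stage "
                "(supply pericentromere intervals in the chromosome models)"
            )
        n_euploid = events["individual"].nunique() if len(events) else 1
        profile = window_frequency(
            events, n_euploid, chroms, window=l.get("window", 300_000)
        )
        scaled = scale_arms(profile, chroms, n_bins=l.get("n_bins", 20))
        files["landscape"] = out / "landscape.tsv"
        profile.to_csv(files["landscape"], sep="\t", index=False, float_format="%.6g")
        files["landscape_scaled"] = out / "landscape.scaled.tsv"
        scaled.to_csv(files["landscape_scaled"], sep="\t", index=False, float_format="%.6g")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- rf -----------------------------------------------------------
    if "rf" in config:
        stage = "rf"
        try:
            r = config["rf"]
            counts = simulate_seed_counts(float(r["rf_cm"]), int(r["n_total"]), rng=rng)
            rf = recombination_frequency(counts)
            low, high = rf_bootstrap_ci(counts, iters=r.get("ci_iters", 1000), rng=rng)
            results["rf"] = {
                "n_green": counts.n_green,
                "n_red": counts.n_red,
                "n_total": counts.n_total,
                "rf_cm": rf,
                "ci_low": low,
                "ci_high": high,
            }
            files["rf"] = out / "rf.json"
            files["rf"].write_text(json.dumps(results["rf"], indent=2, sort_keys=True))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # --- manifest -----------------------------------------------------
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "seed": seed,
        "config_sha256": config_hash,
        "outputs": {
            name: {
                "path": path.name,
                "rows": _row_count(path) if path.suffix in (".tsv", ".bed") else None,
                "sha256": _sha256(path),
            }
            for name, path in sorted(files.items())
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d outputs in %s", len(files), out)
    return manifest
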