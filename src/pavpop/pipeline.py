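"""Composition of the analysis stages into reproducible runs.

Each ``run_*`` function wires dataio + one analysis module into a complete
stage: synthetic or on-disk inputs in, result tables out, with a
provenance block (config hash, seed, package version) written beside every
output set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, pangenome, selection, sweep, synthdata
from .dataio import PAVMatrix, write_table
from .errors import DataError

logger = logging.getLogger(__name__)


def bonferroni_threshold(family_alpha: float = 0.05, n_tests: int = 8_580_000) -> float:
    """Per-test significance threshold controlling the family-wise rate."""
    if n_tests < 1:
        raise DataError("n_tests must be >= 1")
    return family_alpha / n_tests


def _provenance(config: dict, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "version": __version__,
    }


def _write_outputs(outdir: Path, tables: dict[str, pd.DataFrame], prov: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        write_table(df, outdir / f"{name}.tsv")
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")


def run_pangenome(
    pav: PAVMatrix,
    metadata: pd.DataFrame,
    outdir: str | Path | None = None,
    min_present: int = 0,
    k_max: int = 6,
    restarts: int = 20,
    alpha: float = 0.05,
    min_freq: float = 0.1,
    seed: int = 0,
) -> dict:
    """Library filter -> occupancy classification -> enrichment -> private genes."""
    if pav.data.empty:
        raise DataError("pangenome stage: empty PAV matrix")
    config = dict(
        min_present=min_present, k_max=k_max, restarts=restarts,
        alpha=alpha, min_freq=min_freq,
    )
    filtered, excluded = pangenome.filter_libraries(pav, min_present)
    if filtered.data.empty or not len(filtered.libraries):
        raise DataError("pangenome stage: no libraries left after filtering")
    classification = pangenome.classify_occupancy(
        filtered.occupancy(), k_max=k_max, restarts=restarts, seed=seed
    )
    enrichment = pangenome.chisq_enrichment(filtered, metadata, alpha=alpha)
    private = pangenome.private_genes(filtered, metadata, min_freq=min_freq)

    class_table = pd.DataFrame(
        {
            "occupancy": filtered.occupancy(),
            "class": classification.labels,
        }
    )
    results = {
        "classification": classification,
        "class_table": class_table,
        "enrichment": enrichment,
        "private": private,
        "excluded_libraries": excluded,
    }
    if outdir is not None:
        bic_table = pd.DataFrame(
            sorted(classification.bic.items()), columns=["k", "bic"]
        ).set_index("k")
        _write_outputs(
            Path(outdir),
            {
                "classes": class_table,
                "bic": bic_table,
                "enrichment": enrichment,
                "private_genes": private,
            },
            _provenance(config, seed),
        )
    return results


def run_selection(
    haps,
    outdir: str | Path | None = None,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    tajima_window_bp: int = 10_000,
    ihs_cutoff: float = 0.05,
    ihs_threshold: float = 2.0,
    n_bins: int = 50,
    min_snps: int = 10,
    outlier_fraction: float = 0.01,
    seed: int = 0,
) -> dict:
    """iHS scan + windowed extreme-fraction outliers, and Tajima's D windows."""
    config = dict(
        window_bp=window_bp, step_bp=step_bp, tajima_window_bp=tajima_window_bp,
        ihs_cutoff=ihs_cutoff, ihs_threshold=ihs_threshold, n_bins=n_bins,
        min_snps=min_snps, outlier_fraction=outlier_fraction,
    )
    records = selection.ihs_scan(haps, cutoff=ihs_cutoff)
    records = selection.standardize_ihs(records, n_bins=n_bins)
    ihs_table = pd.DataFrame(
        {
            "position": [r.position for r in records],
            "derived_freq": [r.derived_freq for r in records],
            "ihs": [r.ihs for r in records],
            "ihs_std": [r.ihs_std for r in records],
        }
    )
    windows = selection.scan_windows(
        ihs_table["position"].to_numpy(),
        ihs_table["ihs_std"].to_numpy(),
        window_bp=window_bp,
        step_bp=step_bp,
        stat="fraction_extreme",
        threshold=ihs_threshold,
        min_snps=min_snps,
    )
    ihs_outliers = selection.outlier_windows(
        windows, tail="upper", fraction=outlier_fraction
    )

    derived, n_alleles = selection.haplotype_counts(haps)
    tajima = selection.tajima_windows(
        haps.positions, derived, n_alleles, haps.n_hap, window_bp=tajima_window_bp
    )
    tajima_out = selection.outlier_windows(
        tajima.rename(columns={"D": "value"}),
        tail="lower",
        fraction=outlier_fraction,
    ).rename(columns={"value": "D"})

    results = {
        "ihs": ihs_table,
        "ihs_windows": ihs_outliers,
        "tajima_windows": tajima_out,
    }
    if outdir is not None:
        _write_outputs(
            Path(outdir),
            {
                "ihs_sites": ihs_table,
                "ihs_windows": ihs_outliers,
                "tajima_windows": tajima_out,
            },
            _provenance(config, seed),
        )
    return results


def run_sweep(
    observed_ratio: float,
    target_genomewide_ratio: float = 0.22,
    window_bp: int = 20_000,
    n: int = 40,
    calib_reps: int = 3000,
    test_reps: int = 20_000,
    outdir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Calibrate the bottleneck, then test an observed local diversity ratio."""
    config = dict(
        observed_ratio=observed_ratio, target=target_genomewide_ratio,
        window_bp=window_bp, n=n, calib_reps=calib_reps, test_reps=test_reps,
    )
    theta = sweep.theta_per_window(window_bp)
    severity = sweep.calibrate_bottleneck(
        target_genomewide_ratio, n=n, theta=theta, reps=calib_reps, seed=seed
    )
    dem_b = sweep.Demography.bottleneck(severity, n=n)
    dem_c = sweep.Demography.constant(n)
    test = sweep.pi_ratio_test(
        observed_ratio, dem_b, dem_c, theta=theta,
        window_bp=window_bp, reps=test_reps, seed=seed + 1,
    )
    results = {"severity": severity, **test}
    if outdir is not None:
        table = pd.DataFrame([results | {"ratio_quantiles": ""}]).T
        _write_outputs(Path(outdir), {"sweep_test": table}, _provenance(config, seed))
    return results


def demo(outdir: str | Path, seed: int = 0) -> dict:
    """Generate synthetic inputs and run the three analyses end to end."""
    rng_seed = int(seed)
    outdir = Path(outdir)
    specs = [
        synthdata.PAVClassSpec(2000, 0.98),
        synthdata.PAVClassSpec(1500, 0.56),
        synthdata.PAVClassSpec(1500, 0.12),
    ]
    pav, truth = synthdata.gen_pav_matrix(
        specs,
        n_libraries=302,
        subpop_sizes={"Central": 35, "Central-East": 59, "Central-North": 78, "West-Coast": 130},
        seed=rng_seed,
    )
    metadata = synthdata.subpop_metadata(truth)
    pan = run_pangenome(pav, metadata, outdir / "pangenome", seed=rng_seed)

    haps, sweep_truth = synthdata.gen_sweep_haplotypes(
        n_hap=120, n_snps=400, seed=rng_seed
    )
    sel = run_selection(haps, outdir / "selection", min_snps=5, seed=rng_seed)

    swp = run_sweep(
        observed_ratio=0.05,
        calib_reps=1500,
        test_reps=2000,
        outdir=outdir / "sweep",
        seed=rng_seed,
    )
    return {"pangenome": pan, "selection": sel, "sweep": swp, "truth": truth,
            "sweep_truth": sweep_truth}
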