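"""End-to-end runs: simulate -> extract -> analyze -> reproduce.

Each stage consumes and produces plain CSV so stages are independently
testable and scriptable. Every emitted table carries a provenance header
(comment lines starting with ``#``: package version, options, seed) and
each run writes a ``run_manifest.txt`` with row counts, warnings and
SHA-256 checksums of the outputs, so a run can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, reference
from .imaging import RoiSpec, extract_roi, load_image, save_image
from .simulate import CohortSimConfig, ImageSimConfig, simulate_cohort, \
    simulate_roi
from .stats import average_correlations, build_correlation_table, \
    em_impute, encode_glm_predictors, standardized_glm
from .texture import averaged_features

logger = logging.getLogger(__name__)


class RunError(RuntimeError):
    """A pipeline stage could not produce a usable output."""


def _provenance_lines(stage: str, options: dict) -> list[str]:
    opts = " ".join(f"{k}={v}" for k, v in sorted(options.items()))
    return [f"# echotex {__version__} stage={stage}", f"# {opts}"]


def _write_table(df: pd.DataFrame, path: Path, stage: str,
                 options: dict) -> str:
    buf = io.StringIO()
    for line in _provenance_lines(stage, options):
        buf.write(line + "\n")
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    path.write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


def _write_manifest(out_dir: Path, stage: str, options: dict,
                    counts: dict, warnings_list: list[str],
                    checksums: dict[str, str]) -> Path:
    lines = [f"echotex_version: {__version__}", f"stage: {stage}"]
    lines += [f"option.{k}: {v}" for k, v in sorted(options.items())]
    lines += [f"rows.{k}: {v}" for k, v in counts.items()]
    lines += [f"warning: {w}" for w in warnings_list]
    lines += [f"sha256.{name}: {h}" for name, h in sorted(checksums.items())]
    path = out_dir / "run_manifest.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# simulate

def run_simulate_images(out_dir: str | Path, *, n_images: int = 10,
                        seed: int = 0,
                        heterogeneity: tuple[float, float] = (0.0, 1.0),
                        image: ImageSimConfig | None = None) -> Path:
    """Write synthetic ROIs as PNGs plus an ROI manifest and sidecar.

    Heterogeneity is spaced evenly across ``n_images`` over the given
    range; the sidecar records each image's latent parameters so recovery
    tests can grade feature estimates against ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = image or ImageSimConfig()
    rng = np.random.default_rng(seed)
    hets = np.linspace(heterogeneity[0], heterogeneity[1], n_images)
    rows, sidecar = [], []
    for i, het in enumerate(hets):
        cfg = ImageSimConfig(height=base.height, width=base.width,
                             base_level=base.base_level,
                             speckle_scale=base.speckle_scale,
                             speckle_amplitude=base.speckle_amplitude,
                             heterogeneity=float(het),
                             infiltration_brightness=base.infiltration_brightness,
                             n_streaks=base.n_streaks,
                             seed=int(rng.integers(0, 2**31 - 1)))
        img = simulate_roi(cfg)
        name = f"roi_{i:04d}.png"
        save_image(out_dir / name, img)
        side = min(50, base.height, base.width)
        rows.append({"subject_id": f"S{i:05d}", "image": name,
                     "roi_row": 0, "roi_col": 0, "roi_side": side})
        sidecar.append({"subject_id": f"S{i:05d}", **asdict(cfg)})
    opts = {"n_images": n_images, "seed": seed}
    checks = {
        "roi_manifest.csv": _write_table(pd.DataFrame(rows),
                                         out_dir / "roi_manifest.csv",
                                         "simulate-images", opts),
        "ground_truth.csv": _write_table(pd.DataFrame(sidecar),
                                         out_dir / "ground_truth.csv",
                                         "simulate-images", opts),
    }
    _write_manifest(out_dir, "simulate-images", opts,
                    {"images": n_images}, [], checks)
    return out_dir / "roi_manifest.csv"


def run_simulate_cohort(out_dir: str | Path,
                        config: CohortSimConfig) -> Path:
    """Write a synthetic cohort CSV (+ latent ground-truth sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(config)
    opts = {"n_subjects": config.n_subjects, "seed": config.seed,
            "missing_rate": config.missing_rate,
            "missing_mechanism": config.missing_mechanism}
    checks = {
        "cohort.csv": _write_table(sim.data, out_dir / "cohort.csv",
                                   "simulate-cohort", opts),
        "cohort_latent.csv": _write_table(sim.latent,
                                          out_dir / "cohort_latent.csv",
                                          "simulate-cohort", opts),
    }
    _write_manifest(out_dir, "simulate-cohort", opts,
                    {"subjects": len(sim.data)}, [], checks)
    return out_dir / "cohort.csv"


# ---------------------------------------------------------------------------
# extract

def run_extract(manifest_csv: str | Path, out_dir: str | Path, *,
                image_dir: str | Path | None = None,
                levels: int = 256, correlation_variant: str = "walker",
                averaging: str = "feature") -> Path:
    """Texture features for every image listed in an ROI manifest.

    The manifest CSV needs columns ``subject_id, image, roi_row, roi_col,
    roi_side``. Per-image failures are logged and counted; the run only
    fails if no image succeeds.
    """
    manifest_csv = Path(manifest_csv)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_dir = Path(image_dir) if image_dir else manifest_csv.parent
    manifest = pd.read_csv(manifest_csv, comment="#")
    rows, failures = [], []
    for rec in manifest.itertuples(index=False):
        try:
            img = load_image(image_dir / rec.image)
            roi = extract_roi(img, RoiSpec(int(rec.roi_row),
                                           int(rec.roi_col),
                                           int(rec.roi_side)))
            f = averaged_features(roi, levels=levels,
                                  correlation_variant=correlation_variant,
                                  averaging=averaging)
            rows.append({"subject_id": rec.subject_id, "image": rec.image,
                         "asm": f.asm, "entropy": f.entropy, "idm": f.idm,
                         "correlation": f.correlation,
                         "contrast": f.contrast,
                         "echo_intensity": f.echo_intensity})
        except Exception as exc:
            failures.append(f"{rec.image}: {exc}")
            logger.warning("EXTRACT_FAIL %s: %s", rec.image, exc)
    if not rows:
        raise RunError("no image could be processed")
    opts = {"levels": levels, "correlation_variant": correlation_variant,
            "averaging": averaging,
            "displacements": "[0 1],[-1 1],[-1 0],[-1 -1]"}
    out = out_dir / "features.csv"
    checks = {"features.csv": _write_table(pd.DataFrame(rows), out,
                                           "extract", opts)}
    _write_manifest(out_dir, "extract", opts,
                    {"images_in": len(manifest), "features_out": len(rows),
                     "failures": len(failures)}, failures, checks)
    return out


# ---------------------------------------------------------------------------
# analyze

_SUMMARY_COLS = ("age", "bmi", "egfr", "hb", "albumin",
                 "asm", "entropy", "idm", "correlation", "contrast",
                 "echo_intensity",
                 "iswt", "gait_speed", "tuag", "sts60", "hgs")


def run_analyze(cohort_csv: str | Path, out_dir: str | Path, *,
                features_csv: str | Path | None = None,
                em_tol: float = 1e-6) -> dict[str, Path]:
    """Cohort summary, correlation grid and predictor tables.

    ``table1_summary.csv``: mean/SD per variable. ``table2_correlations.csv``:
    the feature x test Spearman grid with the Fisher-z average column.
    ``table3_predictors.csv``: standardized GLM of each texture feature on
    the clinical predictors, with EM-imputed covariates. Correlations use
    pairwise deletion (no imputed values), the GLM uses the imputed
    covariate matrix — mirroring the modeled workflow.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(cohort_csv, comment="#")
    if features_csv is not None:
        feats = pd.read_csv(features_csv, comment="#")
        drop = [c for c in feats.columns
                if c in cohort.columns and c != "subject_id"]
        cohort = cohort.drop(columns=drop).merge(
            feats.drop(columns=[c for c in ("image",) if c in feats]),
            on="subject_id", how="inner")
    if len(cohort) < 3:
        raise RunError(f"joined cohort has {len(cohort)} subjects (< 3)")

    opts = {"em_tol": em_tol, "n_subjects": len(cohort)}
    warn_list: list[str] = []

    summary_rows = [{"variable": c,
                     "mean": cohort[c].mean(),
                     "sd": cohort[c].std(ddof=1),
                     "n_observed": int(cohort[c].notna().sum())}
                    for c in _SUMMARY_COLS if c in cohort.columns]
    table1 = pd.DataFrame(summary_rows)

    ctab = build_correlation_table(cohort)
    table2 = ctab.to_frame()

    encoded = encode_glm_predictors(cohort)
    if encoded.isna().any().any():
        filled, imp = em_impute(encoded.to_numpy(), tol=em_tol)
        encoded = pd.DataFrame(filled, columns=encoded.columns,
                               index=encoded.index)
        if not imp.converged_:
            warn_list.append("EM imputation did not reach tolerance")
    rows3 = []
    for feat in reference.FEATURE_NAMES:
        y = cohort[feat]
        ok = y.notna()
        if ok.sum() <= encoded.shape[1] + 1:
            warn_list.append(f"too few rows to model {feat}")
            continue
        if y[ok].std(ddof=1) == 0:
            warn_list.append(f"constant outcome {feat}; GLM skipped")
            continue
        try:
            results = standardized_glm(y[ok], encoded[ok])
        except ValueError as exc:  # includes collinear designs
            warn_list.append(f"GLM for {feat} failed: {exc}")
            continue
        for res in results:
            rows3.append({"outcome": feat, "predictor": res.name,
                          "beta": res.beta, "t": res.t_stat,
                          "p": res.p_value})
    table3 = pd.DataFrame(rows3)

    paths = {"table1": out_dir / "table1_summary.csv",
             "table2": out_dir / "table2_correlations.csv",
             "table3": out_dir / "table3_predictors.csv"}
    checks = {p.name: _write_table(t, p, "analyze", opts)
              for t, p in ((table1, paths["table1"]),
                           (table2, paths["table2"]),
                           (table3, paths["table3"]))}
    _write_manifest(out_dir, "analyze", opts,
                    {"subjects": len(cohort), "table2_rows": len(table2),
                     "table3_rows": len(table3)}, warn_list, checks)
    return paths


# ---------------------------------------------------------------------------
# reproduce

def run_reproduce(rho_grid: dict[str, dict[str, float]] | None = None):
    """Recompute the published Fisher-z average column from the rho grid.

    Uses the packaged reference grid when ``rho_grid`` is None. Returns
    ``(ok, report)`` where ``report`` is a DataFrame with the recomputed
    averages at 3 decimals next to the published column, plus the
    best-ranked (largest |average|) feature. ``ok`` is False on any
    3-decimal mismatch.
    """
    grid = rho_grid if rho_grid is not None else reference.REFERENCE_RHO
    rows = []
    ok = True
    best_feat, best_mag = None, -1.0
    for feat in reference.FEATURE_NAMES:
        rhos = [grid[feat][t] for t in reference.TEST_NAMES]
        agg = average_correlations(rhos)
        expected = reference.REFERENCE_AVERAGE_R[feat]
        match = agg.r_rounded == round(expected, 3)
        ok &= match
        rows.append({"feature": feat, "computed_average_r": agg.r_rounded,
                     "published_average_r": expected, "match": match})
        if abs(agg.r_back) > best_mag:
            best_feat, best_mag = feat, abs(agg.r_back)
    report = pd.DataFrame(rows)
    report.attrs["best_feature"] = best_feat
    ok &= (best_feat == reference.REFERENCE_BEST_FEATURE)
    return ok, report
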