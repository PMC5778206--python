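"""Run-level workflow: measure a directory of slice images, aggregate per
sample, run the statistical layer, and emit tables and figures.

Outputs of a full run:

* ``measurements.csv`` — per-particle and per-image rows;
* ``summary_table.csv`` — one row per sample with mean, SD and Duncan
  letter for each statistic (the per-sample results table);
* ``grouping.csv`` — long-format Duncan letters with F and p per statistic;
* ``histogram_<sample>.csv`` / ``.png`` — ten-class particle-area
  frequency distributions;
* ``pca_loadings.csv`` / ``pca_scores.csv`` / ``pca_scree.png`` /
  ``pca_biplot.png`` — correlation-matrix PCA over the per-sample means;
* ``correlation.csv`` / ``correlation.png`` — visible vs chemical fat
  regression (only when a chemical table is supplied);
* ``manifest.json`` — config snapshot, input checksums, warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .io import PipelineConfig, read_image, read_measurements, write_measurements
from .morphometry import STATISTIC_NAMES, measure_slice
from .stats import anova_duncan, correlate_vfc_chemical, pca_correlation

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def sample_of(source_id: str) -> str:
    """Sample id = file stem up to the first underscore (rest = replicate)."""
    return str(source_id).split("_", 1)[0]


def measure_directory(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
    cm_per_pixel: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Measure every readable image in a directory.

    Unreadable or unsegmentable images are logged and skipped; the run
    fails only when no image can be measured at all.  Returns the
    per-image summary frame and the manifest dict; both are also written
    to ``output_dir``.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no images found in {input_dir}")
    measurements, inputs, warnings_log = [], [], []
    for path in paths:
        try:
            image = read_image(path, cm_per_pixel)
            m, _, _ = measure_slice(image, config)
            measurements.append(m)
            inputs.append({"path": str(path), "sha256": _sha256(path)})
        except Exception as exc:  # robust batch: skip, never abort the run
            msg = f"skipped {path.name}: {exc}"
            logger.warning(msg)
            warnings_log.append(msg)
    if not measurements:
        raise RuntimeError(f"no readable images in {input_dir}")
    csv_path = output_dir / "measurements.csv"
    write_measurements(measurements, csv_path)
    manifest = {
        "tool": "salamivision",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.asdict(),
        "cm_per_pixel": cm_per_pixel,
        "inputs": inputs,
        "outputs": [str(csv_path)],
        "warnings": warnings_log,
        "conventions": {"connectivity": 8, "perimeter": "subpixel contour, 1 px simplification"},
    }
    with open(output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    images_df, _ = read_measurements(csv_path)
    return images_df, manifest


def build_summary_table(images_df: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample mean/SD of each statistic plus Duncan letters.

    Returns ``(summary, grouping)``: ``summary`` has one row per sample
    with ``<stat>_mean``, ``<stat>_sd`` and ``<stat>_letters`` columns;
    ``grouping`` is the long form with the omnibus F and p per statistic.
    Letters are skipped (empty) when fewer than two samples or fewer than
    two replicates per sample are available.
    """
    df = images_df.copy()
    df["sample"] = df["source_id"].map(sample_of)
    samples = sorted(df["sample"].unique())
    rows = {s: {"sample": s, "n_replicates": int((df["sample"] == s).sum())} for s in samples}
    grouping_rows = []
    for stat in STATISTIC_NAMES:
        groups = {s: df.loc[df["sample"] == s, stat].to_numpy() for s in samples}
        for s in samples:
            vals = groups[s]
            rows[s][f"{stat}_mean"] = float(np.mean(vals))
            rows[s][f"{stat}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        can_test = len(samples) >= 2 and all(len(v) >= 2 for v in groups.values())
        if can_test:
            res = anova_duncan(groups, alpha=alpha)
            letters = res.letters()
            for s in samples:
                rows[s][f"{stat}_letters"] = letters[s]
                grouping_rows.append({
                    "statistic": stat, "sample": s, "mean": rows[s][f"{stat}_mean"],
                    "letters": letters[s], "F": res.f_statistic, "p": res.p_value,
                })
        else:
            logger.warning("Duncan grouping for %s skipped: need >=2 samples with >=2 replicates", stat)
            for s in samples:
                rows[s][f"{stat}_letters"] = ""
    summary = pd.DataFrame([rows[s] for s in samples])
    return summary, pd.DataFrame(grouping_rows)


def summary_extremes(summary: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Min/max of each per-sample mean column of a summary table.

    The ranges of these columns are the headline descriptive numbers of
    a study (e.g. the span of mean particle areas across samples).
    """
    out = {}
    for stat in STATISTIC_NAMES:
        col = summary[f"{stat}_mean"]
        out[stat] = {"min": float(col.min()), "max": float(col.max())}
    return out


def _read_chemical(path: str | Path) -> pd.Series:
    chem = pd.read_csv(path)
    cols = {c.lower(): c for c in chem.columns}
    sample_col = cols.get("sample", cols.get("sample_id"))
    fat_col = cols.get("fat_pct", cols.get("chemical_fat_pct"))
    if sample_col is None or fat_col is None:
        raise ValueError(f"chemical table {path} needs columns sample[_id] and fat_pct")
    return chem.set_index(chem[sample_col].astype(str))[fat_col].astype(float)


def summarize_run(
    measurements_csv: str | Path,
    output_dir: str | Path,
    chemical_csv: str | Path | None = None,
    alpha: float = 0.05,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Aggregate a measurement CSV into the full statistical report."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    images_df, particles_df = read_measurements(measurements_csv)
    n_samples = images_df["source_id"].map(sample_of).nunique()
    if n_samples < 2:
        logger.warning("fewer than 2 samples: statistics skipped, summary only")
    summary, grouping = build_summary_table(images_df, alpha=alpha)
    summary.to_csv(output_dir / "summary_table.csv", index=False, float_format="%.12g")
    if not grouping.empty:
        grouping.to_csv(output_dir / "grouping.csv", index=False, float_format="%.12g")
    _write_histograms(particles_df, config, output_dir)
    if n_samples >= 3:
        _run_pca(summary, chemical_csv, output_dir)
    if chemical_csv is not None and n_samples >= 3:
        _run_correlation(summary, chemical_csv, output_dir)
    return summary


def _write_histograms(particles_df: pd.DataFrame, config: PipelineConfig, output_dir: Path) -> None:
    from .morphometry import AreaClassHistogram  # labels only

    edges = config.area_class_edges
    labels = [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])] + [f">={edges[-1]:g}"]
    particles_df = particles_df.copy()
    particles_df["sample"] = particles_df["source_id"].map(sample_of)
    for sample, grp in particles_df.groupby("sample"):
        idx = np.digitize(grp["area_cm2"].to_numpy(float), edges[1:])
        counts = np.bincount(idx, minlength=len(edges))
        freqs = counts / counts.sum() if counts.sum() else np.zeros(len(edges))
        table = pd.DataFrame({"class": labels, "lower_cm2": list(edges),
                              "count": counts, "frequency_pct": freqs * 100})
        table.to_csv(output_dir / f"histogram_{sample}.csv", index=False, float_format="%.12g")
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.bar(range(len(labels)), freqs * 100, color="0.4")
        ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right", fontsize=7)
        ax.set_xlabel("fat particle area class (cm$^2$)")
        ax.set_ylabel("frequency (%)")
        ax.set_title(f"sample {sample}")
        fig.tight_layout()
        fig.savefig(output_dir / f"histogram_{sample}.png", dpi=120)
        plt.close(fig)


def _feature_table(summary: pd.DataFrame, chemical_csv: str | Path | None) -> pd.DataFrame:
    feats = summary.set_index("sample")[[f"{s}_mean" for s in STATISTIC_NAMES]]
    feats.columns = list(STATISTIC_NAMES)
    if chemical_csv is not None:
        chem = _read_chemical(chemical_csv)
        feats = feats.join(chem.rename("chemical_fat_pct"))
        missing = feats.index[feats["chemical_fat_pct"].isna()]
        if len(missing):
            logger.warning("samples without chemical fat dropped from PCA: %s", list(missing))
            feats = feats.dropna()
    return feats


def _run_pca(summary: pd.DataFrame, chemical_csv: str | Path | None, output_dir: Path) -> None:
    feats = _feature_table(summary, chemical_csv)
    try:
        res = pca_correlation(feats)
    except ValueError as exc:
        logger.warning("PCA skipped: %s", exc)
        return
    pd.DataFrame(res.loadings, index=res.variable_names,
                 columns=[f"PC{i+1}" for i in range(res.loadings.shape[1])]
                 ).to_csv(output_dir / "pca_loadings.csv", float_format="%.12g")
    pd.DataFrame(res.scores, index=feats.index,
                 columns=[f"PC{i+1}" for i in range(res.scores.shape[1])]
                 ).to_csv(output_dir / "pca_scores.csv", float_format="%.12g")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, len(res.eigenvalues) + 1), res.explained_variance_pct, "o-")
    ax.set_xlabel("component")
    ax.set_ylabel("explained variance (%)")
    fig.tight_layout()
    fig.savefig(output_dir / "pca_scree.png", dpi=120)
    plt.close(fig)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    sc = res.scores
    ax.scatter(sc[:, 0], sc[:, 1], color="k", s=18)
    for sid, (x, y) in zip(feats.index, sc[:, :2]):
        ax.annotate(str(sid), (x, y), fontsize=8, xytext=(3, 3), textcoords="offset points")
    scale = 0.9 * max(np.abs(sc[:, :2]).max(), 1e-9)
    for name, (lx, ly) in zip(res.variable_names, res.loadings[:, :2]):
        ax.arrow(0, 0, lx * scale, ly * scale, color="tab:red", head_width=0.05 * scale)
        ax.annotate(name, (lx * scale, ly * scale), color="tab:red", fontsize=7)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(f"PC1 ({res.explained_variance_pct[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({res.explained_variance_pct[1]:.0f}%)")
    fig.tight_layout()
    fig.savefig(output_dir / "pca_biplot.png", dpi=120)
    plt.close(fig)


def _run_correlation(summary: pd.DataFrame, chemical_csv: str | Path, output_dir: Path) -> None:
    chem = _read_chemical(chemical_csv)
    vfc = summary.set_index("sample")["vfc_pct_mean"]
    paired = pd.DataFrame({"vfc": vfc}).join(chem.rename("chemical")).dropna()
    try:
        res = correlate_vfc_chemical(paired["vfc"], paired["chemical"])
    except ValueError as exc:
        logger.warning("correlation skipped: %s", exc)
        return
    pd.DataFrame([{
        "slope": res.slope, "intercept": res.intercept, "r2": res.r2, "n": res.n_points,
    }]).to_csv(output_dir / "correlation.csv", index=False, float_format="%.12g")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(paired["vfc"], paired["chemical"], color="k", s=20)
    xs = np.linspace(paired["vfc"].min(), paired["vfc"].max(), 50)
    ax.plot(xs, res.slope * xs + res.intercept, "-",
            label=f"$R^2$ = {res.r2:.2f}")
    ax.set_xlabel("visible fat content (%)")
    ax.set_ylabel("chemical fat content (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(output_dir / "correlation.png", dpi=120)
    plt.close(fig)
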