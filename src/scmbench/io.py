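"""Ensemble I/O, report assembly and evaluation drivers.

Images are 8-bit grayscale PNG; manifests are CSV files alongside the
images; evaluation reports are JSON with full provenance (config echo,
seeds, package version).  Every randomized step draws from a seed recorded
in the manifest or report, so a run is reproducible from its artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__, alphabet, ensemble, flags, phantom, voronoi

MANIFEST_NAME = "manifest.csv"


def write_ensemble(images: list[np.ndarray], manifest: pd.DataFrame, out_dir) -> list[Path]:
    """Write images as PNG plus the manifest CSV; returns written paths.

    A ``filename`` column is added to the manifest when absent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    if "filename" not in manifest.columns:
        manifest.insert(0, "filename", [f"img_{i:05d}.png" for i in range(len(images))])
    if len(manifest) != len(images):
        raise ValueError("manifest length does not match image count")
    if manifest["filename"].duplicated().any():
        raise ValueError("duplicate filenames in manifest")
    paths = []
    for img, name in zip(images, manifest["filename"]):
        img = np.asarray(img)
        if img.dtype != np.uint8 or img.ndim != 2:
            raise ValueError("images must be 2-D uint8 arrays")
        p = out_dir / name
        Image.fromarray(img, mode="L").save(p)
        paths.append(p)
    manifest.to_csv(out_dir / MANIFEST_NAME, index=False)
    return paths


def read_ensemble(in_dir) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Read a PNG ensemble and its manifest (inferred from the directory
    listing, with a warning, when the manifest file is missing)."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / MANIFEST_NAME
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
    else:
        import warnings

        names = sorted(p.name for p in in_dir.glob("*.png"))
        warnings.warn(f"no {MANIFEST_NAME} in {in_dir}; inferring from directory listing")
        manifest = pd.DataFrame({"filename": names})
    images = []
    for name in manifest["filename"]:
        p = in_dir / name
        if not p.exists():
            raise FileNotFoundError(f"manifest lists missing file {p}")
        images.append(np.asarray(Image.open(p).convert("L")))
    return images, manifest


# ---------------------------------------------------------------------------
# Evaluation drivers
# ---------------------------------------------------------------------------


def evaluate_alphabet(images: list[np.ndarray], threshold: float = 0.9) -> dict:
    """Per-image letter recovery, prevalence and pair statistics."""
    glyphs = alphabet.build_glyph_set()
    records = []
    for i, img in enumerate(images):
        layout, scores, recognizable = alphabet.recover_layout(img, glyphs, threshold)
        counts = layout.counts()
        chi2, gof_pass = alphabet.letter_prevalence_gof(counts)
        pairs, orphans = alphabet.pair_prevalence(layout.grid)
        records.append(
            {
                "index": i,
                "recognizable": recognizable,
                "min_score": float(scores.min()),
                "chi2": chi2,
                "chi2_pass": gof_pass,
                "perfect_prevalence": counts == alphabet.LETTER_MULTISET,
                "pair_counts_ok": pairs == alphabet.PAIR_COUNTS,
                "n_orphans": len(orphans),
            }
        )
    df = pd.DataFrame(records)
    summary = {
        "pct_recognizable": 100.0 * df["recognizable"].mean(),
        "pct_chi2_pass": 100.0 * df["chi2_pass"].mean(),
        "pct_perfect_prevalence": 100.0 * df["perfect_prevalence"].mean(),
        "pct_pairs_correct": 100.0 * ((df["pair_counts_ok"]) & (df["n_orphans"] == 0)).mean(),
    }
    return {"per_image": records, "summary": summary}


def evaluate_voronoi(images: list[np.ndarray], rho_flag: float = 0.9) -> dict:
    """Per-image region recovery, rank correlation and class status."""
    records = []
    for i, img in enumerate(images):
        _, regions = voronoi.recover_regions(img)
        n = len(regions)
        rho = voronoi.area_gray_spearman(regions) if n >= 2 else float("nan")
        nearest, status = voronoi.classify_by_region_count(n) if n >= 1 else (0, "empty")
        records.append(
            {"index": i, "n_regions": n, "rho": rho, "nearest_class": nearest, "status": status}
        )
    df = pd.DataFrame(records)
    counts = df["n_regions"].to_numpy()
    summary = {
        "pct_rho_below_flag": 100.0 * (df["rho"] < rho_flag).mean(),
        "pct_in_class": 100.0 * (df["status"] == "in-class").mean(),
        "region_count_histogram": {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))},
    }
    return {"per_image": records, "summary": summary}


def evaluate_flags(
    images: list[np.ndarray],
    templates: flags.ClassTemplateSet | None = None,
    null_percentiles: tuple[float, float] | None = None,
    max_morans_outliers: int = 8,
) -> dict:
    """Per-image pattern, class, texture and intensity acceptability.

    Layout mirrors an acceptability table: percent of realizations passing
    each constraint.  An image passes the texture check when at most
    ``max_morans_outliers`` of its 256 tile Moran's I values fall outside
    the simulation null band.
    """
    if templates is None:
        templates = flags.build_class_templates()
    if null_percentiles is None:
        null_percentiles = flags.build_intensity_null(n_images=100, seed=0, templates=templates)
    band = flags.morans_null_band(n_tiles=2000, seed=0)
    records = []
    for i, img in enumerate(images):
        pattern = flags.recover_foreground_pattern(img)
        cls, rmae, forbidden, error_tiles = flags.classify_by_rmae(pattern, templates)
        morans = flags.image_morans(img)
        outliers = int(((morans < band[0]) | (morans > band[1])).sum())
        chi2_fg, chi2_bg, intensity_ok = flags.intensity_gof(img, pattern, null_percentiles)
        records.append(
            {
                "index": i,
                "class": cls,
                "rmae_best": float(rmae.min()),
                "pattern_exact": error_tiles.size == 0,
                "n_error_tiles": int(error_tiles.size),
                "forbidden_violation": forbidden,
                "morans_outlier_tiles": outliers,
                "texture_ok": outliers <= max_morans_outliers,
                "chi2_fg": chi2_fg,
                "chi2_bg": chi2_bg,
                "intensity_ok": intensity_ok,
            }
        )
    df = pd.DataFrame(records)
    summary = {
        "pct_pattern_exact": 100.0 * df["pattern_exact"].mean(),
        "pct_forbidden_free": 100.0 * (~df["forbidden_violation"]).mean(),
        "pct_texture_ok": 100.0 * df["texture_ok"].mean(),
        "pct_intensity_ok": 100.0 * df["intensity_ok"].mean(),
    }
    return {"per_image": records, "summary": summary}


def evaluate_ensemble(
    train_images: list[np.ndarray],
    gen_images: list[np.ndarray],
    n_pairs: int = 10_000,
    k: int = 5,
    seed: int = 0,
    train_labels=None,
    gen_labels=None,
) -> dict:
    """Full distributional comparison of two phantom-like ensembles."""
    train_table = ensemble.extract_feature_families(
        train_images, [ensemble.phantom_masks(i) for i in train_images]
    )
    gen_table = ensemble.extract_feature_families(
        gen_images, [ensemble.phantom_masks(i) for i in gen_images]
    )
    out = ensemble.similarity_summary(train_table, gen_table, n_pairs=n_pairs, seed=seed)
    emb_t2, emb_g2 = ensemble.pca_embed(train_table.complete(), gen_table.complete(), n_components=2)
    coverage, density = ensemble.coverage_density(emb_t2, emb_g2, k=k)
    out.update({"coverage": coverage, "density": density, "k": k, "n_pairs": n_pairs, "seed": seed})
    if gen_labels is not None:
        out["prevalence"] = ensemble.class_prevalence_summary(gen_labels)
    if train_labels is not None:
        out["train_prevalence"] = ensemble.class_prevalence_summary(train_labels)
    return out


_EVALUATORS = {
    "alphabet": evaluate_alphabet,
    "voronoi": evaluate_voronoi,
    "flags": evaluate_flags,
}


def run_report(config: dict, out_path=None) -> dict:
    """Assemble a JSON evaluation report from a config.

    Config keys: ``model`` (alphabet | voronoi | flags | ensemble),
    ``dir`` (image directory; for ``ensemble``: ``train_dir`` and
    ``gen_dir``), plus model-specific options.  Deterministic given the
    config.
    """
    model = config.get("model")
    if model in _EVALUATORS:
        images, manifest = read_ensemble(config["dir"])
        result = _EVALUATORS[model](images)
    elif model == "ensemble":
        train_images, train_man = read_ensemble(config["train_dir"])
        gen_images, gen_man = read_ensemble(config["gen_dir"])
        result = evaluate_ensemble(
            train_images,
            gen_images,
            n_pairs=int(config.get("n_pairs", 10_000)),
            k=int(config.get("k", 5)),
            seed=int(config.get("seed", 0)),
            train_labels=train_man.get("class"),
            gen_labels=gen_man.get("class"),
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    report = {"config": config, "version": __version__, "result": result}
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
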