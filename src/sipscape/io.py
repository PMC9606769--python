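"""Readers, writers, configuration and the end-to-end pipeline.

Artifacts are diff-able text: CSV (UTF-8, '.' decimal, comma separator) for
tables, JSON for structured results, PNG/TIFF for images (lossless only —
JPEG is refused).  Every artifact of a pipeline run carries the hash of the
configuration that produced it, so artifacts from different configurations
cannot be mixed silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger("sipscape")

LOSSLESS_SUFFIXES = {".png", ".tif", ".tiff"}

__all__ = [
    "PipelineConfig",
    "read_images",
    "write_image",
    "write_image_set",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated knobs of the umbrella pipeline.

    Defaults are the study conventions: SIPs at 800×800, collinearity
    pruning at ρ > 0.6, 10 best models per size, β* bands at 0.2/0.5.
    ``image_size``/``n_*`` control the synthetic study fed into the run.
    """

    sip_resolution: int = 800
    rho_threshold: float = 0.6
    n_best: int = 10
    n_robust: int = 12
    seed: int = 0
    image_size: int = 256
    n_participants: int = 40
    images_per_slope: int = 25
    n_pseudo_paintings: int = 150
    k_range_max: int = 8
    distance_variables: tuple[str, ...] | None = None
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if not 64 <= self.sip_resolution <= 4096:
            raise ValueError("sip_resolution outside [64, 4096]")
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold outside (0, 1]")
        if self.n_best < 1 or self.n_robust < 1:
            raise ValueError("n_best and n_robust must be >= 1")
        if self.k_range_max < 2:
            raise ValueError("k_range_max must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "distance_variables" in raw and raw["distance_variables"] is not None:
            raw["distance_variables"] = tuple(raw["distance_variables"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_images(path: str | Path) -> dict[str, np.ndarray]:
    """Read a directory (or manifest CSV) of lossless rasters.

    Returns image_id → H×W×3 float array in [0, 1]; ids are filename stems
    in deterministic lexicographic order.  A manifest CSV must have a
    ``filename`` column (resolved relative to the manifest) and may carry
    a ``set_slope`` column, returned via the array's companion attribute
    ``read_images.last_manifest``.
    """
    path = Path(path)
    manifest = None
    if path.is_file() and path.suffix.lower() == ".csv":
        manifest = pd.read_csv(path)
        if "filename" not in manifest.columns:
            raise ValueError(f"manifest {path} lacks a 'filename' column")
        files = [path.parent / f for f in manifest["filename"]]
    elif path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in LOSSLESS_SUFFIXES | {".jpg", ".jpeg"}
        )
    else:
        raise FileNotFoundError(f"no such directory or manifest: {path}")
    out: dict[str, np.ndarray] = {}
    for f in sorted(files, key=lambda p: p.stem):
        if f.suffix.lower() not in LOSSLESS_SUFFIXES:
            warnings.warn(f"skipping lossy/unsupported format: {f.name}")
            continue
        try:
            with Image.open(f) as im:
                arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
        except Exception as exc:  # noqa: BLE001 - name the file for the user
            raise IOError(f"cannot decode image file {f}") from exc
        if f.stem in out:
            raise ValueError(f"duplicate image id {f.stem!r}")
        out[f.stem] = arr
    read_images.last_manifest = manifest  # type: ignore[attr-defined]
    return out


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB [0,1] array as 8-bit PNG/TIFF; refuses lossy formats."""
    path = Path(path)
    if path.suffix.lower() not in LOSSLESS_SUFFIXES:
        raise ValueError(
            f"refusing lossy/unknown format {path.suffix!r}; use one of "
            f"{sorted(LOSSLESS_SUFFIXES)}"
        )
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def write_image_set(
    images: dict[str, np.ndarray],
    out_dir: str | Path,
    set_slopes: pd.Series | None = None,
) -> Path:
    """Write images plus a manifest CSV (filename, set_slope); returns it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for image_id in sorted(images):
        fname = f"{image_id}.png"
        write_image(images[image_id], out_dir / fname)
        rows.append(
            {
                "filename": fname,
                "set_slope": (
                    float(set_slopes[image_id])
                    if set_slopes is not None and image_id in set_slopes
                    else np.nan
                ),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _dump_json(obj, path: Path, config_hash: str) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    payload = {"config_hash": config_hash, **obj}
    path.write_text(json.dumps(payload, indent=1, default=default, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis chain on a seeded synthetic study.

    Stages: simulate images → SIP table → subset selection → standardized
    regressions → distances to a reference split → participant clustering.
    Stage artifacts (sips.csv, selection.json, results.json, dist.json,
    clusters.json) land in ``config.out_dir`` together with a provenance
    log; a failure aborts with the stage name while earlier artifacts are
    preserved.  Deterministic for a fixed config.
    """
    from . import clustering, distance, ratings, selection, sips, synth

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stage = "simulate"
    bundle: dict = {}
    try:
        logger.info("stage %s: generating synthetic study", stage)
        scfg = synth.SyntheticStudyConfig(
            n_participants=config.n_participants,
            images_per_slope=config.images_per_slope,
            rated_per_slope=max(1, config.images_per_slope // 5),
            n_pseudo_paintings=config.n_pseudo_paintings,
            image_size=config.image_size,
            seed=config.seed,
        )
        sets = synth.generate_image_sets(scfg)
        design = synth.generate_design(scfg)

        stage = "sips"
        logger.info("stage %s: computing SIP table", stage)
        sip_cfg = sips.SIPConfig(resolution=min(config.sip_resolution, config.image_size))
        all_images = {**sets["random_phase"], **sets["pseudo_paintings"]}
        categories = {i: "random_phase" for i in sets["random_phase"]}
        categories.update({i: "style_transferred" for i in sets["pseudo_paintings"]})
        sip_table = sips.compute_sip_table(all_images, sip_cfg, categories)
        sip_table.to_csv(out / "sips.csv")

        ratings_df, truth = synth.generate_ratings(sip_table, design, scfg)
        ratings_df.to_csv(out / "ratings.csv", index=False)

        stage = "selection"
        logger.info("stage %s: subset selection", stage)
        st = sip_table[sip_table["category"] == "style_transferred"]
        X = st[list(sips.EIGHT_MODEL_SIPS)]
        agg = ratings.aggregate_ratings(
            ratings_df[ratings_df["category"] == "style_transferred"]
        )
        merged = None
        for dim in ratings.RATING_DIMENSIONS:
            y = (
                agg[agg["dimension"] == dim]
                .set_index("image_id")
                .loc[st.index, "rating"]
            )
            res = selection.best_subset_search(X, y, n_best=config.n_best)
            merged = res if merged is None else merged.merge(res)
        robust = selection.select_robust_variables(merged, config.n_robust)
        pruned, audit = selection.prune_collinear(
            st, robust, threshold=config.rho_threshold, robustness=merged.robustness
        )
        _dump_json(
            {
                "robust": robust,
                "pruned": pruned,
                "audit": audit,
                "robustness": merged.robustness,
                "models": {
                    s: [dataclasses.asdict(m) for m in mods]
                    for s, mods in merged.models.items()
                },
            },
            out / "selection.json",
            chash,
        )

        stage = "regression"
        logger.info("stage %s: standardized regressions", stage)
        reg_results = {}
        for dim in ratings.RATING_DIMENSIONS:
            y = (
                agg[agg["dimension"] == dim]
                .set_index("image_id")
                .loc[st.index, "rating"]
            )
            reg_results[dim] = ratings.standardized_regression(X, y)
        _dump_json(
            {
                dim: {
                    "beta_star": dict(zip(r.predictors, r.beta_star)),
                    "p": dict(zip(r.predictors, r.p_values)),
                    "r2_adj": r.r2_adj,
                }
                for dim, r in reg_results.items()
            },
            out / "results.json",
            chash,
        )

        stage = "distance"
        logger.info("stage %s: Mahalanobis distances", stage)
        # reference = random-phase set; test = pseudo-paintings
        ref = sip_table[sip_table["category"] == "random_phase"]
        vars_ = (
            list(config.distance_variables)
            if config.distance_variables
            else distance.select_differing_variables(
                st, ref, list(sips.EIGHT_MODEL_SIPS)
            )[:5]
        )
        refdist = distance.build_reference(ref, vars_)
        dtab = distance.distance_table(st, refdist)
        corr = distance.distance_rating_correlation(dtab, agg)
        _dump_json(
            {
                "variables": vars_,
                "d2": dtab["mahalanobis_sq"].to_dict(),
                "correlations": {
                    str(k): corr[k].to_dict() for k in corr.columns
                },
            },
            out / "dist.json",
            chash,
        )

        stage = "clustering"
        logger.info("stage %s: participant clustering", stage)
        feats = clustering.participant_feature_vectors(ratings_df, "inter_rating")
        cres = clustering.kmeans_with_diagnostics(
            feats, range(1, config.k_range_max + 1), seed=config.seed
        )
        _dump_json(
            {
                "assignments": cres.assignments.to_dict(),
                "chosen_k": cres.chosen_k,
                "elbow_k": cres.elbow_k,
                "wss": cres.wss,
                "silhouette": cres.silhouette,
                "gap": cres.gap,
            },
            out / "clusters.json",
            chash,
        )

        bundle = {
            "config_hash": chash,
            "artifacts": [
                "sips.csv",
                "ratings.csv",
                "selection.json",
                "results.json",
                "dist.json",
                "clusters.json",
            ],
            "truth_beta_star": truth.beta_star.to_dict(),
        }
        _dump_json(bundle, out / "provenance.json", chash)
        logger.info("pipeline complete: %s", out)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def check_artifact_hash(path: str | Path, config: PipelineConfig) -> None:
    """Refuse to mix artifacts produced under a different configuration."""
    payload = json.loads(Path(path).read_text())
    if payload.get("config_hash") != config.config_hash():
        raise ValueError(
            f"artifact {path} was produced under config hash "
            f"{payload.get('config_hash')}, current is {config.config_hash()}"
        )
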