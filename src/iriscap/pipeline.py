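"""End-to-end orchestration: cohort -> PSDs -> imposter fit -> capacity tables.

A run starts either from a synthetic cohort (each class a random stable
AR(p) Gaussian process with N realizations — a stand-in with the same
statistical structure as preprocessed iris vectors) or from a directory of
normalized iris images (one subdirectory per class), and produces:

    per-class enrollment spectra, cross-class imposter scores, the Erlang
    (K, P) fit, and sphere-packing / enrollment capacity tables,

all written as CSV/JSON artifacts stamped with the seed and a config hash
so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ar import ARModel, PowerSpectrum, aic_sweep, ar_psd, burg_fit, random_stable_ar, select_order, simulate_ar
from .capacity import enrollment_table, sphere_packing_table
from .detection import relative_entropy
from .imposter import ImposterFit, ImposterHistogram, enrollment_spectrum, fit_erlang_lsq, imposter_scores
from .preprocess import GaborParams, load_normalized_image, preprocess_image

__all__ = ["CohortSpec", "RunConfig", "PipelineResult", "generate_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

_TABLE1_NOISE_GRID = (1, 10, 50, 100, 200, 300, 400, 500)
_TABLE2_TAU_GRID = (1, 10, 50, 100, 200, 400, 600, 800, 1000)
_TABLE2_DELTA_GRID = (0.5, 0.1, 0.01, 0.001)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic study cohort: M classes x N realizations of length n.

    Defaults mirror a small high-quality iris study: 21 classes with 10
    images each (the reduced interval-camera cohort size), vectors of 4800
    samples, and moderate AR order 4 so per-class spectra stay smooth and
    low-order while remaining mutually distinct.
    """

    n_classes: int = 21
    images_per_class: int = 10
    vector_length: int = 4800
    ar_order: int = 4
    max_pole_radius: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.images_per_class < 2:
            raise ValueError("need at least 2 classes and 2 images per class")
        if self.vector_length < 4 * self.ar_order:
            raise ValueError("vector_length must be >= 4 * ar_order")
        if not 0 < self.max_pole_radius < 1:
            raise ValueError("max_pole_radius must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, serializable to/from YAML."""

    mode: str = "synthetic"  # "synthetic" | "images"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    image_dir: str | None = None
    pupil_side: str = "top"
    gabor_f0: float = 1.0 / 9.0
    gabor_sigma: float = 0.5
    ar_order: int | None = None  # None -> AIC sweep over aic_orders
    aic_orders: tuple[int, ...] = tuple(range(1, 13))
    psd_grid: int | None = None  # None -> vector length
    enroll_fraction: float = 0.5
    metric: str = "relative_entropy"
    n_bins: int = 50
    K_candidates: tuple[int, ...] = tuple(range(1, 13))
    noise_grid: tuple[float, ...] = _TABLE1_NOISE_GRID
    tau_grid: tuple[float, ...] = _TABLE2_TAU_GRID
    delta_grid: tuple[float, ...] = _TABLE2_DELTA_GRID
    fmr_mode: str = "unit_grid"
    seed: int = 0
    output_dir: str = "iriscap_run"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            raw["cohort"] = CohortSpec(**raw["cohort"])
        for key in ("aic_orders", "K_candidates", "noise_grid", "tau_grid", "delta_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    models: dict[str, ARModel] | None
    enrollment_spectra: dict[str, PowerSpectrum]
    scores: list[float]
    fit: ImposterFit
    sphere_table: pd.DataFrame
    enroll_table: pd.DataFrame
    order_used: int
    output_dir: Path


def generate_cohort(spec: CohortSpec):
    """Draw the synthetic cohort: per-class AR models and realizations.

    Returns (models, realizations): ``models[label]`` is the class ARModel,
    ``realizations[label]`` an (N, n) array.  Child seeds are spawned from
    the spec seed, so the cohort is fully reproducible, and distinct child
    streams make the class spectra pairwise distinct (checked).
    """
    root = np.random.SeedSequence(spec.seed)
    model_seeds, data_seeds = root.spawn(2)
    model_rng = np.random.default_rng(model_seeds)
    data_rng = np.random.default_rng(data_seeds)
    models: dict[str, ARModel] = {}
    realizations: dict[str, np.ndarray] = {}
    for idx in range(spec.n_classes):
        label = f"class{idx:03d}"
        models[label] = random_stable_ar(spec.ar_order, model_rng, spec.max_pole_radius)
        realizations[label] = simulate_ar(
            models[label], spec.vector_length, spec.images_per_class, data_rng
        )
    grid = min(spec.vector_length, 1024)
    spectra = {lb: ar_psd(m, grid) for lb, m in models.items()}
    labels = list(models)
    for a, m in enumerate(labels):
        for k in labels[a + 1 :]:
            if relative_entropy(spectra[m], spectra[k]) <= 0:
                raise RuntimeError(f"degenerate cohort: classes {m} and {k} coincide")
    return models, realizations


def _vectors_from_images(config: RunConfig) -> dict[str, list[np.ndarray]]:
    image_dir = Path(config.image_dir)
    if not image_dir.is_dir():
        raise FileNotFoundError(f"image directory {image_dir} not found")
    params = GaborParams(f0=config.gabor_f0, sigma=config.gabor_sigma)
    per_class: dict[str, list[np.ndarray]] = {}
    for class_dir in sorted(p for p in image_dir.iterdir() if p.is_dir()):
        vecs = []
        for img_path in sorted(class_dir.iterdir()):
            if img_path.suffix.lower() not in (".png", ".tif", ".tiff", ".bmp"):
                continue
            image = load_normalized_image(img_path, pupil_side=config.pupil_side)
            vecs.append(preprocess_image(image, params).values)
        if vecs:
            per_class[class_dir.name] = vecs
    if len(per_class) < 2:
        raise ValueError("image mode needs >= 2 class subdirectories with images")
    return per_class


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full study and write all artifacts to the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    log_events: list[dict] = []

    models = None
    if config.mode == "synthetic":
        models, realizations = generate_cohort(config.cohort)
        per_class = {lb: list(arr) for lb, arr in realizations.items()}
    elif config.mode == "images":
        per_class = _vectors_from_images(config)
    else:
        raise ValueError("mode must be 'synthetic' or 'images'")

    first_vec = next(iter(per_class.values()))[0]
    if config.ar_order is not None:
        order = int(config.ar_order)
    else:
        curve = aic_sweep(first_vec, config.aic_orders)
        order = select_order(curve)
        log_events.append({"stage": "fit-ar", "event": "aic_selected_order", "order": order})

    n_grid = int(config.psd_grid or len(first_vec))
    if config.metric in ("whittle", "whittle_llr") and n_grid != len(first_vec):
        raise ValueError("the whittle metric requires psd_grid == vector length")
    enroll: dict[str, PowerSpectrum] = {}
    held_out_psds: dict[str, list[PowerSpectrum]] = {}
    for label, vecs in per_class.items():
        psds = [ar_psd(burg_fit(v, order), n_grid) for v in vecs]
        enroll[label], held_out_psds[label] = enrollment_spectrum(psds, config.enroll_fraction)

    # Whittle-metric imposter scoring reuses each class's held-out raw vectors
    n_enrolled = {lb: len(per_class[lb]) - len(held_out_psds[lb]) for lb in per_class}
    held_out_vecs = {lb: per_class[lb][n_enrolled[lb] :] for lb in per_class}
    scores = imposter_scores(
        enroll,
        metric=config.metric if config.metric != "whittle_llr" else "whittle",
        queries=held_out_vecs if config.metric in ("whittle", "whittle_llr") else None,
    )
    hist = ImposterHistogram.from_scores(scores, bins=config.n_bins, metric_name=config.metric)
    fit = fit_erlang_lsq(hist, K_candidates=config.K_candidates)
    log_events.append(
        {"stage": "fit-imposter", "event": "erlang_fit", "K": fit.K, "P": fit.P, "sse": fit.sse}
    )

    sphere = sphere_packing_table(fit, config.noise_grid)
    enroll_tab = enrollment_table(fit, config.tau_grid, config.delta_grid, config.fmr_mode)

    # ---- artifacts ------------------------------------------------------
    float_fmt = "%.17g"
    spectra_df = pd.DataFrame(
        {"frequency": np.arange(n_grid) / n_grid}
        | {lb: s.values for lb, s in enroll.items()}
    )
    spectra_df.to_csv(out / "enrollment_spectra.csv", index=False, float_format=float_fmt)
    pd.DataFrame({"score": scores}).to_csv(
        out / "imposter_scores.csv", index=False, float_format=float_fmt
    )
    (out / "imposter_fit.json").write_text(
        json.dumps(json.loads(fit.to_json()) | stamp, sort_keys=True) + "\n"
    )
    for name, df in (("capacity_sphere.csv", sphere), ("capacity_enroll.csv", enroll_tab)):
        df.to_csv(out / name, index=False, float_format=float_fmt)
    (out / "run_log.json").write_text(
        json.dumps(stamp | {"order_used": order, "events": log_events}, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: K=%d P=%.3g (%s scores)", fit.K, fit.P, len(scores))
    return PipelineResult(
        config=config,
        models=models,
        enrollment_spectra=enroll,
        scores=scores,
        fit=fit,
        sphere_table=sphere,
        enroll_table=enroll_tab,
        order_used=order,
        output_dir=out,
    )
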