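"""End-to-end experiment drivers.

Two protocols are packaged:

* **simulation** — an analytic phantom sinogram is under-sampled, refilled
  by each requested method, and scored twice: sinogram errors (max and sum
  of absolute differences) against the full analytic sinogram, and image
  RMSE against the full-view FBP reconstruction, which serves as the gold
  standard.
* **k-space pipeline** — the measurement-domain chain: per-spoke inverse
  Fourier transform, magnitude, displacement-based view upsampling, FBP.

Runs are deterministic given their configuration; the seed only feeds the
optional complex-noise generator.  Every run with an output directory
writes a JSON manifest of all parameters alongside the CSV metrics and
exported images.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .containers import RadialKSpace, ReconImage, Sinogram, ifft_radial, \
    magnitude, undersample_views
from .fbp import FbpConfig, fbp
from .interpolate import EstimatorConfig, linear_view_interp, \
    sinc_view_interp, upsample_sinogram
from .metrics import max_abs_error, rmse, sum_abs_error
from .phantom import kspace_from_sinogram, make_phantom, sinogram_from_phantom

__all__ = ["ExperimentConfig", "fill_views", "run_simulation_experiment",
           "run_kspace_pipeline", "METHODS"]

METHODS = ("displacement", "linear", "sinc", "none")


@dataclass
class ExperimentConfig:
    """Full description of one simulation experiment.

    ``n_views_full`` is the target view count (the gold standard);
    ``n_views_measured`` divides it, and their ratio is the interpolation
    factor.  ``normalize_rmse`` scales both images by the gold standard's
    maximum before the image RMSE, putting RMSE on a unit-intensity scale.
    """

    phantom_name: str = "rotating_features"
    n_views_full: int = 180
    n_views_measured: int = 60
    coverage_deg: float = 360.0
    n_radial: int = 256
    methods: tuple[str, ...] = ("displacement", "linear", "sinc")
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    fbp: FbpConfig = field(default_factory=FbpConfig)
    noise_sigma: float = 0.0
    seed: int = 0
    normalize_rmse: bool = True
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_views_full % self.n_views_measured:
            raise ValueError(
                f"n_views_full={self.n_views_full} must be divisible by "
                f"n_views_measured={self.n_views_measured}"
            )
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}; "
                             f"choose from {METHODS}")

    @property
    def factor(self) -> int:
        return self.n_views_full // self.n_views_measured

    def manifest(self) -> dict:
        d = asdict(self)
        d["factor"] = self.factor
        return d


def fill_views(s: Sinogram, factor: int, method: str,
               cfg: EstimatorConfig | None = None) -> Sinogram:
    """Dispatch a view-filling method by name ('none' returns the input)."""
    if method == "none" or factor == 1:
        return s
    if method == "displacement":
        return upsample_sinogram(s, factor, cfg)
    if method == "linear":
        return linear_view_interp(s, factor)
    if method == "sinc":
        return sinc_view_interp(s, factor)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def run_simulation_experiment(cfg: ExperimentConfig) -> dict:
    """Run the under-sample → refill → reconstruct → score protocol.

    Returns a report dict with one row per method holding the sinogram
    errors versus the full analytic sinogram (None when the method leaves
    the view count short of full) and the image RMSE versus the full-view
    FBP gold standard.
    """
    ph = make_phantom(cfg.phantom_name)
    full = sinogram_from_phantom(ph, cfg.n_views_full, cfg.coverage_deg,
                                 cfg.n_radial)
    if cfg.noise_sigma > 0:
        from .phantom import add_complex_noise
        rng = np.random.default_rng(cfg.seed)
        k = add_complex_noise(kspace_from_sinogram(full), cfg.noise_sigma, rng)
        full = magnitude(ifft_radial(k))
    measured = undersample_views(full, cfg.factor) if cfg.factor > 1 else full
    gold = fbp(full, cfg.fbp)
    gold_scale = np.abs(gold.pixels).max() if cfg.normalize_rmse else 1.0
    gold_scale = gold_scale or 1.0

    rows, images = [], {"gold": gold}
    for method in cfg.methods:
        filled = fill_views(measured, cfg.factor, method, cfg.estimator)
        if filled.n_views == full.n_views:
            max_err = max_abs_error(filled.values, full.values)
            sum_err = sum_abs_error(filled.values, full.values)
        else:
            max_err = sum_err = None
        img = fbp(filled, cfg.fbp)
        images[method] = img
        rows.append({
            "method": method,
            "max_abs_err": max_err,
            "sum_abs_err": sum_err,
            "rmse": rmse(img.pixels / gold_scale, gold.pixels / gold_scale),
        })

    report = {"config": cfg.manifest(), "metrics": rows}
    if cfg.output_dir is not None:
        _write_outputs(report, images, cfg)
    report["images"] = images
    return report


def _write_outputs(report: dict, images: dict[str, ReconImage],
                   cfg: ExperimentConfig) -> None:
    from .io import write_image_nifti, write_metrics_csv

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metrics_csv(report["metrics"], out / "metrics.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report["config"], fh, indent=1, default=str)
    for name, img in images.items():
        write_image_nifti(img, out / f"recon_{name}.nii.gz")


def run_kspace_pipeline(kspace: RadialKSpace, factor: int = 1,
                        estimator: EstimatorConfig | None = None,
                        fbp_cfg: FbpConfig | None = None,
                        reference: ReconImage | None = None,
                        normalize_rmse: bool = True) -> dict:
    """Measurement-domain chain: 1D inverse FT per spoke → magnitude →
    displacement view upsampling → FBP.

    Returns ``{"sinogram", "image", "rmse"}``; RMSE against the optional
    reference image is scale-normalized by the reference maximum.
    """
    sino = magnitude(ifft_radial(kspace))
    if factor > 1:
        sino = upsample_sinogram(sino, factor, estimator)
    img = fbp(sino, fbp_cfg)
    result = {"sinogram": sino, "image": img, "rmse": None}
    if reference is not None:
        scale = (np.abs(reference.pixels).max() or 1.0) \
            if normalize_rmse else 1.0
        result["rmse"] = rmse(img.pixels / scale, reference.pixels / scale)
    return result
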