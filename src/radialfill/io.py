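"""File I/O: HDF5 containers for k-space/sinograms, NIfTI/PNG image export,
CSV metrics tables.

The container is a single HDF5 file holding one dataset ``/samples``
(complex or real 2D) with attributes ``kind`` ("kspace" | "sinogram"),
``angles_deg``, ``coverage_deg`` and, for sinograms, ``delta_gamma_deg``.
Round-trips are lossless for both value parts and all metadata.
"""

from __future__ import annotations

import numpy as np

from .containers import RadialKSpace, ReconImage, Sinogram

__all__ = ["read_container", "write_container", "write_image_nifti",
           "write_image_png", "write_metrics_csv"]

_REQUIRED = {"kind", "angles_deg", "coverage_deg"}


def write_container(obj: RadialKSpace | Sinogram, path) -> None:
    """Write a k-space or sinogram object to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        if isinstance(obj, RadialKSpace):
            f.create_dataset("samples", data=obj.samples)
            f.attrs["kind"] = "kspace"
        elif isinstance(obj, Sinogram):
            f.create_dataset("samples", data=obj.values)
            f.attrs["kind"] = "sinogram"
            f.attrs["delta_gamma_deg"] = float(obj.delta_gamma_deg)
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__}")
        f.attrs["angles_deg"] = np.asarray(obj.angles_deg, dtype=float)
        f.attrs["coverage_deg"] = float(obj.coverage_deg)


def read_container(path) -> RadialKSpace | Sinogram:
    """Read an HDF5 container back into its domain object.

    Raises a validation error naming any missing metadata fields.
    """
    import h5py

    with h5py.File(path, "r") as f:
        missing = sorted(_REQUIRED - set(f.attrs))
        if "samples" not in f:
            missing.append("/samples dataset")
        if missing:
            raise ValueError(
                f"container {path} is missing required fields: "
                + ", ".join(missing)
            )
        kind = f.attrs["kind"]
        samples = f["samples"][()]
        angles = np.asarray(f.attrs["angles_deg"], dtype=float)
        coverage = float(f.attrs["coverage_deg"])
        if kind == "kspace":
            return RadialKSpace(samples=samples, angles_deg=angles,
                                coverage_deg=coverage)
        if kind == "sinogram":
            if "delta_gamma_deg" not in f.attrs:
                raise ValueError(
                    f"container {path} is missing required fields: "
                    "delta_gamma_deg"
                )
            return Sinogram(values=samples, angles_deg=angles,
                            coverage_deg=coverage,
                            delta_gamma_deg=float(f.attrs["delta_gamma_deg"]))
        raise ValueError(f"unknown container kind {kind!r}")


def write_image_nifti(img: ReconImage, path) -> None:
    """Export a reconstruction as NIfTI with isotropic pixel size."""
    import nibabel as nib

    affine = np.diag([img.pixel_size_mm, img.pixel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(img.pixels[..., None].astype(np.float32),
                             affine), str(path))


def write_image_png(img: ReconImage, path) -> None:
    """8-bit grayscale quicklook, min-max scaled."""
    import imageio.v3 as iio

    p = img.pixels
    span = p.max() - p.min()
    scaled = (p - p.min()) / span if span > 0 else np.zeros_like(p)
    iio.imwrite(str(path), (255 * scaled).astype(np.uint8))


def write_metrics_csv(rows: list[dict], path) -> None:
    """Metrics table (method, max_abs_err, sum_abs_err, rmse) as CSV."""
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)
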