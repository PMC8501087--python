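"""I/O, post-processing and run configuration.

File conventions:

* binary masks — 8-bit PNG with the 0/255 convention (any nonzero value is
  mapped to foreground 1, with a warning when intermediate values appear);
* grayscale/multimodal images — 32-bit float TIFF with channels first, or
  PNG for single-channel 8/16-bit data;
* medical volumes — NIfTI (processed slice-wise); any nonzero voxel is
  foreground, pixel spacing is taken from the header;
* dataset layout on disk — ``images/``, ``labels/``, ``flags.csv`` and an
  optional ``truth/`` directory of clean reference masks (synthetic
  scenarios only), plus ``meta.yaml``.

Coordinates are 0-based (row, col) with the origin at the top-left; the
connected-component convention is 4-connectivity unless configured
otherwise, shared with the metrics module's surface extraction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .metrics import _structure


def keep_largest_component(mask: np.ndarray, connectivity: int = 4
                           ) -> np.ndarray:
    """Retain only the largest connected foreground component.

    Empty input maps to empty output. Ties are broken in favour of the
    component containing the smallest (row, col) pixel in raster order
    (scipy labels components in raster order, so the smallest label wins).
    """
    mask = np.asarray(mask)
    fg = mask.astype(bool)
    if not fg.any():
        return np.zeros_like(mask, dtype=np.uint8)
    labeled, n = ndimage.label(fg, structure=_structure(fg.ndim, connectivity))
    if n == 1:
        return fg.astype(np.uint8)
    sizes = np.bincount(labeled.ravel())[1:]
    winner = int(np.argmax(sizes)) + 1
    return (labeled == winner).astype(np.uint8)


# --------------------------------------------------------------------------
# masks and images
# --------------------------------------------------------------------------

def write_mask(path, mask: np.ndarray, spacing=None) -> Path:
    """Write a binary mask; PNG uses 0/255, NIfTI stores spacing in the
    header."""
    path = Path(path)
    mask = np.asarray(mask).astype(np.uint8)
    if path.suffix in (".png", ".tif", ".tiff"):
        if mask.ndim != 2:
            raise ValueError(f"{path.suffix} masks must be 2D")
        iio.imwrite(path, (mask * 255).astype(np.uint8))
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib
        affine = np.eye(4)
        if spacing is not None:
            for i, s in enumerate(spacing):
                affine[i, i] = s
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
    else:
        raise ValueError(f"unsupported mask format: {path.suffix!r}")
    return path


def read_mask(path) -> tuple[np.ndarray, tuple[float, ...] | None]:
    """Read a binary mask; returns (grid, spacing-or-None). Nonzero values
    map to 1 (a warning is emitted for non-binary inputs)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    if path.suffix in (".png", ".tif", ".tiff"):
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:   # collapse RGB(A)
            arr = arr[..., 0]
        vals = np.unique(arr)
        if not np.isin(vals, (0, 255)).all() and not np.isin(vals, (0, 1)).all():
            warnings.warn(f"{path.name}: non-binary label values mapped to "
                          "foreground", stacklevel=2)
        return (arr > 0).astype(np.uint8), None
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib
        img = nib.load(str(path))
        grid = (np.asanyarray(img.dataobj) > 0).astype(np.uint8)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:grid.ndim])
        return grid, spacing
    raise ValueError(f"unsupported mask format: {path.suffix!r}")


def write_image(path, image: np.ndarray) -> Path:
    """Write a (channels, H, W) float image as multichannel float TIFF."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = image[None]
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    return path


def read_image(path) -> np.ndarray:
    """Read an image to (channels, H, W) float32 in [0, 1] where possible."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path), dtype=np.float32)
        return arr[None] if arr.ndim == 2 else arr
    if path.suffix == ".png":
        arr = np.asarray(iio.imread(path), dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[..., 0]
        return (arr / arr.max() if arr.max() > 1 else arr)[None]
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib
        arr = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float32)
        return arr[None] if arr.ndim == 2 else arr
    raise ValueError(f"unsupported image format: {path.suffix!r}")


# --------------------------------------------------------------------------
# dataset layout
# --------------------------------------------------------------------------

def write_dataset(out_dir, images: np.ndarray, labels: np.ndarray,
                  high_quality: np.ndarray, ids, clean_masks=None,
                  meta: dict | None = None) -> Path:
    """Write the on-disk layout consumed by ``aide train``:
    images/, labels/, flags.csv, optional truth/, meta.yaml."""
    import pandas as pd
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    if clean_masks is not None:
        (out / "truth").mkdir(exist_ok=True)
    for i, sid in enumerate(ids):
        write_image(out / "images" / f"{sid}.tif", images[i])
        write_mask(out / "labels" / f"{sid}.png", labels[i])
        if clean_masks is not None:
            write_mask(out / "truth" / f"{sid}.png", clean_masks[i])
    pd.DataFrame({"id": list(ids),
                  "quality": ["high" if q else "low" for q in high_quality]}
                 ).to_csv(out / "flags.csv", index=False)
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta or {}, fh)
    return out


def read_dataset(path):
    """Read a dataset layout back; returns (images, labels, high_quality,
    ids, clean_masks-or-None, meta)."""
    import pandas as pd
    path = Path(path)
    flags = pd.read_csv(path / "flags.csv", dtype={"id": str})
    ids = list(flags["id"])
    hq = np.array([q == "high" for q in flags["quality"]])
    images = np.stack([read_image(path / "images" / f"{sid}.tif")
                       for sid in ids])
    labels = np.stack([read_mask(path / "labels" / f"{sid}.png")[0]
                       for sid in ids])
    clean = None
    if (path / "truth").is_dir():
        clean = np.stack([read_mask(path / "truth" / f"{sid}.png")[0]
                          for sid in ids])
    meta = {}
    if (path / "meta.yaml").exists():
        with open(path / "meta.yaml") as fh:
            meta = yaml.safe_load(fh) or {}
    return images, labels, hq, ids, clean, meta


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured run configuration with data/model/loss/aide/optim
    sections; round-trips losslessly through YAML, unspecified fields keep
    their logged defaults."""

    data: dict = field(default_factory=dict)
    model: dict = field(default_factory=lambda: {"n_modalities": 1,
                                                 "base_channels": 32})
    loss: dict = field(default_factory=lambda: {"alpha": 1.0, "epsilon": 1.0,
                                                "k_views": 4,
                                                "temperature": 0.5})
    aide: dict = field(default_factory=lambda: {
        "filter_fraction": 0.5, "correction_fraction": 0.25,
        "warmup_epochs": 5, "correction_period": 10, "ramp_epochs": 10,
        "enable_correction": True, "postprocess_corrections": True})
    optim: dict = field(default_factory=lambda: {
        "epochs": 30, "batch_size": 8, "learning_rate": 1e-3,
        "optimizer": "adam", "seed": 0})
    output: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for section, values in (d or {}).items():
            if not hasattr(cfg, section):
                raise ValueError(f"unknown config section {section!r}")
            getattr(cfg, section).update(values or {})
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def build(self):
        """Materialize (ModelSpec, AideConfig) from the sections."""
        from .engine import AideConfig
        from .losses import LossParams
        from .nn import ModelSpec
        spec = ModelSpec(**self.model)
        lp = LossParams(alpha=self.loss.get("alpha", 1.0),
                        epsilon=self.loss.get("epsilon", 1.0),
                        prob_floor=self.loss.get("prob_floor", 1e-7))
        aide = AideConfig(loss_params=lp,
                          k_views=self.loss.get("k_views", 4),
                          temperature=self.loss.get("temperature", 0.5),
                          **self.aide, **self.optim)
        return spec, aide
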