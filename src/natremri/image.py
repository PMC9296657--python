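"""In-memory containers for magnitude MR volumes and ROI masks.

Conventions: voxel indices are 0-based and voxel-centred, axes are
right-handed, and physical coordinates (mm) of a voxel centre are
``index * spacing``. Masks are binary and inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: integer labels used when an ROISet is written as a single NIfTI label map
ROI_LABELS = {"tumour": 1, "non_tumour": 2, "phantom": 3}


@dataclass
class ImageVolume:
    """A magnitude MR image with its voxel spacing and modality tag.

    Parameters
    ----------
    data
        Non-negative voxel array (2-D or 3-D).
    spacing
        Voxel size in mm along each axis.
    modality
        One of ``{"na23", "h1", "dwi"}``.
    meta
        Free-form acquisition metadata (b-value, TR, seed, ...) carried
        through the pipeline but never interpreted by it.
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    modality: str = "na23"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.data.ndim}-D volume"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voxel values must be finite")
        if np.any(self.data < 0):
            raise ValueError("magnitude voxel values must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def coordinate_grid(self) -> np.ndarray:
        """Physical voxel-centre coordinates, shape ``(*shape, ndim)`` in mm."""
        axes = [np.arange(n) * s for n, s in zip(self.shape, self.spacing)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    # ---- NIfTI round trip -------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        """Write the volume as NIfTI with a JSON sidecar for the metadata."""
        path = Path(path)
        affine = np.diag(list(self.spacing) + [1.0] * (4 - self.data.ndim))
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, path)
        sidecar = {"modality": self.modality, "spacing": list(self.spacing)}
        sidecar.update(self.meta)
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, default=float)
        )

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str | None = None) -> "ImageVolume":
        path = Path(path)
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        meta: dict = {}
        sidecar = path.with_suffix("").with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            modality = modality or meta.pop("modality", None)
            meta.pop("spacing", None)
        return cls(data=data, spacing=spacing, modality=modality or "na23", meta=meta)


@dataclass
class ROISet:
    """Named binary masks (tumour / non_tumour / phantom) on one image grid."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid shape")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    def validate_against(self, image: ImageVolume) -> None:
        for name, mask in self.masks.items():
            if mask.shape != image.shape:
                raise ValueError(f"mask '{name}' shape {mask.shape} != image {image.shape}")
            if not mask.any():
                raise ValueError(f"mask '{name}' is empty")

    def to_label_nifti(self, path: str | Path, spacing: tuple[float, ...]) -> None:
        """Write all masks into one integer label map (tumour=1, non_tumour=2, phantom=3)."""
        shape = next(iter(self.masks.values())).shape
        labels = np.zeros(shape, dtype=np.int16)
        for name, mask in self.masks.items():
            labels[mask] = ROI_LABELS.get(name, max(ROI_LABELS.values()) + 1)
        affine = np.diag(list(spacing) + [1.0] * (4 - labels.ndim))
        nib.save(nib.Nifti1Image(labels, affine), Path(path))

    @classmethod
    def from_label_nifti(cls, path: str | Path) -> "ROISet":
        labels = np.asarray(nib.load(Path(path)).dataobj)
        masks = {
            name: labels == lab for name, lab in ROI_LABELS.items() if (labels == lab).any()
        }
        return cls(masks=masks)
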