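"""ADC map computation and brain-mask preprocessing.

Turns a paired (b=0, b=1000 s/mm^2) diffusion-weighted acquisition into a
standardized, brain-masked apparent diffusion coefficient (ADC) map:

1. voxelwise ADC from the monoexponential signal model S_b = S0 * exp(-b*ADC);
2. brain extraction on the b=0 volume (intensity threshold, largest
   26-connected component, hole filling);
3. triple morphological erosion of the brain mask with a 3x3x3 box kernel,
   trimming partial-volume voxels at the brain surface;
4. intensity standardization: canonical units (mm^2/s), exclusion of
   non-finite voxels and physical clipping to [0, adc_max].

Voxels where the signal pair is non-physical (S_b > S0, or a non-positive
signal) are noise-dominated; they are set to ADC = 0 and removed from the
mask so they cannot contaminate the histogram tails downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Physical ceiling for brain ADC values, mm^2/s (free water at body
#: temperature is ~3e-3; anything above 4e-3 is noise or CSF pulsation).
ADC_MAX_DEFAULT = 4.0e-3

#: 3x3x3 box structuring element used for erosion and connectivity.
BOX_KERNEL = np.ones((3, 3, 3), dtype=bool)


class GridMismatchError(ValueError):
    """Raised when two volumes do not share shape and affine."""


@dataclass(frozen=True)
class DwiPair:
    """One subject-timepoint: paired b=0 and diffusion-weighted volumes.

    Parameters
    ----------
    s0, sb : ndarray
        3-D signal volumes (arbitrary units) on the same grid.
    b : float
        Diffusion weighting of ``sb`` in s/mm^2; must be positive.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray or None
        4x4 voxel-to-world affine; identity if omitted.
    """

    s0: np.ndarray
    sb: np.ndarray
    b: float
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        if self.s0.shape != self.sb.shape:
            raise GridMismatchError(
                f"b=0 and b={self.b} volumes differ in shape: "
                f"{self.s0.shape} vs {self.sb.shape}"
            )
        if self.affine is not None and self.affine.shape != (4, 4):
            raise GridMismatchError("affine must be 4x4")
        if not self.b > 0:
            raise ValueError(f"b-value must be positive, got {self.b}")

    @property
    def shape(self) -> tuple:
        return self.s0.shape


@dataclass(frozen=True)
class BrainMask:
    """Binary brain mask with a provenance tag.

    Provenance is one of ``extracted`` (computed from the b=0 volume),
    ``supplied`` (user-provided), or either suffixed ``|eroded x k``.
    """

    data: np.ndarray
    provenance: str = "supplied"

    def __post_init__(self):
        if self.data.dtype != np.bool_:
            object.__setattr__(self, "data", self.data.astype(bool))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def issubset(self, other: "BrainMask") -> bool:
        return bool(np.all(~self.data | other.data))


@dataclass(frozen=True)
class AdcMap:
    """Voxelwise ADC volume in mm^2/s with its mask and processing record."""

    data: np.ndarray
    mask: BrainMask
    standardization: dict = field(default_factory=dict)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def in_mask_values(self) -> np.ndarray:
        """Return the 1-D sample of in-mask ADC values."""
        return self.data[self.mask.data]

    def with_mask(self, mask: BrainMask) -> "AdcMap":
        if mask.data.shape != self.data.shape:
            raise GridMismatchError("mask grid does not match ADC grid")
        return replace(self, mask=mask)


def compute_adc(pair: DwiPair) -> AdcMap:
    """Compute the voxelwise ADC map from a b=0 / b>0 signal pair.

    ADC = ln(S0/Sb)/b wherever both signals are positive and Sb <= S0.
    Non-physical voxels (Sb > S0, or a non-positive signal) get ADC = 0 and
    are excluded from the validity mask; their count is recorded.

    Returns an unstandardized :class:`AdcMap` whose mask is the validity
    mask (tagged ``computed-valid``) — brain extraction is a separate step.
    """
    s0 = np.asarray(pair.s0, dtype=float)
    sb = np.asarray(pair.sb, dtype=float)
    valid = (s0 > 0) & (sb > 0) & (sb <= s0)
    adc = np.zeros(s0.shape, dtype=float)
    np.divide(np.log(s0, where=valid, out=np.zeros_like(s0))
              - np.log(sb, where=valid, out=np.zeros_like(sb)),
              pair.b, out=adc, where=valid)
    adc[~valid] = 0.0
    n_nonphysical = int(np.sum((s0 > 0) & (sb > 0) & (sb > s0)))
    record = {
        "method": "raw",
        "b": pair.b,
        "n_nonphysical_excluded": n_nonphysical,
        "n_nonpositive_signal": int(np.sum((s0 <= 0) | (sb <= 0))),
    }
    return AdcMap(
        data=adc,
        mask=BrainMask(valid, provenance="computed-valid"),
        standardization=record,
        voxel_size=pair.voxel_size,
        affine=pair.affine,
    )


def extract_brain_mask(
    s0: np.ndarray,
    threshold_fraction: float = 0.5,
    min_component_voxels: int = 27,
) -> BrainMask:
    """Extract a brain mask from a b=0 volume.

    The mask is all voxels above ``threshold_fraction`` times the robust
    maximum (99.5th percentile) of the volume, restricted to the largest
    26-connected component, with interior holes filled.

    Raises
    ------
    ValueError
        If the thresholded mask is empty or the largest component is
        smaller than ``min_component_voxels``.
    """
    s0 = np.asarray(s0, dtype=float)
    if not np.all(np.isfinite(s0)):
        raise ValueError("b=0 volume contains non-finite values")
    robust_max = np.percentile(s0, 99.5)
    threshold = threshold_fraction * robust_max
    raw = s0 > threshold
    if not raw.any():
        raise ValueError(
            f"empty brain mask at threshold {threshold:.6g} "
            f"(= {threshold_fraction} x robust max {robust_max:.6g})"
        )
    labels, n_labels = ndimage.label(raw, structure=BOX_KERNEL)
    sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n_labels + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_component_voxels:
        raise ValueError(
            f"largest connected component has {int(sizes[largest - 1])} voxels, "
            f"below minimum {min_component_voxels}"
        )
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    return BrainMask(mask, provenance="extracted")


def erode_mask(mask: BrainMask, iterations: int = 1) -> BrainMask:
    """Erode a binary mask with the 3x3x3 box kernel, ``iterations`` times.

    Matches the default box-kernel behaviour of the standard FSL-style
    mask-erosion step; iterations=0 is the identity. Erosion is
    anti-extensive: the result is always a subset of the input.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask
    data = ndimage.binary_erosion(
        mask.data, structure=BOX_KERNEL, iterations=iterations, border_value=0
    )
    return BrainMask(data, provenance=f"{mask.provenance}|eroded x {iterations}")


def standardize_adc(
    adc: AdcMap,
    method: str = "physical",
    params: dict | None = None,
) -> AdcMap:
    """Standardize an ADC map's intensities.

    method="physical" (default): keep canonical units (mm^2/s), drop
    non-finite voxels from the mask, and clip in-mask values to
    [0, adc_max] (default 4e-3 mm^2/s). Idempotent.

    method="reference-scale": divide all in-mask values by a cohort
    reference value ``params["reference"]`` (dimensionless output).

    The standardization record (method, parameters, clip/exclusion counts)
    is stored on the returned map.
    """
    params = dict(params or {})
    data = adc.data.astype(float, copy=True)
    mask_data = adc.mask.data.copy()

    nonfinite = ~np.isfinite(data) & mask_data
    n_nonfinite = int(nonfinite.sum())
    mask_data &= ~nonfinite
    data[~np.isfinite(data)] = 0.0

    if method == "physical":
        adc_max = float(params.get("adc_max", ADC_MAX_DEFAULT))
        in_mask = data[mask_data]
        n_clip_low = int(np.sum(in_mask < 0))
        n_clip_high = int(np.sum(in_mask > adc_max))
        data[mask_data] = np.clip(in_mask, 0.0, adc_max)
        record = {
            "method": "physical",
            "adc_max": adc_max,
            "n_clipped_low": n_clip_low,
            "n_clipped_high": n_clip_high,
            "n_nonfinite_excluded": n_nonfinite,
        }
    elif method == "reference-scale":
        reference = float(params["reference"])
        if reference <= 0:
            raise ValueError("reference must be positive")
        data[mask_data] = data[mask_data] / reference
        record = {
            "method": "reference-scale",
            "reference": reference,
            "n_nonfinite_excluded": n_nonfinite,
        }
    else:
        raise ValueError(f"unknown standardization method: {method!r}")

    return AdcMap(
        data=data,
        mask=BrainMask(mask_data, provenance=adc.mask.provenance),
        standardization=record,
        voxel_size=adc.voxel_size,
        affine=adc.affine,
    )


def preprocess_pair(
    pair: DwiPair,
    erode_iterations: int = 3,
    threshold_fraction: float = 0.5,
    method: str = "physical",
    params: dict | None = None,
    brain_mask: BrainMask | None = None,
) -> AdcMap:
    """Full per-timepoint preprocessing: ADC, brain mask, erosion, standardize.

    A user-supplied ``brain_mask`` (provenance ``supplied``) bypasses
    extraction; it is still eroded and intersected with the validity mask.
    """
    raw = compute_adc(pair)
    head = brain_mask if brain_mask is not None else extract_brain_mask(
        pair.s0, threshold_fraction=threshold_fraction
    )
    eroded = erode_mask(head, iterations=erode_iterations)
    combined = BrainMask(eroded.data & raw.mask.data, provenance=eroded.provenance)
    return standardize_adc(raw.with_mask(combined), method=method, params=params)


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------

def _affine_or_default(affine, voxel_size):
    if affine is not None:
        return affine
    return np.diag(list(voxel_size) + [1.0])


def save_adc_map(adc: AdcMap, path: str | Path) -> None:
    """Write an ADC map, its mask and a JSON sidecar next to ``path``."""
    path = Path(path)
    affine = _affine_or_default(adc.affine, adc.voxel_size)
    nib.save(nib.Nifti1Image(adc.data.astype(np.float32), affine), path)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    nib.save(nib.Nifti1Image(adc.mask.data.astype(np.uint8), affine), mask_path)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "standardization": adc.standardization,
        "mask_provenance": adc.mask.provenance,
        "n_mask_voxels": adc.mask.n_voxels,
    }, indent=2))


def load_adc_map(path: str | Path) -> AdcMap:
    """Load an ADC map written by :func:`save_adc_map`."""
    path = Path(path)
    img = nib.load(path)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    mask_img = nib.load(mask_path)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    zooms = img.header.get_zooms()[:3]
    return AdcMap(
        data=np.asarray(img.dataobj, dtype=float),
        mask=BrainMask(np.asarray(mask_img.dataobj).astype(bool),
                       provenance=meta.get("mask_provenance", "supplied")),
        standardization=meta.get("standardization", {}),
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
    )


def save_dwi_pair(pair: DwiPair, s0_path: str | Path, sb_path: str | Path) -> None:
    affine = _affine_or_default(pair.affine, pair.voxel_size)
    nib.save(nib.Nifti1Image(pair.s0.astype(np.float32), affine), s0_path)
    nib.save(nib.Nifti1Image(pair.sb.astype(np.float32), affine), sb_path)


def load_dwi_pair(s0_path: str | Path, sb_path: str | Path, b: float) -> DwiPair:
    s0_img = nib.load(s0_path)
    sb_img = nib.load(sb_path)
    if s0_img.shape != sb_img.shape:
        raise GridMismatchError(
            f"{s0_path} and {sb_path} differ in shape: {s0_img.shape} vs {sb_img.shape}"
        )
    zooms = s0_img.header.get_zooms()[:3]
    return DwiPair(
        s0=np.asarray(s0_img.dataobj, dtype=float),
        sb=np.asarray(sb_img.dataobj, dtype=float),
        b=b,
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(s0_img.affine),
    )
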