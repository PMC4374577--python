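"""Image objects as domain + value table.

An image object couples a spatial *domain* (the support region, a boolean
raster with world-coordinate metadata) with an optional *value table*.
Keeping the two separate lets registration operate on domains alone
(meshing, geodesics) while values are resampled only at the end, and makes
foreground segmentation a by-product of mapping: anything outside the
domain simply has no value.

Coordinate convention: 0-based indices, voxel centers at
``world = origin + index * spacing``; world axes follow array axes
(axis 0 first).  All distances are in world units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Domain",
    "ImageObject",
    "DomainError",
    "read_image",
    "write_image",
    "threshold_segment",
    "bounding_box",
]

#: Rec. 601 luma weights used to collapse RGB input to a scalar raster.
_LUMA_601 = np.array([0.299, 0.587, 0.114])


class DomainError(ValueError):
    """Raised for empty, degenerate or inconsistent domains."""


@dataclasses.dataclass
class Domain:
    """Spatial support region of an image object.

    Parameters
    ----------
    mask :
        Boolean raster, 2D or 3D; True marks cells inside the domain.
    origin :
        World coordinate of the center of cell ``(0, ..., 0)``.
    spacing :
        Per-axis cell size in world units; strictly positive.
    """

    mask: np.ndarray
    origin: tuple = None
    spacing: tuple = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise DomainError(f"mask must be 2D or 3D, got rank {self.mask.ndim}")
        if self.origin is None:
            self.origin = (0.0,) * self.mask.ndim
        if self.spacing is None:
            self.spacing = (1.0,) * self.mask.ndim
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if len(self.origin) != self.mask.ndim or len(self.spacing) != self.mask.ndim:
            raise DomainError("origin/spacing rank must match mask rank")
        if any(s <= 0 for s in self.spacing):
            raise DomainError("spacing components must be strictly positive")

    @property
    def dim(self) -> int:
        return self.mask.ndim

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def world_of_index(self, idx) -> np.ndarray:
        """World coordinates of cell-center ``idx`` (array of index vectors ok)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_of_world(self, pts) -> np.ndarray:
        """Fractional index coordinates of world points."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_world(self, pts, dilate: int = 0) -> np.ndarray:
        """True where the nearest cell to each world point is in the mask.

        ``dilate`` tests against an n-cell face-dilated mask instead.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        mask = self.mask
        if dilate:
            mask = ndimage.binary_dilation(mask, iterations=dilate)
        idx = np.rint(self.index_of_world(pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            out[ok] = mask[tuple(idx[ok].T)]
        return out


@dataclasses.dataclass
class ImageObject:
    """A domain plus an optional value table.

    ``values`` is defined wherever the domain mask is true.  Scalar rasters
    match the mask shape exactly; multi-channel rasters carry one trailing
    channel axis.
    """

    domain: Domain
    values: np.ndarray = None

    def __post_init__(self):
        if self.values is not None:
            self.values = np.asarray(self.values)
            spatial = self.values.shape[: self.domain.dim]
            if spatial != self.domain.shape or self.values.ndim > self.domain.dim + 1:
                raise DomainError(
                    f"values shape {self.values.shape} incongruent with mask "
                    f"shape {self.domain.shape}"
                )

    @property
    def nchannels(self) -> int:
        if self.values is None or self.values.ndim == self.domain.dim:
            return 1
        return self.values.shape[-1]

    def value_at(self, idx, fill=None):
        """Value at an integer index; outside the domain return ``fill``
        or raise ``DomainError`` when no fill is given."""
        idx = tuple(int(i) for i in idx)
        if not self.domain.mask[idx]:
            if fill is None:
                raise DomainError(f"index {idx} outside the domain")
            return fill
        return self.values[idx]


# ----------------------------------------------------------------- I/O ----

def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, kind: str = "auto", rgb: str = "luminance") -> ImageObject:
    """Read PNG/TIFF (2D) or NIfTI-1 (3D) into an :class:`ImageObject`.

    The returned object has a full-raster (all-true) domain.  NIfTI spacing
    and origin come from the header; 2D formats default to unit spacing.
    RGB input collapses to Rec. 601 luminance unless ``rgb='keep'``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        if kind == "2d":
            raise DomainError("NIfTI input is 3D but kind='2d' was requested")
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise DomainError(f"unsupported NIfTI dimensionality {data.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        dom = Domain(np.ones(data.shape, bool), origin=origin, spacing=spacing)
        return ImageObject(dom, np.asarray(data, dtype=np.float64))
    # 2D raster formats
    if kind == "3d":
        raise DomainError("PNG/TIFF input is 2D but kind='3d' was requested")
    import imageio.v3 as iio

    data = iio.imread(path)
    if data.ndim == 3:
        if rgb == "luminance":
            data = data[..., :3].astype(np.float64) @ _LUMA_601
        elif rgb == "keep":
            data = data.astype(np.float64)
        else:
            raise ValueError(f"unknown rgb mode {rgb!r}")
    elif data.ndim != 2:
        raise DomainError(f"unsupported image dimensionality {data.ndim}")
    dom = Domain(np.ones(data.shape[:2], bool))
    return ImageObject(dom, np.asarray(data, dtype=np.float64))


def write_image(obj: ImageObject, path, fill=0) -> None:
    """Write an image object; locations outside the domain get ``fill``.

    Format is chosen by extension: ``.png``/``.tif(f)`` for 2D,
    ``.nii``/``.nii.gz`` for 3D.  An object without values writes its mask
    (0/255 for 2D rasters, 0/1 for NIfTI).
    """
    path = Path(path)
    dom = obj.domain
    if obj.values is None:
        if dom.dim == 2:
            data = np.where(dom.mask, 255, 0).astype(np.uint8)
        else:
            data = dom.mask.astype(np.uint8)
    else:
        mask = dom.mask
        if obj.values.ndim > dom.dim:
            mask = mask[..., None]
        data = np.where(mask, obj.values, fill)
    if _is_nifti(path):
        if dom.dim != 3:
            raise DomainError("NIfTI output requires a 3D object")
        import nibabel as nib

        affine = np.diag(list(dom.spacing) + [1.0])
        affine[:3, 3] = dom.origin
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
        return
    if dom.dim != 2:
        raise DomainError("PNG/TIFF output requires a 2D object")
    import imageio.v3 as iio

    if data.dtype.kind == "f":
        # 2D raster formats are integer; clip into 16-bit range
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
        if data.max(initial=0) < 256:
            data = data.astype(np.uint8)
    iio.imwrite(path, data)


# ---------------------------------------------------------- operations ----

def threshold_segment(obj: ImageObject, low, high, largest_component: bool = False) -> Domain:
    """Segment a foreground domain by grey-value thresholding.

    The mask is true where ``low <= value <= high`` (restricted to the
    input's domain).  With ``largest_component`` only the largest
    face-connected foreground component is kept.
    """
    if obj.values is None:
        raise DomainError("threshold_segment requires an object with values")
    vals = obj.values
    if vals.ndim > obj.domain.dim:
        raise DomainError("threshold_segment requires a scalar value table")
    mask = (vals >= low) & (vals <= high) & obj.domain.mask
    if not mask.any():
        raise DomainError("thresholding produced an empty domain")
    if largest_component:
        labels, n = ndimage.label(mask)  # default structure = face connectivity
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return Domain(mask, origin=obj.domain.origin, spacing=obj.domain.spacing)


def bounding_box(domain: Domain):
    """Tight axis-aligned bounding box over true cells, in world coordinates.

    Returns ``(lo, hi, r_max)`` where ``lo``/``hi`` are world coordinates of
    the extreme cell centers and ``r_max = max_i (hi_i - lo_i)`` — the
    maximum extent used to scale the RBF shape parameter ``c = delta*r_max``.
    """
    if domain.is_empty():
        raise DomainError("bounding_box of an empty domain")
    idx = np.argwhere(domain.mask)
    lo = domain.world_of_index(idx.min(axis=0))
    hi = domain.world_of_index(idx.max(axis=0))
    r_max = float(np.max(hi - lo))
    return lo, hi, r_max
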