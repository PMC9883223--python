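"""Volume loading and automatic soft-tissue binarization.

A :class:`Volume` is a 3D scalar grid with per-axis voxel spacing in mm.
Axis convention throughout the package: +x = subject-left, +y = subject-backward,
+z = up; voxel centers sit on the integer lattice of the array indices.

Soft tissue is segmented fully automatically: a global Otsu threshold splits
the intensity histogram into two classes, the tissue class is taken as
foreground, and only the largest 26-connected component is retained (which
removes disconnected specks such as headrest fragments or noise islands).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "load_volume",
    "otsu_threshold",
    "binarize_soft_tissue",
    "save_mask",
]

#: documented axis convention string; stored on every Volume
AXIS_CONVENTION = "+x=subject-left, +y=subject-backward, +z=up"


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    axis_convention: str = AXIS_CONVENTION
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("volume needs at least 2 samples per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.allclose(self.spacing, self.spacing[0]):
            self.metadata.setdefault("anisotropic", True)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """Boolean soft-tissue occupancy grid derived from a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    threshold_used: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        if not self.data.any():
            raise ValueError("mask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Readers


def _load_raw(path: Path) -> Volume:
    """Raw binary array with a JSON sidecar {shape, dtype, spacing[, order]}."""
    path = Path(path)
    if path.suffix == ".json":
        sidecar, raw = path, path.with_suffix(".raw")
    else:
        sidecar, raw = path.with_suffix(".json"), path
    try:
        header = json.loads(sidecar.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read raw-volume sidecar {sidecar}: {exc}") from exc
    if "raw" in header:
        raw = sidecar.parent / header["raw"]
    shape = tuple(int(s) for s in header["shape"])
    data = np.fromfile(raw, dtype=np.dtype(header["dtype"]))
    if data.size != int(np.prod(shape)):
        raise ValueError(f"raw file {raw} has {data.size} samples, header says {shape}")
    data = data.reshape(shape, order=header.get("order", "C"))
    return Volume(data, tuple(header.get("spacing", (0.3, 0.3, 0.3))))


def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return Volume(data, tuple(float(z) for z in zooms))


def _load_nrrd(path: Path) -> Volume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NRRD file {path}: {exc}") from exc
    # SimpleITK arrays come out (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(data, tuple(float(s) for s in img.GetSpacing()))


def _load_dicom_dir(path: Path) -> Volume:
    """Stack a DICOM series, ordering slices by position along the slice normal
    (not by filename)."""
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise ValueError(f"cannot read DICOM file {f}: {exc}") from exc
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")

    first = slices[0]
    orient = np.array(getattr(first, "ImageOrientationPatient",
                              [1, 0, 0, 0, 1, 0]), dtype=float)
    normal = np.cross(orient[:3], orient[3:])

    def slice_pos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
        return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))

    slices.sort(key=slice_pos)
    arrays = [ds.pixel_array.T for ds in slices]  # (rows, cols) -> (x=cols? keep (c,r))
    data = np.stack(arrays, axis=-1)

    row_sp, col_sp = (float(v) for v in getattr(first, "PixelSpacing", [0.3, 0.3]))
    if len(slices) > 1:
        zs = [slice_pos(ds) for ds in slices]
        slice_sp = float(np.median(np.diff(zs))) or row_sp
    else:
        slice_sp = float(getattr(first, "SliceThickness", row_sp))
    return Volume(data, (col_sp, row_sp, abs(slice_sp)))


_READERS = {
    "raw+json_header": _load_raw,
    "raw": _load_raw,
    "nifti": _load_nifti,
    "nrrd": _load_nrrd,
    "dicom_dir": _load_dicom_dir,
}


def infer_format(path: str | Path) -> str:
    path = Path(path)
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith((".raw", ".json")):
        return "raw+json_header"
    raise ValueError(f"cannot infer volume format from {path}")


def load_volume(path: str | Path, format: str | None = None) -> Volume:
    """Load a CBCT-like volume from disk.

    Parameters
    ----------
    path
        File (NIfTI/NRRD/raw+JSON sidecar) or directory (DICOM series).
    format
        One of ``dicom_dir``, ``nifti``, ``nrrd``, ``raw+json_header``;
        inferred from the path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or infer_format(path)
    if fmt not in _READERS:
        raise ValueError(f"unknown volume format {fmt!r}")
    return _READERS[fmt](path)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a BinaryMask to NIfTI or NRRD (chosen by extension)."""
    path = Path(path)
    data = mask.data.astype(np.uint8)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(mask.spacing) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
        img.SetSpacing(tuple(mask.spacing))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported mask output format: {path}")


# ---------------------------------------------------------------------------
# Otsu thresholding


def otsu_threshold(intensities, bins: int = 256) -> float:
    """Otsu's threshold: the cut maximizing between-class variance.

    ``intensities`` is either an array of scalar samples or a precomputed
    histogram ``(counts, bin_edges)``.  Candidate thresholds are the upper
    edges of the nonempty bins (a cut inside a run of empty bins produces
    the same partition of the data, so only the lowest such cut is
    considered); the exhaustive scan over all candidates is evaluated and
    ties are broken toward the lower threshold, making the result
    deterministic for a fixed binning.  Values ``<= t`` fall in the lower
    class.
    """
    if isinstance(intensities, tuple) and len(intensities) == 2:
        counts, edges = intensities
        counts = np.asarray(counts, dtype=float)
        edges = np.asarray(edges, dtype=float)
        if len(edges) != len(counts) + 1:
            raise ValueError("histogram must be (counts, bin_edges)")
    else:
        values = np.asarray(intensities, dtype=float).ravel()
        values = values[np.isfinite(values)]
        if values.size == 0 or values.min() == values.max():
            raise ValueError("degenerate histogram: need at least two distinct values")
        counts, edges = np.histogram(values, bins=bins)
        counts = counts.astype(float)

    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    if total <= 0 or np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: need at least two distinct values")

    # cumulative class-0 weight and mean for every cut after bin c
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    mu0 = np.divide(csum, w0, out=np.zeros_like(csum), where=w0 > 0)
    mu1 = np.divide(csum[-1] + counts[-1] * centers[-1] - csum, w1,
                    out=np.zeros_like(csum), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[counts[:-1] == 0] = -np.inf  # canonical cut: right after a nonempty bin
    best = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(edges[best + 1])


def binarize_soft_tissue(volume: Volume, invert: bool = False, bins: int = 256) -> BinaryMask:
    """Threshold a volume with Otsu's method and keep the largest tissue blob.

    By default the brighter class is tissue (``invert=False``: foreground is
    ``data > t``).  Set ``invert=True`` for acquisitions where tissue is the
    darker class.  Only the largest 26-connected foreground component
    survives, which is the face/head in any face-like scan.
    """
    t = otsu_threshold(volume.data, bins=bins)
    fg = (volume.data < t) if invert else (volume.data > t)
    if not fg.any():
        raise ValueError("no tissue found: empty foreground after thresholding")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = labels == int(np.argmax(sizes))
    return BinaryMask(fg, volume.spacing, threshold_used=t,
                      metadata={"n_components_before_selection": int(n),
                                "inverted": bool(invert)})
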