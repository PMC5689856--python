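"""Core domain types and shared I/O for the dose engine.

Coordinate convention (used everywhere in this package): right-handed,
millimetres, isocenter at the origin.  ``Grid3D.origin`` is the position of
the *center* of voxel ``(0, 0, 0)`` and indices are 0-based.  For gantry
angle 0 the source sits at ``(0, 0, +SAD)`` and the beam travels along
``-z``; the gantry rotates about the ``y`` axis (patient superior-inferior).

Relative electron density (ED) is dimensionless with water = 1.0.  It is
used both to attenuate the primary fluence and — as a surrogate for relative
mass density — wherever a mass weighting is needed.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Grid3D",
    "CTtoEDTable",
    "DensityVolume",
    "Material",
    "MaterialTable",
    "Spectrum",
    "Structure",
    "StructureSet",
    "ConfigurationError",
    "FormatError",
    "hu_to_density",
    "load_materials",
    "material_blend",
    "read_dose_grid",
    "write_dose_grid",
]


class ConfigurationError(ValueError):
    """Invalid beam-model / table configuration."""


class FormatError(ValueError):
    """Unreadable or unsupported file content."""


# ---------------------------------------------------------------------------
# Grid


@dataclass
class Grid3D:
    """Scalar field on a regular 3D grid.

    Parameters
    ----------
    spacing : (3,) float, mm
    origin : (3,) float, mm — center of voxel (0, 0, 0), isocenter frame.
    values : ndarray, shape (nx, ny, nz)
    unit : str, free-form label for the stored quantity.
    """

    spacing: np.ndarray
    origin: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array with dims >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center positions, shape (nx, ny, nz, 3)."""
        x, y, z = (self.axis_coords(i) for i in range(3))
        return np.stack(np.meshgrid(x, y, z, indexing="ij"), axis=-1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (voxel faces), (lo, hi) in mm."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.dims) - 0.5) * self.spacing
        return lo, hi

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds()
        p = np.atleast_2d(points)
        return np.all((p >= lo) & (p <= hi), axis=-1)

    def sample(self, points: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        """Trilinear (order=1) or nearest (order=0) sample at mm positions.

        Points outside the voxel-center lattice are clamped for order=1 only
        within half a voxel; beyond the outer bounds the fill value is used.
        """
        from scipy.ndimage import map_coordinates

        p = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (p - self.origin) / self.spacing
        inside = self.contains(p)
        out = np.full(p.shape[0], fill, dtype=float)
        if np.any(inside):
            coords = idx[inside].T
            out[inside] = map_coordinates(
                self.values, coords, order=order, mode="nearest"
            )
        if np.isscalar(points) or np.asarray(points).ndim == 1:
            return out[0]
        return out

    def copy(self, values: np.ndarray | None = None) -> "Grid3D":
        return Grid3D(
            self.spacing.copy(),
            self.origin.copy(),
            self.values.copy() if values is None else np.asarray(values, float),
            self.unit,
        )


#: Dose distributions are plain grids with values in Gy (absolute, calibrated).
DoseGrid = Grid3D


# ---------------------------------------------------------------------------
# CT number -> relative electron density


@dataclass
class CTtoEDTable:
    """User-commissioned CT-number (HU) to relative electron density table.

    Interpolation is piecewise linear; HU outside the table range clamp to
    the end values (standard commissioning practice).
    """

    entries: np.ndarray  # (n, 2): HU, ED

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[1] != 2 or len(self.entries) < 2:
            raise ConfigurationError("CT->ED table needs at least 2 (HU, ED) rows")
        hu = self.entries[:, 0]
        if np.any(np.diff(hu) <= 0):
            raise ConfigurationError("CT->ED table HU values must be strictly increasing")
        if np.any(self.entries[:, 1] < 0):
            raise ConfigurationError("CT->ED table ED values must be >= 0")

    def ed(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(hu, self.entries[:, 0], self.entries[:, 1])


DEFAULT_CT_TO_ED = None  # populated lazily below


@dataclass
class Structure:
    name: str
    mask: np.ndarray
    density_override: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.density_override is not None and self.density_override < 0:
            raise ConfigurationError("density override must be >= 0")


@dataclass
class StructureSet:
    structures: list[Structure] = field(default_factory=list)

    def __post_init__(self) -> None:
        dims = {s.mask.shape for s in self.structures}
        if len(dims) > 1:
            raise ConfigurationError("all structure masks must share grid dims")

    def get(self, name: str) -> Structure | None:
        for s in self.structures:
            if s.name == name:
                return s
        return None


@dataclass
class DensityVolume:
    """Voxelized relative electron density plus an inside-patient mask."""

    grid: Grid3D
    body_mask: np.ndarray

    def __post_init__(self) -> None:
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        if self.body_mask.shape != self.grid.values.shape:
            raise ValueError("body_mask dims must match the grid")
        if np.any(self.grid.values < 0):
            raise ValueError("electron density must be >= 0")

    @property
    def ed(self) -> np.ndarray:
        return self.grid.values


def hu_to_density(
    ct: Grid3D,
    table: CTtoEDTable,
    overrides: StructureSet | None = None,
) -> DensityVolume:
    """Convert a CT-number grid to relative electron density.

    Piecewise-linear interpolation of the commissioned table with end
    clamping; voxels inside an override structure take the override ED
    regardless of their CT number.  The body mask is taken from a structure
    named ``body`` or ``external`` when present, otherwise every voxel is
    considered inside.
    """
    ed = table.ed(ct.values)
    body = np.ones(ct.values.shape, dtype=bool)
    if overrides is not None:
        for s in overrides.structures:
            if s.mask.shape != ct.values.shape:
                raise ConfigurationError("override mask dims must match the CT grid")
            if s.density_override is not None:
                ed = np.where(s.mask, s.density_override, ed)
            if s.name.lower() in ("body", "external"):
                body = s.mask
    return DensityVolume(Grid3D(ct.spacing, ct.origin, ed, unit="rel. electron density"), body)


# ---------------------------------------------------------------------------
# Materials and spectra


@dataclass
class Spectrum:
    """16-bin energy-differential photon fluence weights."""

    bin_energies: np.ndarray  # MeV
    bin_weights: np.ndarray  # sum to 1

    def __post_init__(self) -> None:
        self.bin_energies = np.asarray(self.bin_energies, dtype=float)
        self.bin_weights = np.asarray(self.bin_weights, dtype=float)
        if self.bin_energies.shape != (16,) or self.bin_weights.shape != (16,):
            raise ConfigurationError("spectrum must have exactly 16 bins")
        if np.any(np.diff(self.bin_energies) <= 0):
            raise ConfigurationError("bin energies must be strictly increasing")
        if np.any(self.bin_weights < 0):
            raise ConfigurationError("bin weights must be >= 0")
        total = self.bin_weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            if total <= 0:
                raise ConfigurationError("spectrum weights sum to zero")
            self.bin_weights = self.bin_weights / total

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.bin_energies * self.bin_weights))


@dataclass
class Material:
    name: str
    reference_ed: float
    mu_over_rho: np.ndarray  # cm^2/g, 16 bins
    muen_over_rho: np.ndarray  # cm^2/g, 16 bins

    def __post_init__(self) -> None:
        self.mu_over_rho = np.asarray(self.mu_over_rho, dtype=float)
        self.muen_over_rho = np.asarray(self.muen_over_rho, dtype=float)
        for c in (self.mu_over_rho, self.muen_over_rho):
            if c.shape != (16,):
                raise ConfigurationError("material coefficients need 16 bins")
            if np.any(c <= 0):
                raise ConfigurationError("material coefficients must be > 0")


class MaterialTable:
    """The nine-material radiological property set, ED-indexed.

    The set always contains exactly nine materials, one of which is water at
    reference ED 1.0.  Properties for an arbitrary ED are obtained by linear
    interpolation between the two bracketing materials (clamped outside the
    tabulated ED range).
    """

    def __init__(self, materials: list[Material], bin_energies: np.ndarray):
        if len(materials) != 9:
            raise ConfigurationError("the material set must contain exactly nine entries")
        materials = sorted(materials, key=lambda m: m.reference_ed)
        names = [m.name for m in materials]
        if "water" not in names:
            raise ConfigurationError("one material must be named 'water'")
        water = materials[names.index("water")]
        if not np.isclose(water.reference_ed, 1.0):
            raise ConfigurationError("water must have reference ED 1.0")
        eds = np.array([m.reference_ed for m in materials])
        if np.any(np.diff(eds) <= 0):
            raise ConfigurationError("material reference EDs must be distinct")
        self.materials = materials
        self.bin_energies = np.asarray(bin_energies, dtype=float)
        self._eds = eds
        self._mu = np.stack([m.mu_over_rho for m in materials])  # (9, 16)
        self._muen = np.stack([m.muen_over_rho for m in materials])
        self.water = water

    def blend(self, ed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (mu/rho, muen/rho) for ED value(s); see material_blend."""
        ed_arr = np.asarray(ed, dtype=float)
        if np.any(ed_arr < 0):
            raise ValueError("electron density must be >= 0")
        flat = ed_arr.ravel()
        mu = np.empty(flat.shape + (16,))
        muen = np.empty(flat.shape + (16,))
        for b in range(16):
            mu[:, b] = np.interp(flat, self._eds, self._mu[:, b])
            muen[:, b] = np.interp(flat, self._eds, self._muen[:, b])
        if ed_arr.ndim == 0:
            return mu[0], muen[0]
        return mu.reshape(ed_arr.shape + (16,)), muen.reshape(ed_arr.shape + (16,))


def load_materials(path: str | Path | None = None) -> MaterialTable:
    """Load the nine-material table (default: the packaged surrogate table)."""
    if path is None:
        with resources.files("ccdose.data").joinpath("materials.yaml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    energies = np.array(doc["bin_energies_mev"], dtype=float)
    mats = [
        Material(
            name=m["name"],
            reference_ed=float(m["reference_ed"]),
            mu_over_rho=np.array(m["mu_over_rho"], dtype=float),
            muen_over_rho=np.array(m["muen_over_rho"], dtype=float),
        )
        for m in doc["materials"]
    ]
    return MaterialTable(mats, energies)


_DEFAULT_MATERIALS: MaterialTable | None = None


def default_materials() -> MaterialTable:
    global _DEFAULT_MATERIALS
    if _DEFAULT_MATERIALS is None:
        _DEFAULT_MATERIALS = load_materials()
    return _DEFAULT_MATERIALS


def material_blend(ed: float | np.ndarray, table: MaterialTable | None = None):
    """(mu/rho[16], muen/rho[16]) at the given relative electron density.

    Locates the bracketing materials by reference ED and linearly interpolates
    each coefficient bin; EDs outside the nine-material range clamp to the end
    materials.  ED exactly at a node returns that material's coefficients.
    """
    if table is None:
        table = default_materials()
    return table.blend(ed)


# ---------------------------------------------------------------------------
# Grid I/O: internal ".ccd" format and DICOM RT Dose subset

_CCD_MAGIC = b"CCDGRID1"


def _write_ccd(grid: Grid3D, path: Path) -> None:
    header = {
        "dims": list(grid.dims),
        "spacing_mm": [float(s) for s in grid.spacing],
        "origin_mm": [float(o) for o in grid.origin],
        "unit": grid.unit,
        "dtype": "float32-le",
        "order": "x-fastest",
    }
    payload = json.dumps(header).encode()
    # x-fastest flat order: index = ix + nx*(iy + ny*iz)
    flat = np.asarray(grid.values, dtype="<f4").transpose(2, 1, 0).ravel()
    with open(path, "wb") as fh:
        fh.write(_CCD_MAGIC)
        fh.write(struct.pack("<I", len(payload)))
        fh.write(payload)
        fh.write(flat.tobytes())


def _read_ccd(path: Path) -> Grid3D:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _CCD_MAGIC:
            raise FormatError(f"{path}: not an internal grid file (bad magic)")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode())
        nx, ny, nz = header["dims"]
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
    values = data.reshape(nz, ny, nx).transpose(2, 1, 0).astype(float)
    return Grid3D(header["spacing_mm"], header["origin_mm"], values, header.get("unit", ""))


def _write_rtdose(grid: Grid3D, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0

    nx, ny, nz = grid.dims
    ds.Columns = nx
    ds.Rows = ny
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(grid.spacing[2] * k) for k in range(nz)]
    ds.FrameOfReferenceUID = generate_uid()

    vmax = float(np.max(grid.values)) if grid.values.size else 0.0
    scaling = vmax / (2**31 - 1) if vmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    stored = np.round(grid.values / scaling).astype("<u4")
    # DICOM pixel data: frames (z), rows (y), cols (x)
    ds.PixelData = stored.transpose(2, 1, 0).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _read_rtdose(path: Path) -> Grid3D:
    import pydicom

    ds = pydicom.dcmread(str(path))
    for tag in ("ImagePositionPatient", "PixelSpacing", "GridFrameOffsetVector", "DoseGridScaling"):
        if not hasattr(ds, tag):
            raise FormatError(f"{path}: missing required RT Dose tag {tag}")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0], atol=1e-6):
            raise FormatError(f"{path}: non-uniform GridFrameOffsetVector not supported")
        z_spacing = float(dz[0])
    else:
        z_spacing = 1.0
    spacing = [float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), z_spacing]
    origin = [float(v) for v in ds.ImagePositionPatient]
    arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if arr.ndim == 2:
        arr = arr[None, ...]
    values = arr.transpose(2, 1, 0)  # (frames, rows, cols) -> (x, y, z)
    return Grid3D(spacing, origin, values, unit="Gy")


def write_dose_grid(grid: Grid3D, path: str | Path) -> None:
    """Write a dose grid; format chosen by extension (.dcm DICOM RT Dose, else internal)."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        _write_rtdose(grid, path)
    else:
        _write_ccd(grid, path)


def read_dose_grid(path: str | Path) -> Grid3D:
    """Read a dose grid written by :func:`write_dose_grid` or a DICOM RT Dose file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".dcm":
        return _read_rtdose(path)
    return _read_ccd(path)
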