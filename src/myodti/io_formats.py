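"""Readers and writers for every on-disk representation the pipeline touches.

NIfTI volumes (via nibabel), FSL-style ``bval``/``bvec`` gradient tables,
TCK streamline files, and the tabular outputs (CSV / JSON).  All spatial
bookkeeping is explicit: a volume carries its :class:`ImageGrid`, every
pipeline stage checks grid compatibility before combining arrays, and
streamline points always live in world millimetres.

Coordinate convention: voxel indices are 0-based; voxel ``(i, j, k)`` owns
the half-open world cube centred on ``affine @ (i, j, k, 1)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GridMismatchError",
    "ImageGrid",
    "GradientScheme",
    "Volume4D",
    "LabelMap",
    "CALF_MUSCLES",
    "read_nifti",
    "write_nifti",
    "read_gradients",
    "write_gradients",
    "write_streamlines",
    "read_streamlines",
    "write_json_report",
]

#: Default label table: the seven calf muscles segmented in a lower-leg study.
CALF_MUSCLES: dict[int, str] = {
    1: "extensor_digitorum",
    2: "gastrocnemius_lateralis",
    3: "gastrocnemius_medialis",
    4: "peroneus",
    5: "soleus",
    6: "tibialis_anterior",
    7: "tibialis_posterior",
}


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not (shape or affine differ)."""


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice: shape, voxel size in mm and a voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths of a voxel in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def from_voxel_size(cls, shape, voxel_size) -> "ImageGrid":
        vs = np.asarray(voxel_size, dtype=float)
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValueError("voxel_size must be a strictly positive triple")
        aff = np.diag([*vs, 1.0])
        return cls(tuple(shape), aff)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices (..., 3) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm points (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "ImageGrid", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def require_match(self, other: "ImageGrid", what: str = "volumes") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} are on different grids: shape {self.shape} vs {other.shape}, "
                f"max affine deviation "
                f"{np.abs(self.affine - other.affine).max():.3g} mm"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion acquisition scheme: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError("bvecs must be (n, 3)")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) length mismatch"
            )
        dw = bvals > 0
        if dw.sum() < 7:
            raise ValueError(
                "insufficient diffusion weighting: need >= 7 b > 0 measurements "
                f"for a tensor fit, got {int(dw.sum())}"
            )
        if (~dw).sum() < 1:
            raise ValueError("scheme needs at least one b = 0 measurement")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            n_bad = int(np.sum(np.abs(norms - 1.0) > 1e-6))
            warnings.warn(
                f"renormalizing {n_bad} non-unit b-vector(s) "
                f"(max deviation {np.abs(norms - 1.0).max():.2e})",
                stacklevel=2,
            )
            bvecs = bvecs.copy()
            bvecs[dw] = bvecs[dw] / norms[:, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvals > 0


@dataclass
class Volume4D:
    """Signal volume (x, y, z[, measurement]) on an :class:`ImageGrid`."""

    data: np.ndarray
    grid: ImageGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if tuple(self.data.shape[:3]) != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape[:3]} does not match grid "
                f"{self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            n = int(np.sum(~np.isfinite(self.data)))
            raise ValueError(f"volume contains {n} non-finite voxel value(s)")

    @property
    def n_measurements(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]


@dataclass
class LabelMap:
    """Integer muscle segmentation sharing a grid with the image volumes."""

    labels: np.ndarray
    grid: ImageGrid
    names: dict[int, str] = field(default_factory=lambda: dict(CALF_MUSCLES))

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("label map must be integer typed")
        if labels.ndim != 3:
            raise ValueError(f"label map must be 3D, got {labels.ndim}D")
        if tuple(labels.shape) != self.grid.shape:
            raise GridMismatchError("label shape does not match grid")
        self.labels = labels.astype(np.int32)
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.names)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from the name table")

    @property
    def present_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def read_nifti(path, names: dict[int, str] | None = None):
    """Read a NIfTI file; integer-typed images come back as a :class:`LabelMap`.

    Raises on missing files, non-NIfTI payloads, 2D images and NaN voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises ImageFileError subclasses
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim < 3:
        raise ValueError(f"{path}: expected a 3D/4D image, got {data.ndim}D")
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    grid = ImageGrid(tuple(data.shape[:3]), img.affine)
    if np.issubdtype(data.dtype, np.integer):
        if data.ndim != 3:
            raise ValueError(f"{path}: integer label map must be 3D")
        kwargs = {"names": names} if names is not None else {}
        return LabelMap(data, grid, **kwargs)
    n_nan = int(np.sum(~np.isfinite(data)))
    if n_nan:
        raise ValueError(f"{path}: {n_nan} non-finite voxel value(s)")
    return Volume4D(data, grid)


def write_nifti(obj: Volume4D | LabelMap, path) -> Path:
    """Write a volume or label map losslessly (float64 / int32 on disk)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, LabelMap):
        img = nib.Nifti1Image(obj.labels.astype(np.int32), obj.grid.affine)
    else:
        img = nib.Nifti1Image(np.asarray(obj.data, dtype=np.float64), obj.grid.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# FSL gradient tables
# ---------------------------------------------------------------------------

def read_gradients(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-dialect gradient table.

    ``bval``: one whitespace-separated row of b-values.  ``bvec``: three rows
    (x, y, z components).  Per-entry pairing is preserved; unit norms are
    validated by :class:`GradientScheme` (renormalized with a warning beyond
    1e-6 deviation, rejected beyond 1e-3).
    """
    for p in (bval_path, bvec_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"no such gradient file: {p}")
    bvals = np.loadtxt(bval_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: rows are components
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"gradient table length mismatch: {len(bvals)} b-values vs "
            f"{len(bvecs)} b-vectors"
        )
    dw = bvals > 0
    if dw.any():
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            worst = float(np.abs(norms - 1.0).max())
            if worst > 0.5:  # grossly non-unit, e.g. (2,0,0): renormalize loudly
                warnings.warn(
                    f"b-vectors deviate from unit norm by up to {worst:.3g}; "
                    "renormalizing",
                    stacklevel=2,
                )
                bvecs = bvecs.copy()
                bvecs[dw] = bvecs[dw] / norms[:, None]
    return GradientScheme(bvals, bvecs)


def write_gradients(scheme: GradientScheme, bval_path, bvec_path) -> None:
    Path(bval_path).parent.mkdir(parents=True, exist_ok=True)
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in scheme.bvecs.T:  # three rows: x, y, z
            fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Streamlines (TCK)
# ---------------------------------------------------------------------------

def write_streamlines(streamlines, path) -> Path:
    """Write streamlines (iterable of (n_i, 3) world-mm arrays) to TCK.

    An empty collection produces a valid file with zero streamlines.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = [np.asarray(s, dtype=np.float32) for s in streamlines]
    for s in pts:
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("each streamline must be an (n, 3) array of mm points")
    tractogram = nib.streamlines.Tractogram(pts, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))
    return path


def read_streamlines(path) -> list[np.ndarray]:
    """Read a TCK file back as a list of (n_i, 3) world-mm float32 arrays."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such streamline file: {path}")
    tck = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=np.float32) for s in tck.streamlines]


def write_json_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default) + "\n")
    return path
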