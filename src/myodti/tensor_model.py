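"""Per-voxel diffusion tensor estimation and scalar map derivation.

The signal model is the single diffusion tensor,

    S_i = S0 * exp(-b_i * g_i^T D g_i),

with b in s/mm^2 and D carried in units of 1e-3 mm^2/s throughout (the
conversion happens inside the design matrix).  Fitting is log-linear least
squares followed by iteratively reweighted least squares with weights equal
to the squared predicted signal, which undoes the heteroscedasticity the log
transform introduces.  The robust variant adds Geman-McClure reweighting and
residual-based outlier rejection before a final clean refit, in the spirit
of the REKINDLE family of estimators: measurements whose log-domain residual
exceeds ``kappa`` robust standard deviations are excluded.

Scalar maps: FA, MD, lambda1..3 and RD come from a per-voxel eigen
decomposition with eigenvalues sorted descending.  Voxels with negative
eigenvalues are kept but flagged invalid (physically impossible diffusion),
so downstream averaging can exclude them instead of silently clamping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io_formats import GradientScheme, ImageGrid, Volume4D

__all__ = [
    "Tensor",
    "TensorField",
    "ScalarMaps",
    "RobustFit",
    "design_matrix",
    "predict_signal",
    "fit_tensor_wls",
    "fit_tensor_robust",
    "fit_tensor_field",
    "eigen_maps",
    "snr_map",
    "write_tensor_field",
    "read_tensor_field",
    "write_scalar_maps",
]

# Lower-triangular element order used everywhere for the 6-vector form.
TENSOR_ELEMENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

_MAX_ITER = 20
_TOL = 1e-6
_KAPPA = 6.0


@dataclass(frozen=True)
class Tensor:
    """Symmetric diffusion tensor (units 1e-3 mm^2/s) plus the b=0 signal."""

    d: np.ndarray  # (6,) Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    s0: float

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (6,):
            raise ValueError("tensor needs 6 unique elements")
        object.__setattr__(self, "d", d)

    @property
    def matrix(self) -> np.ndarray:
        dxx, dyy, dzz, dxy, dxz, dyz = self.d
        return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3)."""
        return np.sort(np.linalg.eigvalsh(self.matrix))[::-1]

    @classmethod
    def from_matrix(cls, m: np.ndarray, s0: float) -> "Tensor":
        m = np.asarray(m, dtype=float)
        return cls(
            np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]]), s0
        )

    @classmethod
    def from_eigen(cls, evals, evecs, s0: float = 1.0) -> "Tensor":
        """Build from eigenvalues (1e-3 mm^2/s) and column eigenvectors."""
        evecs = np.asarray(evecs, dtype=float)
        m = evecs @ np.diag(np.asarray(evals, dtype=float)) @ evecs.T
        return cls.from_matrix(m, s0)


class RobustFit(NamedTuple):
    tensor: Tensor
    outliers: np.ndarray  # boolean, per measurement
    fell_back: bool  # True when rejection left too few points


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(n, 7) design for theta = [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz].

    The 1e-3 factor converts the stored diffusivity units to mm^2/s.
    """
    b = scheme.bvals * 1e-3
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def predict_signal(tensor: Tensor, scheme: GradientScheme) -> np.ndarray:
    """Forward model: S_i = S0 exp(-b_i g_i^T D g_i) for every measurement."""
    X = design_matrix(scheme)
    theta = np.concatenate([[np.log(tensor.s0)], tensor.d])
    return np.exp(X @ theta)


def _check_design(X: np.ndarray) -> None:
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(
            f"degenerate gradient scheme: design matrix condition number {cond:.3g}"
        )


def _prepare_signals(signals: np.ndarray) -> np.ndarray:
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    if np.any(s <= 0):
        n = int(np.sum(s <= 0))
        warnings.warn(
            f"clamping {n} non-positive signal value(s) to machine epsilon "
            "for the log transform",
            stacklevel=3,
        )
        s = np.where(s > 0, s, np.finfo(float).eps)
    return s


def _wls_solve(X, Y, weights):
    """Batched weighted LS: solve (X' W X) theta = X' W y per voxel row."""
    A = np.einsum("vn,ni,nj->vij", weights, X, X)
    rhs = np.einsum("vn,ni,vn->vi", weights, X, Y)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def _fit_wls_batch(Y: np.ndarray, X: np.ndarray, weights: np.ndarray | None = None):
    """Log-linear init + predicted-signal-squared IRLS, vectorized over voxels.

    Y is (V, n) of log signals; optional fixed per-measurement weight factors
    (V, n) multiply the adaptive exp(2 X theta) weights (used for outlier
    exclusion and robust reweighting).
    """
    base = np.ones_like(Y) if weights is None else weights
    theta = _wls_solve(X, Y, base)  # OLS when base == 1
    for _ in range(_MAX_ITER):
        # weights are scale-free per voxel: normalize the log-predicted
        # signal before exponentiating so extreme fits cannot overflow
        logw = 2.0 * (theta @ X.T)
        logw -= logw.max(axis=1, keepdims=True)
        w = base * np.exp(np.maximum(logw, -60.0))
        w = np.maximum(w, 1e-12 * w.max(axis=1, keepdims=True))
        new = _wls_solve(X, Y, w)
        delta = np.abs(new - theta).max(axis=1)
        scale = np.abs(theta).max(axis=1) + 1e-30
        theta = new
        if np.all(delta / scale < _TOL):
            break
    return theta


def fit_tensor_wls(signals, scheme: GradientScheme) -> Tensor:
    """Weighted least squares tensor fit for a single voxel."""
    X = design_matrix(scheme)
    _check_design(X)
    s = _prepare_signals(signals)
    if s.shape[1] != len(scheme):
        raise ValueError("signal length does not match gradient scheme")
    theta = _fit_wls_batch(np.log(s), X)[0]
    return Tensor(theta[1:], float(np.exp(theta[0])))


def fit_tensor_robust(
    signals, scheme: GradientScheme, kappa: float = _KAPPA
) -> RobustFit:
    """Robust tensor fit with Geman-McClure IRLS and outlier rejection.

    Steps: (1) robust IRLS fit where each measurement is additionally
    down-weighted by the Geman-McClure function of its studentized log
    residual, (2) measurements with |residual| > kappa * robust scale are
    flagged as outliers, (3) a final plain WLS refit excludes them.  If
    rejection would leave fewer than 7 measurements (or no b = 0), the
    non-robust fit is returned and the voxel flagged via ``fell_back``.
    """
    X = design_matrix(scheme)
    _check_design(X)
    s = _prepare_signals(signals)
    y = np.log(s)

    theta = _fit_wls_batch(y, X)
    for _ in range(_MAX_ITER):
        r = y - theta @ X.T
        scale = _robust_scale(r)
        gm = 1.0 / (1.0 + (r / scale) ** 2) ** 2
        new = _fit_wls_batch(y, X, weights=gm)
        if np.abs(new - theta).max() / (np.abs(theta).max() + 1e-30) < _TOL:
            theta = new
            break
        theta = new

    r = (y - theta @ X.T)[0]
    scale = float(_robust_scale(r[None, :])[0, 0])
    outliers = np.abs(r) > kappa * scale
    keep = ~outliers
    if keep.sum() < 7 or not np.any(keep & scheme.b0_mask):
        return RobustFit(fit_tensor_wls(signals, scheme), outliers, True)
    theta = _fit_wls_batch(y, X, weights=keep[None, :].astype(float))[0]
    return RobustFit(Tensor(theta[1:], float(np.exp(theta[0]))), outliers, False)


def _robust_scale(r: np.ndarray) -> np.ndarray:
    """1.4826 * MAD per voxel row, floored to avoid zero division."""
    med = np.median(r, axis=1, keepdims=True)
    mad = np.median(np.abs(r - med), axis=1, keepdims=True)
    return np.maximum(1.4826 * mad, 1e-10)


@dataclass
class TensorField:
    """Fitted tensors on a grid: (X, Y, Z, 6) elements plus S0 and flags."""

    d: np.ndarray  # (X, Y, Z, 6) in 1e-3 mm^2/s
    s0: np.ndarray  # (X, Y, Z)
    grid: ImageGrid
    fitted: np.ndarray  # (X, Y, Z) bool: voxel was inside the fit mask
    fallback: np.ndarray  # (X, Y, Z) bool: robust fit fell back / clamped input

    def tensor_at(self, idx) -> Tensor:
        return Tensor(self.d[idx], float(self.s0[idx]))

    def matrices(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) symmetric matrices."""
        d = self.d
        m = np.zeros(d.shape[:-1] + (3, 3))
        m[..., 0, 0] = d[..., 0]
        m[..., 1, 1] = d[..., 1]
        m[..., 2, 2] = d[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = d[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = d[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = d[..., 5]
        return m


def fit_tensor_field(
    dwi: Volume4D,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    robust: bool = True,
    kappa: float = _KAPPA,
) -> TensorField:
    """Fit every in-mask voxel (vectorized); robust adds GM reweighting.

    The field-level robust path mirrors :func:`fit_tensor_robust` with the
    per-voxel loop replaced by batched linear algebra.
    """
    if dwi.data.ndim != 4:
        raise ValueError("need a 4D DWI volume")
    if dwi.data.shape[3] != len(scheme):
        raise ValueError("DWI measurement count does not match gradient scheme")
    X = design_matrix(scheme)
    _check_design(X)
    shape = dwi.grid.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    sig = dwi.data[mask]  # (V, n)
    clamped = np.any(sig <= 0, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig = _prepare_signals(sig)
    y = np.log(sig)

    theta = _fit_wls_batch(y, X)
    fell_back = np.zeros(y.shape[0], dtype=bool)
    if robust:
        for _ in range(_MAX_ITER):
            r = y - theta @ X.T
            scale = _robust_scale(r)
            gm = 1.0 / (1.0 + (r / scale) ** 2) ** 2
            new = _fit_wls_batch(y, X, weights=gm)
            if np.abs(new - theta).max() / (np.abs(theta).max() + 1e-30) < _TOL:
                theta = new
                break
            theta = new
        r = y - theta @ X.T
        scale = _robust_scale(r)
        keep = np.abs(r) <= kappa * scale
        bad = (keep.sum(axis=1) < 7) | ~np.any(keep & scheme.b0_mask, axis=1)
        keep[bad] = True
        fell_back = bad
        theta = _fit_wls_batch(y, X, weights=keep.astype(float))

    d_flat = theta[:, 1:]
    s0_flat = np.exp(theta[:, 0])
    d = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    fb = np.zeros(shape, dtype=bool)
    d[mask] = d_flat
    s0[mask] = s0_flat
    fb[mask] = fell_back | clamped
    return TensorField(d, s0, dwi.grid, mask.copy(), fb)


@dataclass
class ScalarMaps:
    """Derived scalar maps on the diffusion grid (diffusivities 1e-3 mm^2/s)."""

    fa: np.ndarray
    md: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    rd: np.ndarray
    grid: ImageGrid
    valid: np.ndarray  # fitted, non-degenerate, non-negative eigenvalues
    snr: np.ndarray | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {
            "fa": self.fa,
            "md": self.md,
            "lambda1": self.lambda1,
            "rd": self.rd,
        }
        if self.snr is not None:
            out["snr"] = self.snr
        return out


def eigen_maps(field: TensorField) -> ScalarMaps:
    """Eigen-decompose the tensor field into FA / MD / lambda / RD maps.

    FA = sqrt(3/2) * sqrt(sum (lambda_i - MD)^2 / sum lambda_i^2), set to 0
    where all eigenvalues vanish.  Voxels with any negative eigenvalue or a
    fit fallback are flagged invalid but their values are kept.
    """
    evals = np.linalg.eigvalsh(field.matrices())  # ascending
    l3, l2, l1 = evals[..., 0], evals[..., 1], evals[..., 2]
    md = (l1 + l2 + l3) / 3.0
    rd = (l2 + l3) / 2.0
    ssq = l1**2 + l2**2 + l3**2
    dev = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(ssq > 0, dev / np.where(ssq > 0, ssq, 1), 0.0))
    fa = np.where(ssq > 0, fa, 0.0)
    valid = field.fitted & ~field.fallback & (l3 >= 0)
    return ScalarMaps(fa, md, l1, l2, l3, rd, field.grid, valid)


# On-disk component order for the 6-volume tensor NIfTI (lower triangular).
_DISK_ORDER = ("dxx", "dxy", "dyy", "dxz", "dyz", "dzz")
_TO_DISK = [TENSOR_ELEMENTS.index(e) for e in _DISK_ORDER]
_FROM_DISK = [_DISK_ORDER.index(e) for e in TENSOR_ELEMENTS]


def write_tensor_field(field: TensorField, path):
    """Write the tensor as a 6-component NIfTI, lower-triangular order."""
    from .io_formats import write_nifti

    return write_nifti(Volume4D(field.d[..., _TO_DISK], field.grid), path)


def read_tensor_field(path) -> TensorField:
    """Read a 6-component lower-triangular tensor NIfTI back into a field."""
    from .io_formats import read_nifti

    vol = read_nifti(path)
    if vol.data.ndim != 4 or vol.data.shape[3] != 6:
        raise ValueError("tensor file must have exactly 6 components")
    d = vol.data[..., _FROM_DISK]
    fitted = np.any(d != 0, axis=-1)
    return TensorField(
        d, np.zeros(vol.grid.shape), vol.grid, fitted,
        np.zeros(vol.grid.shape, dtype=bool),
    )


def write_scalar_maps(maps: ScalarMaps, out_dir):
    """Write fa/md/lambda1/rd (and snr if present) as individual NIfTIs."""
    from pathlib import Path

    from .io_formats import write_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.as_dict().items():
        write_nifti(Volume4D(np.asarray(arr, dtype=float), maps.grid),
                    out / f"{name}.nii.gz")
    write_nifti(
        Volume4D(maps.valid.astype(float), maps.grid), out / "valid.nii.gz"
    )
    return out


def snr_map(dwi: Volume4D, sigma: Volume4D, scheme: GradientScheme) -> np.ma.MaskedArray:
    """Per-voxel SNR: mean b = 0 signal over the local noise sigma.

    Voxels with sigma = 0 are masked (undefined), never infinite.
    """
    dwi.grid.require_match(sigma.grid, "DWI and noise-sigma map")
    if sigma.data.ndim != 3:
        raise ValueError("sigma map must be 3D")
    b0 = dwi.data[..., scheme.b0_mask].mean(axis=3)
    invalid = sigma.data <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(invalid, 0.0, b0 / np.where(invalid, 1.0, sigma.data))
    return np.ma.MaskedArray(snr, mask=invalid)
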