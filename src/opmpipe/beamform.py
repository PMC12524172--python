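"""LCMV beamformer: covariance, weights, pseudo-T images, virtual electrodes.

The beamformer solves, per location, for spatial weights w minimising the
projected variance w' C w subject to unit gain on the local leadfield
(w' l = 1), giving w = C^-1 l / (l' C^-1 l).  The data covariance C is
Tikhonov-regularised by 5 % of its largest eigenvalue.  Source orientation
is the direction of maximum beamformer-projected signal-to-noise, i.e. the
leading generalised eigenvector of (L' C^-1 L, L' C^-2 L) restricted to the
tangential plane (the radial leadfield of a spherical conductor is null).

Pseudo-T contrast images use the symmetric bounded form
T = (P_active - P_control) / (P_active + P_control); a noise-normalised
variant (P_a - P_c) / (2 P_noise) is available behind ``mode="noise"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .data import Recording, TrialSet
from .exceptions import EmptySetError, GeometryError
from .forward import SensorArray, leadfield as _leadfield, tangential_basis
from .preprocess import bandpass_array


# ---------------------------------------------------------------------------
# covariance

@dataclass
class Covariance:
    """Channel covariance (fT^2) over a frequency band, plus its provenance."""

    matrix: np.ndarray
    band: tuple[float, float]
    n_samples: int
    channel_mask: np.ndarray            # which channels of the array the rows map to
    regularization_fraction: float | None = None

    @property
    def is_regularized(self) -> bool:
        return self.regularization_fraction is not None


def compute_covariance(source, band=(1.0, 150.0), sampling_rate=None) -> Covariance:
    """Sample covariance of band-filtered data, mean removed per channel.

    ``source`` may be a Recording, a TrialSet (good trials are filtered
    per-trial then concatenated), or a raw channels x samples array (then
    ``sampling_rate`` is required).  Bad channels are excluded; the retained
    channel mask is recorded on the result.
    """
    if isinstance(source, TrialSet):
        fs = source.sampling_rate
        mask = ~source.bad_channels
        X = source.data[~source.bad_trials][:, mask]
        Xf = bandpass_array(X, fs, *band) if band else X
        flat = np.concatenate(list(Xf), axis=-1)
    elif isinstance(source, Recording):
        fs = source.sampling_rate
        mask = source.good_channels
        flat = source.data[mask]
        if band:
            flat = bandpass_array(flat, fs, *band)
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw arrays")
        fs = sampling_rate
        flat = np.asarray(source, float)
        mask = np.ones(flat.shape[0], dtype=bool)
        if band:
            flat = bandpass_array(flat, fs, *band)
    n_ch, n_samp = flat.shape
    if n_samp < 5 * n_ch:
        warnings.warn(f"covariance from only {n_samp} samples for {n_ch} channels; "
                      "regularization will carry the conditioning")
    flat = flat - flat.mean(axis=1, keepdims=True)
    C = flat @ flat.T / n_samp
    return Covariance(matrix=C, band=tuple(band) if band else None,
                      n_samples=n_samp, channel_mask=mask)


def regularize(cov: Covariance, fraction: float = 0.05) -> Covariance:
    """Tikhonov: C + fraction * lambda_max(C) * I."""
    lam = float(np.linalg.eigvalsh(cov.matrix)[-1])
    return replace(cov, matrix=cov.matrix + fraction * lam * np.eye(cov.matrix.shape[0]),
                   regularization_fraction=fraction)


# ---------------------------------------------------------------------------
# weights and orientation

def lcmv_weights(C_reg: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Unit-gain minimum-variance weights w = C^-1 l / (l' C^-1 l)."""
    l = np.asarray(l, float)
    if np.linalg.norm(l) == 0:
        raise GeometryError("zero leadfield: no weights exist")
    Cil = linalg.solve(C_reg, l, assume_a="pos")
    return Cil / (l @ Cil)


def optimal_orientation(C_reg: np.ndarray, L: np.ndarray,
                        basis: tuple[np.ndarray, np.ndarray],
                        degeneracy_rtol: float = 1e-8) -> np.ndarray:
    """Maximum projected-SNR source orientation in the tangential plane.

    Solves the 2x2 generalised eigenproblem (L' C^-1 L) c = mu (L' C^-2 L) c
    over the tangential columns of L and maps the leading eigenvector back
    into 3-space via ``basis = (t1, t2)``.  A degenerate pencil (isotropic
    noise makes every direction equivalent in SNR) falls back to the leading
    eigenvector of L' C^-1 L.  Unit norm, sign fixed to a positive first
    nonzero component.
    """
    Lt = L[:, :2]
    CiL = linalg.solve(C_reg, Lt, assume_a="pos")
    A = Lt.T @ CiL
    B = CiL.T @ CiL
    vals, vecs = linalg.eigh(A, B)
    if vals[-1] - vals[0] <= degeneracy_rtol * abs(vals[-1]):
        warnings.warn("degenerate orientation pencil; using leading eigenvector "
                      "of L' C^-1 L")
        vals2, vecs2 = linalg.eigh(A)
        c = vecs2[:, -1]
    else:
        c = vecs[:, -1]
    eta = c[0] * basis[0] + c[1] * basis[1]
    eta = eta / np.linalg.norm(eta)
    nz = np.nonzero(np.abs(eta) > 1e-12)[0]
    if nz.size and eta[nz[0]] < 0:
        eta = -eta
    return eta


class _Solver:
    """Bundles a regularised covariance with the array geometry."""

    def __init__(self, array: SensorArray, cov_reg: Covariance):
        self.array = array
        self.mask = cov_reg.channel_mask
        self.C = cov_reg.matrix

    def leadfield(self, location) -> tuple[np.ndarray, tuple]:
        L = _leadfield(location, self.array)[self.mask]
        t1, t2, _ = tangential_basis(location, self.array.sphere_origin)
        return L, (t1, t2)

    def weights(self, location) -> tuple[np.ndarray, np.ndarray]:
        L, basis = self.leadfield(location)
        eta = optimal_orientation(self.C, L, basis)
        w = lcmv_weights(self.C, L[:, :2] @ np.array([basis[0] @ eta, basis[1] @ eta]))
        return w, eta


# ---------------------------------------------------------------------------
# source grids and images

def make_grid(array: SensorArray, spacing: float = 0.004,
              brain_radius: float = 0.08, zmin: float = 0.0,
              bounds=None) -> np.ndarray:
    """Regular source grid inside the conductor, upper-hemisphere mask.

    Coordinates are metres with the origin at the sphere centre.  ``bounds``
    (3 x 2) optionally restricts to a box, for focused searches.
    """
    lo = np.full(3, -brain_radius)
    hi = np.full(3, brain_radius)
    if bounds is not None:
        b = np.asarray(bounds, float)
        lo, hi = np.maximum(lo, b[:, 0]), np.minimum(hi, b[:, 1])
    axes = [np.arange(lo[d], hi[d] + spacing / 2, spacing) for d in range(3)]
    P = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.linalg.norm(P, axis=1)
    keep = (r < brain_radius) & (r > 0.01) & (P[:, 2] > zmin)
    return P[keep] + array.sphere_origin


@dataclass
class PseudoTImage:
    """Voxelwise beamformer power contrast on a source grid."""

    points: np.ndarray
    values: np.ndarray
    spacing: float
    normalized: bool = False

    def normalize(self) -> "PseudoTImage":
        """Divide by the largest absolute deflection from zero (max |T| = 1)."""
        m = np.max(np.abs(self.values))
        if m == 0:
            raise ValueError("cannot normalize an all-zero image")
        return PseudoTImage(points=self.points, values=self.values / m,
                            spacing=self.spacing, normalized=True)


def pseudo_t_image(ts: TrialSet, band: tuple[float, float],
                   active_window: tuple[float, float],
                   control_window: tuple[float, float],
                   grid: np.ndarray | None = None, spacing: float = 0.004,
                   reg_fraction: float = 0.05, normalize: bool = False,
                   mode: str = "contrast", chunk: int = 256) -> PseudoTImage:
    """Voxelwise active-vs-control projected-power contrast.

    Band-filters the good trials, builds the regularised covariance from the
    whole (good) data, then per voxel projects the active and control
    windows through unit-gain weights at the optimal orientation.  P is the
    trial-summed projected variance in the window.
    """
    sa, sc = ts.sample_slice(active_window), ts.sample_slice(control_window)
    if sa.stop == sa.start or sc.stop == sc.start:
        raise EmptySetError("empty contrast window")
    fs = ts.sampling_rate
    mask = ~ts.bad_channels
    X = bandpass_array(ts.data[~ts.bad_trials][:, mask], fs, *band)
    cov = compute_covariance(np.concatenate(list(X), axis=-1), band=None,
                             sampling_rate=fs)
    cov = replace(cov, channel_mask=mask, band=tuple(band))
    creg = regularize(cov, reg_fraction)
    solver = _Solver(ts.array, creg)

    if grid is None:
        grid = make_grid(ts.array, spacing=spacing)
    n_vox = grid.shape[0]
    W = np.empty((n_vox, int(mask.sum())))
    for v in range(n_vox):
        W[v], _ = solver.weights(grid[v])

    Xa, Xc = X[:, :, sa], X[:, :, sc]
    Pa = np.empty(n_vox)
    Pc = np.empty(n_vox)
    for lo in range(0, n_vox, chunk):
        sl = slice(lo, min(lo + chunk, n_vox))
        Ya = np.einsum("vc,tcs->vts", W[sl], Xa)
        Yc = np.einsum("vc,tcs->vts", W[sl], Xc)
        Pa[sl] = Ya.var(axis=2).sum(axis=1)
        Pc[sl] = Yc.var(axis=2).sum(axis=1)

    if mode == "contrast":
        T = (Pa - Pc) / (Pa + Pc)
    elif mode == "noise":
        # band-filtered covariances are rank deficient, so the smallest
        # eigenvalue is no noise estimate; use the Tikhonov floor instead
        sigma2 = reg_fraction * float(np.linalg.eigvalsh(cov.matrix)[-1])
        n_tr = Xa.shape[0]
        Pn = n_tr * sigma2 * (W ** 2).sum(axis=1)
        T = (Pa - Pc) / (2 * Pn)
    else:
        raise ValueError(f"unknown pseudo-T mode '{mode}'")
    img = PseudoTImage(points=grid, values=T, spacing=spacing)
    return img.normalize() if normalize else img


def find_peak_location(img: PseudoTImage, sign: str = "min") -> np.ndarray:
    """Arg-extremum voxel (min for a beta ERD, max for a gamma response).

    Ties resolve to the lowest voxel index (argmin/argmax convention).
    """
    if img.values.size == 0:
        raise EmptySetError("empty image")
    idx = int(np.argmin(img.values) if sign == "min" else np.argmax(img.values))
    return img.points[idx]


def group_peak_location(images: list[PseudoTImage], sign: str = "min") -> np.ndarray:
    """Extremum of the group-mean image (subject images normalised first)."""
    if not images:
        raise EmptySetError("no images")
    pts = images[0].points
    for im in images[1:]:
        if im.points.shape != pts.shape or not np.allclose(im.points, pts):
            raise ValueError("images must share one source grid")
    mean = np.mean([im.normalize().values if not im.normalized else im.values
                    for im in images], axis=0)
    return find_peak_location(PseudoTImage(points=pts, values=mean,
                                           spacing=images[0].spacing), sign)


# ---------------------------------------------------------------------------
# virtual electrodes

@dataclass
class VirtualElectrode:
    """Beamformer-reconstructed source time course at one location (a.u.)."""

    data: np.ndarray          # (n_samples,) or (n_trials, n_samples)
    location: np.ndarray
    orientation: np.ndarray
    sampling_rate: float
    band: tuple[float, float] | None = None


def extract_virtual_electrode(source, location, band=None,
                              cov_band=(1.0, 150.0),
                              reg_fraction: float = 0.05) -> VirtualElectrode:
    """Broadband-weighted source time course at one location.

    Weights and orientation come from the broadband (default 1-150 Hz)
    regularised covariance; ``band`` optionally filters the channel data
    before projection, so one set of weights serves every analysis band.
    ``source`` is a Recording or TrialSet.
    """
    cov = regularize(compute_covariance(source, band=cov_band), reg_fraction)
    solver = _Solver(source.array if isinstance(source, (Recording, TrialSet))
                     else None, cov)
    w, eta = solver.weights(location)
    fs = source.sampling_rate
    if isinstance(source, TrialSet):
        X = source.data[~source.bad_trials][:, ~source.bad_channels]
        if band:
            X = bandpass_array(X, fs, *band)
        ve = np.einsum("c,tcs->ts", w, X)
    else:
        X = source.data[source.good_channels]
        if band:
            X = bandpass_array(X, fs, *band)
        ve = w @ X
    return VirtualElectrode(data=ve, location=np.asarray(location, float),
                            orientation=eta, sampling_rate=fs, band=band)


def extract_virtual_electrodes(source, locations, band=None,
                               cov_band=(1.0, 150.0),
                               reg_fraction: float = 0.05) -> list[VirtualElectrode]:
    """Virtual electrodes at many locations sharing one covariance solve.

    Equivalent to calling :func:`extract_virtual_electrode` per location but
    the broadband covariance and the filtered data are computed once — the
    per-region loop over a whole parcellation is otherwise dominated by
    redundant filtering.
    """
    cov = regularize(compute_covariance(source, band=cov_band), reg_fraction)
    solver = _Solver(source.array, cov)
    fs = source.sampling_rate
    if isinstance(source, TrialSet):
        X = source.data[~source.bad_trials][:, ~source.bad_channels]
    else:
        X = source.data[source.good_channels]
    if band:
        X = bandpass_array(X, fs, *band)
    out = []
    for loc in locations:
        w, eta = solver.weights(loc)
        ve = np.einsum("c,tcs->ts", w, X) if X.ndim == 3 else w @ X
        out.append(VirtualElectrode(data=ve, location=np.asarray(loc, float),
                                    orientation=eta, sampling_rate=fs, band=band))
    return out
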