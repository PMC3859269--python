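"""Iterative reconstruction: ART, SART, total variation and PICCS.

The measurements form the linear ray-sum system A x = y.  ART (Kaczmarz)
processes one ray at a time, projecting the current estimate onto that
ray's hyperplane:

    x <- x + a_i (y_i - <a_i, x>) / ||a_i||^2 .

SART processes one projection view at a time: residuals for all rays of
the view are computed from the same estimate, normalized by the ray weight
sums, back-distributed along the rays and averaged per voxel, scaled by a
relaxation factor omega in (0, 2).

The total variation of an image/volume is the sum over pixels/voxels of
the isotropic forward-difference gradient magnitude; minimizing it favours
piecewise-constant solutions and suppresses the streak and out-of-plane
artifacts of limited-angle sampling.  The TV-regularized methods alternate
one full data-consistency sweep with a few steepest-descent steps on the
TV functional of the whole volume.  The PICCS objective additionally pulls
the estimate toward a prior image X_P:

    J(X) = alpha * TV3D(X - X_P) + (1 - alpha) * TV3D(X),

which reduces to plain TV for alpha = 0.
"""

from __future__ import annotations

import os
import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from . import _siddon
from .config import ReconMethod, SimulationConfig, validate_config
from .phantom import VoxelVolume, build_phantom, empty_volume
from .projection import ProjectionSet, RayWeights, system_matrix

__all__ = [
    "ReconState",
    "ReconHistory",
    "art_sweep",
    "sart_update",
    "tv2d",
    "tv3d",
    "tv_descent",
    "piccs_objective",
    "reconstruct",
]

#: stabilizer added under the square root of the gradient magnitude when
#: differentiating the TV functional (keeps it smooth at zero gradient)
TV_DELTA = 1e-8

#: adaptive TV step: fraction of the mean absolute voxel change of the
#: preceding data-consistency sweep
TV_STEP_FRACTION = 0.2


@dataclass
class ReconState:
    """Current reconstruction estimate with bookkeeping."""

    estimate: VoxelVolume
    iteration: int = 0
    residual_norm: float = float("nan")


@dataclass
class ReconHistory:
    """Per-outer-iteration quality record.

    ``rmse``/``mssim``/``cnr`` entries are NaN when the reference volume or
    region of interest needed to compute them was not supplied.
    """

    residual_norm: list[float] = field(default_factory=list)
    rmse: list[float] = field(default_factory=list)
    mssim: list[float] = field(default_factory=list)
    cnr: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residual_norm)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "residual", "rmse", "mssim", "cnr"])
            for i in range(len(self)):
                writer.writerow([i + 1, self.residual_norm[i], self.rmse[i],
                                 self.mssim[i], self.cnr[i]])


# ---------------------------------------------------------------------------
# row-action updates


def _rays_to_csr(rays: Sequence[tuple[RayWeights, float]], n: int):
    indptr = np.zeros(len(rays) + 1, dtype=np.int64)
    chunks_i, chunks_w, ys = [], [], []
    for r, (rw, yi) in enumerate(rays):
        chunks_i.append(np.asarray(rw.indices, dtype=np.int64))
        chunks_w.append(np.asarray(rw.weights, dtype=np.float64))
        indptr[r + 1] = indptr[r] + len(rw.indices)
        ys.append(float(yi))
    idx = np.concatenate(chunks_i) if chunks_i else np.empty(0, dtype=np.int64)
    w = np.concatenate(chunks_w) if chunks_w else np.empty(0)
    return idx, w, indptr, np.asarray(ys)


def art_sweep(state: ReconState,
              rays: Iterable[tuple[RayWeights, float]]) -> ReconState:
    """One sequential ART sweep: rays are applied in the given order, each
    projecting the estimate exactly onto its measurement hyperplane, so
    immediately after a ray is processed its residual is zero (to floating
    precision).  Rays with zero weight norm are skipped."""
    rays = list(rays)
    vol = state.estimate.copy()
    x = vol.data.ravel()
    idx, w, indptr, y = _rays_to_csr(rays, x.size)
    _siddon.kaczmarz_sweep(x, w, idx, indptr, y)
    res = _residual_norm_csr(x, w, idx, indptr, y)
    return ReconState(vol, state.iteration + 1, res)


def _residual_norm_csr(x, w, idx, indptr, y) -> float:
    pred = np.add.reduceat(w * x[idx], indptr[:-1]) if idx.size else np.zeros_like(y)
    pred[indptr[:-1] == indptr[1:]] = 0.0
    return float(np.linalg.norm(y - pred))


def _sart_view_step(x: np.ndarray, mat: sp.csr_matrix, y: np.ndarray,
                    omega: float, row_sum=None, col_sum=None) -> None:
    """Simultaneous update of ``x`` (in place) from one projection view.

    Normalization sums use absolute weights so the update is well defined
    for sign-indefinite test systems; for tomographic weights (lengths,
    nonnegative) this is the standard SART normalization."""
    if row_sum is None:
        row_sum = np.abs(mat).sum(axis=1).A1 if hasattr(np.abs(mat).sum(axis=1), "A1") \
            else np.asarray(np.abs(mat).sum(axis=1)).ravel()
    if col_sum is None:
        col_sum = np.asarray(np.abs(mat).sum(axis=0)).ravel()
    resid = y - mat @ x
    scaled = np.divide(resid, row_sum, out=np.zeros_like(resid), where=row_sum > 0)
    num = mat.T @ scaled
    update = np.divide(num, col_sum, out=np.zeros_like(num), where=col_sum > 0)
    x += omega * update


def sart_update(state: ReconState,
                views: Sequence[Sequence[tuple[RayWeights, float]]],
                omega: float) -> ReconState:
    """One SART pass: each view (group of rays acquired at one source
    angle) is applied as a simultaneous update; views are processed in
    order.  Voxels not touched by a view are left unchanged.  ``omega``
    must lie in [0, 2); the degenerate value 0 leaves the state unchanged."""
    if not 0 <= omega < 2:
        raise ValueError(f"omega must lie in [0, 2), got {omega}")
    vol = state.estimate.copy()
    x = vol.data.ravel()
    res = float("nan")
    for view in views:
        idx, w, indptr, y = _rays_to_csr(list(view), x.size)
        mat = sp.csr_matrix((w, idx, indptr), shape=(len(y), x.size))
        _sart_view_step(x, mat, y, omega)
    # residual over all views after the pass
    total = 0.0
    for view in views:
        idx, w, indptr, y = _rays_to_csr(list(view), x.size)
        total += _residual_norm_csr(x, w, idx, indptr, y) ** 2
    return ReconState(vol, state.iteration + 1, float(np.sqrt(total)))


# ---------------------------------------------------------------------------
# total variation


def _fdiff(a: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference X(i) - X(i+1) with the out-of-range neighbour
    treated as equal to the edge value (difference 0)."""
    d = np.zeros_like(a)
    head = [slice(None)] * a.ndim
    tail = [slice(None)] * a.ndim
    head[axis] = slice(None, -1)
    tail[axis] = slice(1, None)
    d[tuple(head)] = a[tuple(head)] - a[tuple(tail)]
    return d


def tv2d(image: np.ndarray) -> float:
    """Isotropic total variation of a 2D image: the sum over pixels of
    sqrt(Dx^2 + Dy^2) with forward differences and a zero-gradient edge
    rule.  Nonnegative; zero iff the image is constant; 1-homogeneous."""
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("tv2d expects a 2D array")
    return float(np.sqrt(_fdiff(a, 0) ** 2 + _fdiff(a, 1) ** 2).sum())


def tv3d(volume: VoxelVolume | np.ndarray) -> float:
    """Isotropic total variation of a volume: sum over voxels of
    sqrt(Dx^2 + Dy^2 + Dz^2), same conventions as :func:`tv2d`."""
    a = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 3:
        raise ValueError("tv3d expects a 3D array")
    return float(np.sqrt(_fdiff(a, 0) ** 2 + _fdiff(a, 1) ** 2
                         + _fdiff(a, 2) ** 2).sum())


def _tv3d_gradient(a: np.ndarray, delta: float = TV_DELTA) -> np.ndarray:
    """Gradient of the (delta-smoothed) 3D TV functional."""
    dx, dy, dz = _fdiff(a, 0), _fdiff(a, 1), _fdiff(a, 2)
    mag = np.sqrt(dx * dx + dy * dy + dz * dz + delta)
    g = (dx + dy + dz) / mag
    g[1:, :, :] -= (dx / mag)[:-1, :, :]
    g[:, 1:, :] -= (dy / mag)[:, :-1, :]
    g[:, :, 1:] -= (dz / mag)[:, :, :-1]
    return g


def _piccs_value(a: np.ndarray, prior: np.ndarray | None, alpha: float) -> float:
    if prior is None or alpha == 0.0:
        return tv3d(a)
    return alpha * tv3d(a - prior) + (1.0 - alpha) * tv3d(a)


def _piccs_gradient(a: np.ndarray, prior: np.ndarray | None, alpha: float) -> np.ndarray:
    if prior is None or alpha == 0.0:
        return _tv3d_gradient(a)
    return (alpha * _tv3d_gradient(a - prior)
            + (1.0 - alpha) * _tv3d_gradient(a))


def tv_descent(volume: VoxelVolume | np.ndarray, n_steps: int, step_size: float,
               prior: VoxelVolume | np.ndarray | None = None,
               alpha: float = 0.0) -> VoxelVolume | np.ndarray:
    """Steepest descent on the (prior-weighted) 3D TV objective.

    Performs up to ``n_steps`` steps on
    J(X) = alpha*TV3D(X - prior) + (1-alpha)*TV3D(X) (plain TV when no
    prior is given or alpha is 0).  Each step moves along the normalized
    negative gradient by ``step_size`` (in intensity units), halving the
    step up to 10 times until the objective does not increase; if no
    non-increasing step is found the descent stops.  The objective never
    increases across the call.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    is_vol = isinstance(volume, VoxelVolume)
    a = (volume.data if is_vol else np.asarray(volume, dtype=np.float64)).copy()
    p = None
    if prior is not None:
        p = prior.data if isinstance(prior, VoxelVolume) else np.asarray(prior)
        if p.shape != a.shape:
            raise ValueError("prior shape does not match volume shape")

    obj = _piccs_value(a, p, alpha)
    for _ in range(n_steps):
        g = _piccs_gradient(a, p, alpha)
        gmax = np.abs(g).max()
        if gmax == 0.0 or step_size <= 0.0:
            break
        d = g / gmax
        s = step_size
        accepted = False
        for _halve in range(11):
            trial = a - s * d
            trial_obj = _piccs_value(trial, p, alpha)
            if trial_obj <= obj:
                a, obj = trial, trial_obj
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
    if is_vol:
        return VoxelVolume(a, volume.voxel_size, volume.origin.copy())
    return a


def piccs_objective(X: VoxelVolume | np.ndarray, X_P: VoxelVolume | np.ndarray,
                    alpha: float) -> float:
    """Prior-image-constrained objective
    alpha*TV3D(X - X_P) + (1-alpha)*TV3D(X); equals plain TV3D(X) at
    alpha = 0."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    a = X.data if isinstance(X, VoxelVolume) else np.asarray(X, dtype=np.float64)
    b = X_P.data if isinstance(X_P, VoxelVolume) else np.asarray(X_P, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return alpha * tv3d(a - b) + (1.0 - alpha) * tv3d(a)


# ---------------------------------------------------------------------------
# outer reconstruction loop


def reconstruct(Y: ProjectionSet, cfg: SimulationConfig,
                initial: VoxelVolume | None = None,
                ground_truth: VoxelVolume | None = None,
                roi: tuple[np.ndarray, np.ndarray] | None = None,
                matrices: list[sp.csr_matrix] | None = None,
                ) -> tuple[VoxelVolume, ReconHistory]:
    """Run the configured iterative reconstruction.

    Each outer iteration applies one full ART sweep (all views, rays in
    row-major detector order) or one SART pass (view by view), followed for
    the TV-regularized methods by TV descent over the whole volume, and
    then refreshes the forward projection Y_P.  The loop runs
    ``cfg.recon.n_iterations`` times or until ||Y_P - Y||_2 <= epsilon.

    ``initial`` defaults to the volume rasterized from
    ``cfg.initial_primitives`` (all zeros when that list is empty); the
    PICCS prior image is this initial volume.  When ``ground_truth`` is
    given the history additionally records RMSE over the volume and MSSIM
    on the layer of interest; when ``roi`` (signal, background masks) is
    given it records the CNR of the layer of interest.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    det, ph, rec = cfg.detector, cfg.phantom, cfg.recon
    n_pos = cfg.source.n_projections
    if Y.images.shape != (n_pos, det.n_u, det.n_v):
        raise ValueError(f"projection stack shape {Y.images.shape} does not match "
                         f"the configured geometry {(n_pos, det.n_u, det.n_v)}")

    if matrices is None:
        matrices = system_matrix(cfg)
    a_all = sp.vstack(matrices, format="csr")
    y_flat = Y.images.reshape(n_pos, -1)
    y_all = y_flat.ravel()

    if initial is None:
        if cfg.initial_primitives:
            initial = build_phantom(cfg.initial_primitives, ph)
        else:
            initial = empty_volume(ph)
    if initial.shape != (ph.n_x, ph.n_y, ph.n_z):
        raise ValueError(f"initial volume shape {initial.shape} does not match "
                         f"the phantom grid")
    vol = initial.copy()
    x = vol.data.ravel()
    prior = x.copy() if rec.method is ReconMethod.PICCS else None

    use_sart = rec.method.uses_sart
    if use_sart:
        row_sums = [np.asarray(np.abs(m).sum(axis=1)).ravel() for m in matrices]
        col_sums = [np.asarray(np.abs(m).sum(axis=0)).ravel() for m in matrices]

    indices = a_all.indices
    data = a_all.data
    indptr = a_all.indptr

    history = ReconHistory()
    residual = float(np.linalg.norm(a_all @ x - y_all))
    gt_loi = ground_truth.layer(rec.layer_of_interest) if ground_truth is not None else None

    for _k in range(rec.n_iterations):
        if residual <= rec.epsilon:
            break
        x_before = x.copy()
        if use_sart:
            for v, mat in enumerate(matrices):
                _sart_view_step(x, mat, y_flat[v], rec.omega,
                                row_sums[v], col_sums[v])
        else:
            _siddon.kaczmarz_sweep(x, data, indices, indptr, y_all)
        if rec.clamp_nonnegative:
            np.maximum(x, 0.0, out=x)

        if rec.method.uses_tv and rec.tv_steps > 0:
            step = rec.tv_step_size
            if step is None:
                step = TV_STEP_FRACTION * float(np.abs(x - x_before).mean())
            step *= rec.tv_weight
            if step > 0:
                alpha = rec.piccs_alpha if rec.method is ReconMethod.PICCS else 0.0
                p = prior.reshape(vol.shape) if prior is not None else None
                x[:] = tv_descent(x.reshape(vol.shape), rec.tv_steps, step,
                                  prior=p, alpha=alpha).ravel()

        residual = float(np.linalg.norm(a_all @ x - y_all))
        history.residual_norm.append(residual)
        if ground_truth is not None:
            from .metrics import mssim, rmse
            history.rmse.append(rmse(vol.data, ground_truth.data))
            history.mssim.append(mssim(gt_loi, vol.layer(rec.layer_of_interest)))
        else:
            history.rmse.append(float("nan"))
            history.mssim.append(float("nan"))
        if roi is not None:
            from .metrics import RoiSpec, cnr
            history.cnr.append(cnr(vol.layer(rec.layer_of_interest),
                                   RoiSpec(roi[0], roi[1])))
        else:
            history.cnr.append(float("nan"))

    return vol, history
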