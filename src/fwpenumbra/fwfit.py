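"""Voxelwise regularized bi-tensor (free-water elimination) fit for
single-shell DWI.

Signal model per voxel, with f the free-water fractional volume and D the
tissue diffusion tensor:

    A(b, g) = S(b, g)/S0 = (1 - f) exp(-b g'Dg) + f exp(-b d_w)

d_w is the fixed diffusivity of free water at body temperature. The fit
minimizes the sum of squared attenuation residuals per voxel, optionally plus
an isotropic first-difference (graph Laplacian) smoothness penalty on f with
weight ``lambda_reg``; ``lambda_reg = 0`` gives a purely voxelwise fit that
is directly comparable to ground truth and is used by the oracle checks.

Optimization uses projected damped Gauss-Newton steps with per-voxel
monotone backtracking: f is clipped to [0, 1] and the tensor is kept SPD by
clamping its eigenvalues to configurable physical bounds after every step.
The objective is non-increasing on every voxel by construction; iteration
stops at a relative objective tolerance or at ``max_iter``, and voxels that
fail to converge are flagged (last iterate returned).

Tensors are stored internally as 6-vectors in lower-triangular order
(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthcohort import WATER_DIFFUSIVITY, GradientScheme

__all__ = [
    "FitConfig",
    "FWMaps",
    "tensor_fa",
    "fit_dti",
    "init_estimates",
    "fit_freewater",
    "tensor_to_vec",
    "vec_to_tensor",
]

#: Assumed lower bound of tissue mean diffusivity used by the free-water
#: fraction initializer (mm^2/s).
MD_LOW = 0.6e-3


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the regularized bi-tensor fit.

    d_w : free-water diffusivity (mm^2/s), fixed, not fitted.
    eig_min, eig_max : physical bounds on tissue-tensor eigenvalues (mm^2/s).
    max_iter : Gauss-Newton iteration cap.
    tol : relative objective-change convergence tolerance.
    lambda_reg : weight of the spatial smoothness penalty on f (0 disables).
    damping : Marquardt damping factor on the normal equations.
    """

    d_w: float = WATER_DIFFUSIVITY
    eig_min: float = 0.1e-3
    eig_max: float = 2.5e-3
    max_iter: int = 200
    tol: float = 1e-6
    lambda_reg: float = 0.5
    damping: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.eig_min < self.eig_max):
            raise ValueError("eigenvalue bounds must satisfy 0 < eig_min < eig_max")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")


@dataclass
class FWMaps:
    """Fitted free-water maps: FW fraction, tissue tensor, and FA-t."""

    fw: np.ndarray
    tensor: np.ndarray  # (..., 3, 3) symmetric, mm^2/s
    fa_t: np.ndarray
    fit_mask: np.ndarray
    converged: np.ndarray | None = None
    n_iter: int = 0
    objective_history: np.ndarray | None = None  # (n_iter+1, n_voxels) if kept


_VEC_IDX = ([0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2])


def tensor_to_vec(t: np.ndarray) -> np.ndarray:
    """Symmetric (...,3,3) tensor -> (...,6) in (xx,yy,zz,xy,xz,yz) order."""
    return t[..., _VEC_IDX[0], _VEC_IDX[1]]


def vec_to_tensor(v: np.ndarray) -> np.ndarray:
    """(...,6) lower-triangular components -> symmetric (...,3,3) tensor."""
    t = np.empty(v.shape[:-1] + (3, 3), dtype=v.dtype)
    t[..., 0, 0] = v[..., 0]
    t[..., 1, 1] = v[..., 1]
    t[..., 2, 2] = v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = v[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = v[..., 5]
    return t


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(N, 6) matrix B with g'Dg = B @ d6 for the 6-vector tensor."""
    g = scheme.bvecs
    return np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def tensor_fa(tensor: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of symmetric tensors (vectorized).

    FA = sqrt(1/2) sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / sqrt(l1^2+l2^2+l3^2),
    from the tensor eigenvalues; an all-zero tensor maps to FA = 0.
    """
    t = np.asarray(tensor, dtype=float)
    lam = np.linalg.eigvalsh(t)
    num = (
        (lam[..., 0] - lam[..., 1]) ** 2
        + (lam[..., 1] - lam[..., 2]) ** 2
        + (lam[..., 2] - lam[..., 0]) ** 2
    )
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / np.where(den > 0, den, 1.0))
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def _clamp_eigenvalues(d6: np.ndarray, eig_min: float, eig_max: float) -> np.ndarray:
    """Project 6-vector tensors onto the SPD box by eigenvalue clamping."""
    t = vec_to_tensor(d6)
    lam, q = np.linalg.eigh(t)
    lam = np.clip(lam, eig_min, eig_max)
    t = np.einsum("...ab,...b,...cb->...ac", q, lam, q)
    return tensor_to_vec(t)


def _attenuation(dwi: np.ndarray, scheme: GradientScheme) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel attenuation A = S/mean(S_b0), clipped to [0, 1], plus S0."""
    s0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = dwi / np.where(s0 > 0, s0, 1.0)[..., None]
    return np.clip(a, 0.0, 1.0), s0


def fit_dti(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    *,
    eig_min: float = 1e-5,
    eig_max: float = WATER_DIFFUSIVITY,
) -> FWMaps:
    """Conventional single-compartment DTI fit (log-linear least squares).

    Used to initialize the bi-tensor fit and as the uncorrected baseline the
    free-water-corrected FA is compared against.
    """
    a, s0 = _attenuation(dwi, scheme)
    fit_mask = np.asarray(mask, dtype=bool) & (s0 > 0)
    dmask = scheme.dwi_mask
    b = scheme.bvals[dmask]
    design = _design_matrix(scheme)[dmask]

    av = np.clip(a[fit_mask][:, dmask], 1e-6, 1.0)
    y = -np.log(av) / b  # (nv, nd): per-direction apparent diffusivity
    d6, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    d6 = _clamp_eigenvalues(d6.T, eig_min, eig_max)

    tensor = np.zeros(a.shape[:-1] + (3, 3))
    tensor[fit_mask] = vec_to_tensor(d6)
    fa = np.zeros(a.shape[:-1])
    fa[fit_mask] = tensor_fa(vec_to_tensor(d6))
    return FWMaps(fw=np.zeros(a.shape[:-1]), tensor=tensor, fa_t=fa, fit_mask=fit_mask)


def init_estimates(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    config: FitConfig = FitConfig(),
) -> FWMaps:
    """Initial (f, D) estimates for the bi-tensor fit.

    The free-water fraction is interpolated from the observed mean
    diffusivity between an assumed tissue floor (MD_LOW) and pure water:

        f0 = clamp((e(-b MD_low) - e(-b MD_obs)) / (e(-b MD_low) - e(-b d_w)),
                   0.05, 0.95)

    and the tensor is initialized by a log-linear DTI fit on the
    free-water-corrected attenuation (A - f e_w) / (1 - f).
    """
    if np.count_nonzero(scheme.dwi_mask) < 6:
        raise ValueError("at least 6 non-zero-b directions required")
    if not np.any(mask):
        raise ValueError("mask is empty")
    a, s0 = _attenuation(dwi, scheme)
    fit_mask = np.asarray(mask, dtype=bool) & (s0 > 0)

    dmask = scheme.dwi_mask
    b = float(scheme.bvals[dmask].mean())
    dti = fit_dti(dwi, scheme, fit_mask)
    md_obs = np.trace(dti.tensor[fit_mask], axis1=-2, axis2=-1) / 3.0

    e_low = np.exp(-b * MD_LOW)
    e_w = np.exp(-b * config.d_w)
    f0 = (e_low - np.exp(-b * md_obs)) / (e_low - e_w)
    f0 = np.clip(f0, 0.05, 0.95)

    av = a[fit_mask][:, dmask]
    att_w = np.exp(-scheme.bvals[dmask] * config.d_w)
    at = (av - f0[:, None] * att_w) / (1.0 - f0[:, None])
    at = np.clip(at, 1e-4, 1.0)
    design = _design_matrix(scheme)[dmask]
    y = -np.log(at) / scheme.bvals[dmask]
    d6, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    d6 = _clamp_eigenvalues(d6.T, config.eig_min, config.eig_max)

    fw = np.zeros(a.shape[:-1])
    fw[fit_mask] = f0
    tensor = np.zeros(a.shape[:-1] + (3, 3))
    tensor[fit_mask] = vec_to_tensor(d6)
    fa = np.zeros(a.shape[:-1])
    fa[fit_mask] = tensor_fa(vec_to_tensor(d6))
    return FWMaps(fw=fw, tensor=tensor, fa_t=fa, fit_mask=fit_mask)


def _laplacian_edges(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (into the masked voxel vector) of 6-neighbor edges."""
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(np.count_nonzero(mask))
    pairs = []
    for axis in range(3):
        a = idx[tuple(slice(0, -1) if ax == axis else slice(None) for ax in range(3))]
        b = idx[tuple(slice(1, None) if ax == axis else slice(None) for ax in range(3))]
        keep = (a >= 0) & (b >= 0)
        pairs.append(np.stack([a[keep], b[keep]], axis=1))
    edges = np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=np.int64)
    return edges[:, 0], edges[:, 1]


def _model(
    f: np.ndarray, d6: np.ndarray, bvals: np.ndarray, design: np.ndarray, att_w: np.ndarray
) -> np.ndarray:
    e_t = np.exp(-bvals * (d6 @ design.T))
    return (1.0 - f)[:, None] * e_t + f[:, None] * att_w


def _fit_voxelwise(av, f, d6, bvals, design, att_w, config, keep_history):
    """Independent per-voxel projected Gauss-Newton with monotone backtracking."""
    nv = av.shape[0]
    obj = ((_model(f, d6, bvals, design, att_w) - av) ** 2).sum(axis=1)
    history = [obj.copy()] if keep_history else None
    active = np.ones(nv, dtype=bool)
    converged = np.zeros(nv, dtype=bool)
    it = 0
    for it in range(1, config.max_iter + 1):
        if not active.any():
            break
        fa_, da_, ava = f[active], d6[active], av[active]
        e_t = np.exp(-bvals * (da_ @ design.T))
        r = (1.0 - fa_)[:, None] * e_t + fa_[:, None] * att_w - ava
        # Jacobian: d model/df = e_w - e_t ; d model/d d6_j = -(1-f) b B_j e_t
        jac = np.empty((fa_.size, bvals.size, 7))
        jac[:, :, 0] = att_w[None, :] - e_t
        jac[:, :, 1:] = (
            -(1.0 - fa_)[:, None, None]
            * (bvals[None, :, None] * design[None, :, :])
            * e_t[:, :, None]
        )
        g = np.einsum("vnk,vn->vk", jac, r)
        h = np.einsum("vnk,vnl->vkl", jac, jac)
        diag = np.einsum("vkk->vk", h)
        h += (config.damping * np.clip(diag, 1e-12, None))[:, None, :] * np.eye(7)
        h += 1e-14 * np.eye(7)
        delta = np.linalg.solve(h, g[..., None])[..., 0]

        alpha = np.ones(fa_.size)
        best_f, best_d = fa_.copy(), da_.copy()
        best_obj = obj[active].copy()
        improved = np.zeros(fa_.size, dtype=bool)
        pending = np.ones(fa_.size, dtype=bool)
        for _ in range(25):
            if not pending.any():
                break
            fc = np.clip(fa_[pending] - alpha[pending] * delta[pending, 0], 0.0, 1.0)
            dc = _clamp_eigenvalues(
                da_[pending] - alpha[pending, None] * delta[pending, 1:],
                config.eig_min,
                config.eig_max,
            )
            mc = _model(fc, dc, bvals, design, att_w)
            oc = ((mc - av[active][pending]) ** 2).sum(axis=1)
            ok = oc < best_obj[pending]
            sub = np.flatnonzero(pending)
            acc = sub[ok]
            best_f[acc], best_d[acc], best_obj[acc] = fc[ok], dc[ok], oc[ok]
            improved[acc] = True
            pending[acc] = False
            alpha[sub[~ok]] *= 0.5

        prev = obj[active]
        f[active], d6[active] = best_f, best_d
        obj_new = obj.copy()
        obj_new[active] = best_obj
        rel = np.abs(prev - best_obj) / np.maximum(prev, 1e-30)
        done = (rel < config.tol) | ~improved
        idx_active = np.flatnonzero(active)
        converged[idx_active[done & (rel < config.tol)]] = True
        active[idx_active[done]] = False
        obj = obj_new
        if keep_history:
            history.append(obj.copy())
    return f, d6, converged, it, history


def _fit_regularized(av, f, d6, bvals, design, att_w, fit_mask, config, keep_history):
    """Alternating minimization of the coupled (data + smoothness) objective.

    Tensor step: per-voxel projected Gauss-Newton on the data term (the
    penalty does not involve D, so per-voxel monotone backtracking keeps the
    total objective monotone). f step: the data term is replaced by its
    Gauss-Newton quadratic model, giving a sparse SPD system
    (diag(a) + 2 lambda L) delta = -grad that is solved exactly, then the
    step is globally backtracked on the true total objective and f clipped
    to [0, 1]. History (if kept) records the total objective, which is
    non-increasing by construction.
    """
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    nv = av.shape[0]
    lam = config.lambda_reg
    ei, ej = _laplacian_edges(fit_mask)
    ones = np.ones(ei.size)
    w = sparse.coo_matrix((ones, (ei, ej)), shape=(nv, nv))
    w = w + w.T
    lap = (sparse.diags(np.asarray(w.sum(axis=1)).ravel()) - w).tocsr()

    def total(fv, dv):
        r = _model(fv, dv, bvals, design, att_w) - av
        return float((r**2).sum()) + lam * float(fv @ (lap @ fv))

    prev_total = total(f, d6)
    history = [np.array([prev_total])] if keep_history else None
    converged = np.zeros(nv, dtype=bool)
    it = 0
    for it in range(1, config.max_iter + 1):
        # --- tensor step (voxelwise GN, f held fixed) ---
        e_t = np.exp(-bvals * (d6 @ design.T))
        r = (1.0 - f)[:, None] * e_t + f[:, None] * att_w - av
        jac = (
            -(1.0 - f)[:, None, None]
            * (bvals[None, :, None] * design[None, :, :])
            * e_t[:, :, None]
        )
        g = np.einsum("vnk,vn->vk", jac, r)
        h = np.einsum("vnk,vnl->vkl", jac, jac)
        diag = np.einsum("vkk->vk", h)
        h += (config.damping * np.clip(diag, 1e-12, None))[:, None, :] * np.eye(6)
        h += 1e-14 * np.eye(6)
        delta_d = np.linalg.solve(h, g[..., None])[..., 0]
        obj_v = (r**2).sum(axis=1)
        alpha = np.ones(nv)
        pending = np.ones(nv, dtype=bool)
        for _ in range(20):
            if not pending.any():
                break
            dc = _clamp_eigenvalues(
                d6[pending] - alpha[pending, None] * delta_d[pending],
                config.eig_min,
                config.eig_max,
            )
            oc = ((_model(f[pending], dc, bvals, design, att_w) - av[pending]) ** 2).sum(axis=1)
            ok = oc < obj_v[pending]
            sub = np.flatnonzero(pending)
            d6[sub[ok]] = dc[ok]
            pending[sub[ok]] = False
            alpha[sub[~ok]] *= 0.5
            # voxels that never improve simply keep their tensor this round
            pending &= alpha > 1e-6

        # --- f step (coupled quadratic surrogate, exact sparse solve) ---
        e_t = np.exp(-bvals * (d6 @ design.T))
        jf = att_w[None, :] - e_t
        r = (1.0 - f)[:, None] * e_t + f[:, None] * att_w - av
        grad = 2.0 * (r * jf).sum(axis=1) + 2.0 * lam * (lap @ f)
        curv = 2.0 * (jf**2).sum(axis=1)
        sys = sparse.diags(curv + 1e-12) + 2.0 * lam * lap
        delta_f = spsolve(sys.tocsr(), -grad)
        cur = total(f, d6)
        scale = 1.0
        accepted = False
        for _ in range(30):
            f_try = np.clip(f + scale * delta_f, 0.0, 1.0)
            t_try = total(f_try, d6)
            if t_try < cur:
                f, cur = f_try, t_try
                accepted = True
                break
            scale *= 0.5
        if keep_history:
            history.append(np.array([cur]))
        rel = abs(prev_total - cur) / max(prev_total, 1e-30)
        prev_total = cur
        if rel < config.tol:
            converged[:] = True
            break
        if not accepted and rel < 1e-15:
            break
    return f, d6, converged, it, history


def fit_freewater(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    config: FitConfig = FitConfig(),
    *,
    keep_history: bool = False,
) -> FWMaps:
    """Fit the regularized bi-tensor model on every voxel in ``mask``.

    Returns voxelwise FW fraction, tissue tensor (eigenvalues clamped to the
    configured physical bounds), FA-t, the fitted-voxel mask, a per-voxel
    convergence flag, and optionally the per-iteration data-term objective
    (``keep_history=True``), used to assert the monotonicity contract.
    """
    init = init_estimates(dwi, scheme, mask, config)
    fit_mask = init.fit_mask
    a, _ = _attenuation(dwi, scheme)
    av = a[fit_mask]  # (nv, N) includes b0 entries (residual 0 there)

    bvals = scheme.bvals
    design = _design_matrix(scheme)
    att_w = np.exp(-bvals * config.d_w)

    f = init.fw[fit_mask].copy()
    d6 = tensor_to_vec(init.tensor[fit_mask])

    if config.lambda_reg > 0:
        f, d6, converged, it, history = _fit_regularized(
            av, f, d6, bvals, design, att_w, fit_mask, config, keep_history
        )
    else:
        f, d6, converged, it, history = _fit_voxelwise(
            av, f, d6, bvals, design, att_w, config, keep_history
        )

    fw = np.zeros(a.shape[:-1])
    fw[fit_mask] = f
    tensor = np.zeros(a.shape[:-1] + (3, 3))
    tensor[fit_mask] = vec_to_tensor(d6)
    fa_map = np.zeros(a.shape[:-1])
    fa_map[fit_mask] = tensor_fa(vec_to_tensor(d6))
    conv = np.zeros(a.shape[:-1], dtype=bool)
    conv[fit_mask] = converged
    return FWMaps(
        fw=fw,
        tensor=tensor,
        fa_t=fa_map,
        fit_mask=fit_mask,
        converged=conv,
        n_iter=it,
        objective_history=np.asarray(history) if keep_history else None,
    )
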