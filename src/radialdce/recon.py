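"""Regularized dynamic reconstructions from radial k-space.

Four solvers share one verified encoding operator:

* ``mocco_reconstruct`` — data consistency plus an l1 penalty on the part of
  the image time series lying *outside* a learned low-rank temporal model
  (model consistency condition).  Solutions are full rank: the model steers
  but does not confine them.
* ``pcb_reconstruct``   — principal-component-basis reconstruction: the
  series is constrained exactly to the span of K temporal basis functions
  and only the spatial coefficient maps are estimated.
* ``cstv_reconstruct``  — compressed sensing with an l1 penalty on first
  order temporal differences.
* ``sense_reference``   — per-frame unregularized iterative SENSE, used as
  the fully-sampled reference.

The l1 solvers use iteratively re-weighted least squares: each outer
iteration majorizes the l1 term by a weighted quadratic which conjugate
gradients then decreases, so the true objective is non-increasing across
outer iterations.  Internally the encoding operator is scaled to unit
spectral norm and the data to unit mean magnitude, so the regularization
weights are comparable across problem sizes; outputs are rescaled back to
the data's native units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .acquisition import CoilMaps, EncodingSeries, KSpaceSeries, RadialTrajectory


# ---------------------------------------------------------------------------
# temporal bases
# ---------------------------------------------------------------------------

@dataclass
class TemporalBasis:
    """Rank-K matrix of orthonormal temporal basis functions (columns).

    Columns are ordered by descending explained variance; for learned bases
    the independent-component decomposition of the same span is kept in
    ``components`` for inspection (the solvers only use the span).
    """

    basis: np.ndarray           # (n_frames, K)
    origin: str                 # "HR" or "LR"
    components: np.ndarray | None = None

    def __post_init__(self):
        g = self.basis.conj().T @ self.basis
        if not np.allclose(g, np.eye(self.rank), atol=1e-9):
            raise ValueError("basis columns must be orthonormal")

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    @property
    def n_frames(self) -> int:
        return self.basis.shape[0]

    def project(self, series: np.ndarray) -> np.ndarray:
        """Apply the projector B B* along the leading (frame) axis."""
        flat = series.reshape(self.n_frames, -1)
        out = self.basis @ (self.basis.conj().T @ flat)
        return out.reshape(series.shape)

    def residual(self, series: np.ndarray) -> np.ndarray:
        """(I - B B*) series: the part outside the temporal model."""
        return series - self.project(series)


def _orthonormalize(columns: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(columns, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    if rank < columns.shape[1]:
        raise ValueError("temporal curves are linearly dependent (rank-deficient basis)")
    return u[:, :columns.shape[1]]


def build_hr_basis(reference_curves: np.ndarray, n_frames: int) -> TemporalBasis:
    """High-resolution temporal model: reference curve(s) plus a constant.

    The constant column represents static tissue; each reference signal
    curve represents the known lesion dynamics.  Columns are orthonormalized.
    """
    curves = np.atleast_2d(np.asarray(reference_curves, dtype=complex))
    if curves.shape[0] == n_frames and curves.shape[1] != n_frames:
        curves = curves.T
    if curves.shape[1] != n_frames:
        raise ValueError("reference curves must be sampled at the frame centers")
    for c in curves:
        if np.std(c) <= 1e-12 * max(np.abs(np.mean(c)), 1e-30):
            raise ValueError("constant reference curve gives a rank-deficient basis")
    const = np.ones((1, n_frames), dtype=complex) / np.sqrt(n_frames)
    cols = np.vstack([curves, const]).T
    return TemporalBasis(_orthonormalize(cols), origin="HR")


def _spline_smooth(curves: np.ndarray, knot_spacing: int) -> np.ndarray:
    """Least-squares cubic-spline approximation of each column's time course.

    Suppresses frame-to-frame undersampling jitter while following the
    contrast dynamics; one shared design matrix makes this a single lstsq.
    """
    n_frames = curves.shape[0]
    t = np.arange(n_frames, dtype=float)
    interior = np.arange(knot_spacing, n_frames - 1, knot_spacing, dtype=float)
    knots = np.concatenate([[0, 0, 0, 0], interior,
                            [n_frames - 1] * 4])
    design = BSpline.design_matrix(t, knots, 3).toarray()
    coef, *_ = np.linalg.lstsq(design, curves, rcond=None)
    return design @ coef


def learn_lr_basis(kspace: KSpaceSeries, coils: CoilMaps, rank: int = 3,
                   kmax: float = 0.05, knot_spacing: int = 4, seed: int = 0,
                   encoding: EncodingSeries | None = None) -> TemporalBasis:
    """Learn the temporal model from the central (low-frequency) k-space.

    Every radial frame samples the k-space center, so a low-spatial-
    resolution image per frame is formed from samples with |k| <= ``kmax``
    (cycles/pixel).  Each voxel's time curve is smoothed by cubic-spline
    approximation, the rank-``rank`` principal temporal subspace of the
    smoothed curves is extracted, and independent component analysis
    (real/imaginary-stacked) rotates the subspace into independent
    components before re-orthonormalization.  Only the span matters to the
    solvers; ICA fixes the component identification within it.
    """
    if rank > kspace.n_frames:
        raise ValueError("rank cannot exceed the number of frames")
    enc = encoding or EncodingSeries(coils, kspace.trajectory)
    frames = []
    for f in range(kspace.n_frames):
        fe = enc.op(f)
        radii = np.abs(kspace.trajectory.frame_radii(f))
        w = fe.dcf * (radii <= kmax)
        imgs = fe.nufft.adjoint(kspace.samples[f], weights=w)
        frames.append(np.sum(np.conj(fe.coils) * imgs, axis=0))
    lowres = np.stack(frames)                       # (F, N, N)
    mag = np.mean(np.abs(lowres), axis=0)
    voxels = mag > 0.1 * mag.max()
    curves = lowres[:, voxels]                      # (F, V) complex
    smooth = _spline_smooth(curves, knot_spacing)
    u, s, _ = np.linalg.svd(smooth, full_matrices=False)
    u = u[:, :rank]
    components = _ica_components(u, s[:rank], seed)
    return TemporalBasis(u, origin="LR", components=components)


def _ica_components(u: np.ndarray, scales: np.ndarray,
                    seed: int) -> np.ndarray | None:
    """Independent temporal components of the learned subspace.

    ICA runs on the real/imaginary-stacked representation of the scaled
    subspace; the sources are projected back onto the complex span, so they
    carry no information beyond the subspace itself -- they identify the
    physically distinct time courses within it.
    """
    from sklearn.decomposition import FastICA

    K = u.shape[1]
    y = np.concatenate([np.real(u * scales), np.imag(u * scales)], axis=1)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = FastICA(n_components=K, random_state=seed,
                              max_iter=500).fit_transform(y)
        return u @ (u.conj().T @ sources.astype(complex))
    except Exception:
        return None


# ---------------------------------------------------------------------------
# solver configuration and outputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconConfig:
    """Iteration budget and regularization of the l1 solvers.

    ``lam`` is quoted relative to k-space data normalized to unit mean
    magnitude and an encoding operator of unit spectral norm.  ``max_iter``
    caps the *total* number of conjugate-gradient iterations; ``tol`` is the
    relative k-space residual at which iteration stops.
    """

    lam: float = 10.0
    max_iter: int = 400
    tol: float = 1e-9
    irls_epsilon: float = 1e-2    # weight floor, as a fraction of the median |r|
    inner_cg_iter: int = 10

    def __post_init__(self):
        if self.lam < 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid solver configuration")


MOCCO_DEFAULT = ReconConfig(lam=10.0)
CSTV_DEFAULT = ReconConfig(lam=2.0)


@dataclass
class ImageSeries:
    """Reconstructed complex image stack with solver provenance."""

    frames: np.ndarray            # (n_frames, N, N) complex
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def matrix(self) -> int:
        return self.frames.shape[-1]


@dataclass
class SpatialCoefficients:
    """K complex coefficient maps of a subspace (PCB) reconstruction."""

    coeffs: np.ndarray            # (K, N, N)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _operator_norm(enc: EncodingSeries, n_iter: int = 20, seed: int = 0) -> float:
    """Spectral norm of the weighted normal operator E'WE for one frame via
    power iteration (frames are statistically equivalent for golden-angle
    binning)."""
    fe = enc.op(0)
    N = enc.coils.sensitivities.shape[-1]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N))
    lam = 1.0
    for _ in range(n_iter):
        x = fe.normal_w(x)
        lam = np.linalg.norm(x)
        x /= lam
    return float(lam)


def _cg(apply_a, b, x0, n_iter, rtol=1e-12, precond=None):
    """(Preconditioned) conjugate gradients on A x = b, A Hermitian PSD."""
    x = x0.copy()
    r = b - apply_a(x)
    z = precond(r) if precond is not None else r
    p = z.copy()
    rz = np.vdot(r, z).real
    b_norm = np.linalg.norm(b)
    n_done = 0
    for _ in range(n_iter):
        ap = apply_a(p)
        denom = np.vdot(p, ap).real
        if denom <= 0:
            break
        alpha = rz / denom
        x += alpha * p
        r -= alpha * ap
        n_done += 1
        if np.linalg.norm(r) <= rtol * b_norm:
            break
        z = precond(r) if precond is not None else r
        rz_new = np.vdot(r, z).real
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, n_done


def _normalized_problem(kspace: KSpaceSeries, coils: CoilMaps,
                        trajectory: RadialTrajectory,
                        encoding: EncodingSeries | None):
    enc = encoding or EncodingSeries(coils, trajectory)
    scale = float(np.mean(np.abs(kspace.samples)))
    if scale == 0:
        scale = 1.0
    op_norm = _operator_norm(enc)
    m = kspace.samples / scale
    sqrt_l = np.sqrt(op_norm)
    return enc, m, scale, sqrt_l


def _irls_solve(kspace, coils, trajectory, config, lam_eff, penalty,
                penalty_adj, reweight, make_precond, penalty_norm,
                encoding, tag):
    """Shared IRLS driver for the l1-regularized solvers.

    ``penalty`` maps a series (F, N, N) to residual coefficients r;
    ``penalty_adj`` is its adjoint.  ``reweight(r)`` returns the IRLS
    weights (``reweight(None)`` the unit weights of the first pass, which
    seed the residual magnitudes -- reweighting from s = 0 self-traps);
    ``penalty_norm(r)`` is the penalized norm (plain or group l1).  Solves
    min ||W^1/2 (E s - m)||^2 + lam_eff * penalty_norm(r(s)) by reweighted
    quadratics.  Each quadratic is attacked by preconditioned conjugate
    gradients: ``make_precond(weights, d0, lam_eff)`` builds a solver-
    specific preconditioner that is exact in the penalty's temporal
    eigenstructure (the reweighting spreads the penalty's spectrum over
    ~1/irls_epsilon, which unpreconditioned CG cannot absorb within the
    iteration budget, and a plain Jacobi diagonal over-damps the penalty's
    null space).
    """
    enc, m, scale, sqrt_l = _normalized_problem(kspace, coils, trajectory,
                                                encoding)
    F = kspace.n_frames
    N = coils.sensitivities.shape[-1]
    m_norm = np.linalg.norm(m)
    fe0 = enc.op(0)
    # exact diagonal of E'WE: density-weight total times coil power
    rss2 = np.sum(np.abs(fe0.coils) ** 2, axis=0)
    d0 = float(np.sum(fe0.dcf)) * rss2 / (sqrt_l**2)

    def e_normal(s):
        return enc.normal_w(s) / (sqrt_l**2)

    rhs = enc.adjoint_w(m) / sqrt_l
    s = np.zeros((F, N, N), dtype=complex)
    total_iter = 0
    objective, residuals = [], []
    converged = False
    first = True
    while total_iter < config.max_iter:
        if lam_eff > 0:
            weights = reweight(None if first else penalty(s))
            first = False
            precond = make_precond(weights, d0, lam_eff)

            def apply_a(x):
                return e_normal(x) + (lam_eff / 2.0) * penalty_adj(
                    weights * penalty(x))
        else:
            def apply_a(x):
                return e_normal(x)

            def precond(x):
                return x / d0[None]
        s, n_done = _cg(apply_a, rhs, s, min(config.inner_cg_iter,
                                             config.max_iter - total_iter),
                        precond=precond)
        total_iter += max(n_done, 1)
        rk = enc.forward(s) / sqrt_l - m
        res = np.linalg.norm(rk) / m_norm
        residuals.append(float(res))
        obj = (np.sum(fe0.dcf * np.abs(rk) ** 2)
               + lam_eff * penalty_norm(penalty(s)))
        objective.append(float(obj))
        if res < config.tol:
            converged = True
            break
        if lam_eff == 0 and n_done < config.inner_cg_iter:
            converged = True
            break
    out = s * (scale / sqrt_l)
    prov = {"solver": tag, "lambda": config.lam, "iterations": total_iter,
            "converged": converged, "objective": objective,
            "kspace_residual": residuals,
            "normalization": {"mean_abs_m": scale, "op_norm": sqrt_l**2}}
    return ImageSeries(frames=out, provenance=prov)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

#: map the published regularization weights onto the internal normalization
#: (unit-spectral-norm weighted encoding, unit-mean data); the grouped MOCCO
#: penalty and the elementwise TV penalty live on different scales.  Fixed
#: once for all experiments.
MOCCO_LAMBDA_SCALE = 1e-3
CSTV_LAMBDA_SCALE = 0.3


def mocco_reconstruct(kspace: KSpaceSeries, coils: CoilMaps,
                      trajectory: RadialTrajectory, basis: TemporalBasis,
                      config: ReconConfig = MOCCO_DEFAULT,
                      encoding: EncodingSeries | None = None) -> ImageSeries:
    """Model-consistency-condition reconstruction.

    Minimizes data consistency plus an l1 penalty on the part of the image
    series outside the temporal model,
    ``||W^1/2 (E s - m)||_2^2 + lam * sum_x ||((I - B B*) s)_x||_2``:
    the temporal-model residual is grouped per voxel (l2 across time, l1
    across voxels), so voxels whose dynamics genuinely depart from the
    model are released as coherent outliers while incoherent undersampling
    jitter stays suppressed.  The solution is full rank: the model steers
    but does not confine it.
    """
    if basis.n_frames != kspace.n_frames:
        raise ValueError("basis and k-space frame counts disagree")
    eps_frac = config.irls_epsilon

    def reweight(r):
        if r is None:
            return np.ones((1, 1, 1))
        gnorm = np.sqrt(np.sum(np.abs(r) ** 2, axis=0))
        nz = gnorm[gnorm > 0]
        eps = max(eps_frac * (np.median(nz) if nz.size else 1.0), 1e-30)
        return (1.0 / np.maximum(gnorm, eps))[None]

    def make_precond(w, d0, lam_eff):
        # per voxel the penalty Hessian is (lam/2) w_x (I - B B*): exactly
        # invertible by splitting along / off the model span
        def precond(x):
            span = basis.project(x)
            offs = x - span
            return span / d0[None] + offs / (d0[None] + (lam_eff / 2.0) * w)

        return precond

    def pnorm(r):
        return float(np.sum(np.sqrt(np.sum(np.abs(r) ** 2, axis=0))))

    return _irls_solve(kspace, coils, trajectory, config,
                       lam_eff=config.lam * MOCCO_LAMBDA_SCALE,
                       penalty=basis.residual, penalty_adj=basis.residual,
                       reweight=reweight, make_precond=make_precond,
                       penalty_norm=pnorm, encoding=encoding,
                       tag=f"MOCCO-{basis.origin}")


def cstv_reconstruct(kspace: KSpaceSeries, coils: CoilMaps,
                     trajectory: RadialTrajectory,
                     config: ReconConfig = CSTV_DEFAULT,
                     encoding: EncodingSeries | None = None) -> ImageSeries:
    """Compressed sensing with first-order temporal total variation."""
    if kspace.n_frames < 2:
        raise ValueError("temporal TV needs at least two frames")

    F = kspace.n_frames
    eps_frac = config.irls_epsilon

    def diff(s):
        return s[1:] - s[:-1]

    def diff_adj(r):
        out = np.zeros((r.shape[0] + 1,) + r.shape[1:], dtype=complex)
        out[:-1] -= r
        out[1:] += r
        return out

    def reweight(r):
        if r is None:
            return np.ones((F - 1, 1, 1))
        absr = np.abs(r)
        nz = absr[absr > 0]
        eps = max(eps_frac * (np.median(nz) if nz.size else 1.0), 1e-30)
        return 1.0 / np.maximum(absr, eps)

    # DCT-II eigenvalues of the temporal second-difference operator D'D
    tv_eigs = 2.0 - 2.0 * np.cos(np.pi * np.arange(F) / F)

    def make_precond(w, d0, lam_eff):
        # approximate the per-voxel penalty Hessian by its mean weight and
        # diagonalize the difference operator in the temporal DCT domain,
        # which keeps the (unpenalized) constant mode undamped
        from scipy.fft import dct, idct

        w_mean = np.mean(w, axis=0)
        denom = d0[None] + (lam_eff / 2.0) * w_mean[None] * \
            tv_eigs[:, None, None]

        def precond(x):
            spec = dct(x.real, axis=0, norm="ortho") + 1j * dct(
                x.imag, axis=0, norm="ortho")
            spec /= denom
            return idct(spec.real, axis=0, norm="ortho") + 1j * idct(
                spec.imag, axis=0, norm="ortho")

        return precond

    def pnorm(r):
        return float(np.sum(np.abs(r)))

    return _irls_solve(kspace, coils, trajectory, config,
                       lam_eff=config.lam * CSTV_LAMBDA_SCALE,
                       penalty=diff, penalty_adj=diff_adj, reweight=reweight,
                       make_precond=make_precond, penalty_norm=pnorm,
                       encoding=encoding, tag="CS-TV")


def pcb_reconstruct(kspace: KSpaceSeries, coils: CoilMaps,
                    trajectory: RadialTrajectory, basis: TemporalBasis,
                    config: ReconConfig = ReconConfig(lam=0.0),
                    encoding: EncodingSeries | None = None
                    ) -> tuple[ImageSeries, SpatialCoefficients]:
    """Subspace (principal-component-basis) reconstruction.

    Solves the quadratic problem for the K spatial coefficient maps by
    conjugate gradients and expands ``s = B c``; every voxel curve of the
    output lies exactly in the span of the basis.
    """
    if basis.n_frames != kspace.n_frames:
        raise ValueError("basis and k-space frame counts disagree")
    enc, m, scale, sqrt_l = _normalized_problem(kspace, coils, trajectory,
                                                encoding)
    F = kspace.n_frames
    N = coils.sensitivities.shape[-1]
    K = basis.rank
    B = basis.basis

    def expand(c):
        return (B @ c.reshape(K, -1)).reshape(F, N, N)

    def contract(s):
        return (B.conj().T @ s.reshape(F, -1)).reshape(K, N, N)

    def apply_a(c):
        return contract(enc.normal_w(expand(c))) / (sqrt_l**2)

    rhs = contract(enc.adjoint_w(m)) / sqrt_l
    c0 = np.zeros((K, N, N), dtype=complex)
    c, n_done = _cg(apply_a, rhs, c0, config.max_iter, rtol=config.tol)
    s = expand(c)
    res = float(np.linalg.norm(enc.forward(s) / sqrt_l - m) / np.linalg.norm(m))
    out = s * (scale / sqrt_l)
    prov = {"solver": f"PCB-{basis.origin}", "rank": K, "iterations": n_done,
            "converged": n_done < config.max_iter, "kspace_residual": [res]}
    return (ImageSeries(frames=out, provenance=prov),
            SpatialCoefficients(coeffs=c * (scale / sqrt_l)))


def sense_reference(kspace: KSpaceSeries, coils: CoilMaps,
                    trajectory: RadialTrajectory, max_iter: int = 30,
                    tol: float = 1e-9,
                    encoding: EncodingSeries | None = None) -> ImageSeries:
    """Per-frame unregularized iterative SENSE (conjugate gradients).

    Intended for fully-sampled data, where it serves as the reference arm;
    operators are built frame by frame and discarded (fully-sampled frames
    are too large to cache).
    """
    enc = encoding or EncodingSeries(coils, trajectory, cache=False)
    F = kspace.n_frames
    N = coils.sensitivities.shape[-1]
    out = np.empty((F, N, N), dtype=complex)
    iters = []
    for f in range(F):
        fe = enc.op(f)
        rhs = fe.adjoint_w(kspace.samples[f])
        x, n_done = _cg(fe.normal_w, rhs, rhs.copy(), max_iter, rtol=tol)
        out[f] = x
        iters.append(n_done)
    prov = {"solver": "SENSE", "iterations": iters, "converged": True}
    return ImageSeries(frames=out, provenance=prov)
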