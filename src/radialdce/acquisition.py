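"""Golden-angle radial multi-coil k-space simulation.

Turns the dynamic phantom into frame-binned radial k-space: trajectory
generation, smooth synthetic coil sensitivities, NUFFT sampling through the
same encoding operator later used by the solvers, and calibrated complex
Gaussian noise injection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nufft import GriddingNufft2D
from .phantom import GOLDEN_ANGLE, DynamicPhantom


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialTrajectory:
    """Golden-angle radial sampling pattern binned into frames.

    ``angles`` holds one angle per projection (radians, modulo pi);
    ``readout`` the normalized radii along a spoke in cycles/pixel;
    ``frame_index`` assigns projections to frames in acquisition order.
    """

    angles: np.ndarray
    readout: np.ndarray
    frame_index: np.ndarray

    @property
    def n_projections(self) -> int:
        return self.angles.size

    @property
    def n_readout(self) -> int:
        return self.readout.size

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.max()) + 1

    @property
    def projections_per_frame(self) -> int:
        return self.n_projections // self.n_frames

    def frame_angles(self, frame: int) -> np.ndarray:
        return self.angles[self.frame_index == frame]

    def frame_coords(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(kx, ky) of all samples of one frame, flattened spoke-major."""
        ang = self.frame_angles(frame)
        kx = np.outer(np.cos(ang), self.readout).ravel()
        ky = np.outer(np.sin(ang), self.readout).ravel()
        return kx, ky

    def frame_radii(self, frame: int) -> np.ndarray:
        ang = self.frame_angles(frame)
        return np.broadcast_to(self.readout, (ang.size, self.n_readout)).ravel()


def golden_angle_trajectory(n_projections: int, n_readout: int,
                            projections_per_frame: int) -> RadialTrajectory:
    """Continuous golden-angle spoke ordering binned into equal frames."""
    if n_projections % projections_per_frame:
        raise ValueError("n_projections must be divisible by projections_per_frame")
    angles = np.mod(np.arange(n_projections) * GOLDEN_ANGLE, np.pi)
    # radii span [-0.5, 0.5) cycles/pixel; n_readout = 2*matrix gives the
    # standard 2x readout oversampling along the spoke
    readout = (np.arange(n_readout) - n_readout // 2) / n_readout
    frame_index = np.arange(n_projections) // projections_per_frame
    return RadialTrajectory(angles, readout, frame_index)


def density_weights(trajectory: RadialTrajectory, frame: int) -> np.ndarray:
    """Ramp (|k|) density compensation with a small DC plateau.

    Scaled as the polar area element |k| dk dtheta so that the weighted
    adjoint approximates the inverse transform on well-sampled data.  Used
    only for gridding references and solver initialization.
    """
    r = np.abs(trajectory.frame_radii(frame))
    p = trajectory.frame_angles(frame).size
    dk = 1.0 / trajectory.n_readout
    return np.maximum(r, dk / 4) * dk * np.pi / p


# ---------------------------------------------------------------------------
# coil maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoilMaps:
    """Complex coil sensitivities, unit root-sum-of-squares inside support."""

    sensitivities: np.ndarray   # (n_coils, N, N)
    support: np.ndarray         # boolean (N, N)

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]


def simulate_coil_maps(n_coils: int = 16, matrix: int = 192, seed: int = 0,
                       support: np.ndarray | None = None) -> CoilMaps:
    """Smooth loop-like sensitivities from coil centers ringing the object.

    Gaussian magnitude bumps centered outside the support with a gentle,
    coil-specific linear phase; the stack is normalized to unit
    root-sum-of-squares at every voxel (exactly 1 inside the support).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    N = matrix
    yy, xx = np.meshgrid(np.arange(N) - N // 2, np.arange(N) - N // 2,
                         indexing="ij")
    if support is None:
        support = xx**2 + yy**2 <= (0.48 * N) ** 2
    maps = np.empty((n_coils, N, N), dtype=complex)
    ring = 0.65 * N
    width = 0.6 * N
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cx, cy = ring * np.cos(ang), ring * np.sin(ang)
        mag = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2)))
        gx, gy = rng.uniform(-1.5, 1.5, 2) / N
        phase = 2 * np.pi * (gx * xx + gy * yy) + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    rss = np.maximum(rss, 1e-12)
    maps /= rss
    return CoilMaps(sensitivities=maps, support=support)


# ---------------------------------------------------------------------------
# encoding operator and k-space sampling
# ---------------------------------------------------------------------------

class FrameEncoding:
    """Encoding operator E of one frame: coil weighting + NUFFT."""

    def __init__(self, coils: CoilMaps, trajectory: RadialTrajectory,
                 frame: int, oversamp: float = 2.0, width: int = 8):
        kx, ky = trajectory.frame_coords(frame)
        self.nufft = GriddingNufft2D(coils.sensitivities.shape[-1], kx, ky,
                                     oversamp=oversamp, width=width)
        self.coils = coils.sensitivities
        self.dcf = density_weights(trajectory, frame)
        self.n_samples = kx.size

    def forward(self, image: np.ndarray) -> np.ndarray:
        """image (N, N) -> samples (n_coils, n_samples)."""
        return self.nufft.forward(self.coils * image[None])

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        imgs = self.nufft.adjoint(samples)
        return np.sum(np.conj(self.coils) * imgs, axis=0)

    def gridded(self, samples: np.ndarray) -> np.ndarray:
        """Density-compensated adjoint (gridding reconstruction)."""
        imgs = self.nufft.adjoint(samples, weights=self.dcf)
        return np.sum(np.conj(self.coils) * imgs, axis=0)

    def adjoint_w(self, samples: np.ndarray) -> np.ndarray:
        """Adjoint of the density-weighted data term: E* W samples."""
        return self.gridded(samples)

    def normal_w(self, image: np.ndarray) -> np.ndarray:
        """Weighted normal operator E* W E (W = ramp density weights).

        The weighting flattens the radial sampling-density spectrum, so
        conjugate gradients on this operator converge in tens rather than
        hundreds of iterations.
        """
        return self.adjoint_w(self.forward(image))


class EncodingSeries:
    """Per-frame encoding operators for a whole dynamic acquisition.

    Operators are built lazily; with ``cache=True`` (the default for
    undersampled data) they are retained for reuse across solver iterations.
    """

    def __init__(self, coils: CoilMaps, trajectory: RadialTrajectory,
                 oversamp: float = 2.0, width: int = 8, cache: bool = True):
        self.coils = coils
        self.trajectory = trajectory
        self.oversamp = oversamp
        self.width = width
        self.cache = cache
        self._ops: dict[int, FrameEncoding] = {}

    @property
    def n_frames(self) -> int:
        return self.trajectory.n_frames

    def op(self, frame: int) -> FrameEncoding:
        if frame in self._ops:
            return self._ops[frame]
        fe = FrameEncoding(self.coils, self.trajectory, frame,
                           self.oversamp, self.width)
        if self.cache:
            self._ops[frame] = fe
        return fe

    def forward(self, series: np.ndarray) -> np.ndarray:
        """series (n_frames, N, N) -> samples (n_frames, n_coils, n_samples)."""
        return np.stack([self.op(f).forward(series[f])
                         for f in range(self.n_frames)])

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        return np.stack([self.op(f).adjoint(samples[f])
                         for f in range(self.n_frames)])

    def adjoint_w(self, samples: np.ndarray) -> np.ndarray:
        return np.stack([self.op(f).adjoint_w(samples[f])
                         for f in range(self.n_frames)])

    def normal(self, series: np.ndarray) -> np.ndarray:
        out = np.empty_like(series)
        for f in range(self.n_frames):
            fe = self.op(f)
            out[f] = fe.adjoint(fe.forward(series[f]))
        return out

    def normal_w(self, series: np.ndarray) -> np.ndarray:
        out = np.empty_like(series)
        for f in range(self.n_frames):
            out[f] = self.op(f).normal_w(series[f])
        return out


@dataclass
class KSpaceSeries:
    """Frame-binned multi-coil radial samples (the measured data m)."""

    samples: np.ndarray          # (n_frames, n_coils, samples_per_frame)
    trajectory: RadialTrajectory
    noise_sigma: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]


def sample_kspace(phantom: DynamicPhantom, coils: CoilMaps,
                  trajectory: RadialTrajectory,
                  encoding: EncodingSeries | None = None) -> KSpaceSeries:
    """Sample each frame of the phantom through the encoding operator."""
    if phantom.n_frames != trajectory.n_frames:
        raise ValueError("phantom and trajectory frame counts disagree")
    enc = encoding or EncodingSeries(coils, trajectory)
    samples = enc.forward(phantom.truth_series)
    return KSpaceSeries(samples=samples, trajectory=trajectory)


def save_kspace(kspace: KSpaceSeries, path: str) -> None:
    """Persist a k-space series (samples + trajectory + noise level) as HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=kspace.samples)
        f.create_dataset("angles", data=kspace.trajectory.angles)
        f.create_dataset("radii", data=kspace.trajectory.readout)
        f.create_dataset("frame_index", data=kspace.trajectory.frame_index)
        f.attrs["noise_sigma"] = kspace.noise_sigma


def load_kspace(path: str) -> KSpaceSeries:
    import h5py

    with h5py.File(path, "r") as f:
        traj = RadialTrajectory(f["angles"][...], f["radii"][...],
                                f["frame_index"][...])
        return KSpaceSeries(samples=f["samples"][...], trajectory=traj,
                            noise_sigma=float(f.attrs["noise_sigma"]))


def add_complex_noise(kspace: KSpaceSeries, fraction: float,
                      seed: int = 0, sigma: float | None = None) -> KSpaceSeries:
    """Add i.i.d. complex Gaussian noise per channel.

    The complex standard deviation (sqrt(E|n|^2)) is ``fraction`` times the
    mean k-space magnitude over all samples, matching a noise level quoted
    as a percentage of the mean signal magnitude.  Passing ``sigma``
    overrides the fraction with an absolute standard deviation (used to
    noise-match a control arm).
    """
    if fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    if sigma is None:
        if fraction == 0:
            return kspace
        sigma = fraction * np.mean(np.abs(kspace.samples))
    elif sigma == 0:
        return kspace
    rng = np.random.default_rng(seed)
    shape = kspace.samples.shape
    noise = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    noise *= sigma / np.sqrt(2.0)
    return replace(kspace, samples=kspace.samples + noise,
                   noise_sigma=float(sigma))
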