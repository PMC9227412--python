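"""Dynamic digital reference object for breast DCE-MRI.

Builds a 2D breast-like phantom whose enhancing lesions follow the extended
Tofts model (ETM) driven by a population arterial input function, converted
to image intensity through the spoiled gradient-echo (SPGR) steady-state
signal equation.  The phantom carries its own ground truth (concentration
and complex signal time series), which downstream acquisition/reconstruction
stages try to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

GOLDEN_ANGLE = np.pi * (np.sqrt(5.0) - 1.0) / 2.0  # ~111.246 degrees


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueParameters:
    """Extended Tofts parameters of one tissue.

    ktrans is the plasma-to-EES transfer constant in 1/min, ve and vp are
    the EES and plasma volume fractions, t10 the native T1 in ms.
    """

    ktrans: float
    ve: float
    vp: float
    t10: float = 1444.0

    def __post_init__(self):
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")
        if not (0 <= self.ve <= 1 and 0 <= self.vp <= 1):
            raise ValueError("ve and vp must lie in [0, 1]")
        if self.ve + self.vp > 1:
            raise ValueError("ve + vp must not exceed 1")
        if self.t10 <= 0:
            raise ValueError("t10 must be positive")
        if self.ktrans > 0 and self.ve == 0:
            raise ValueError("ve = 0 with ktrans > 0 leaves kep undefined")


@dataclass(frozen=True)
class ScanProtocol:
    """SPGR acquisition parameters (times in ms, flip angle in degrees)."""

    tr: float = 4.7
    te: float = 2.4
    flip_angle: float = 30.0
    r1: float = 4.9            # contrast relaxivity, 1/(mM s)
    frame_duration: float = 5.0  # s
    n_frames: int = 128
    matrix: int = 192
    fov: float = 340.0 * 192 / 448  # mm; preserves the 0.75 mm pixel

    def __post_init__(self):
        if not (self.tr > self.te > 0):
            raise ValueError("need tr > te > 0")
        if not (0 < self.flip_angle < 90):
            raise ValueError("flip angle must be in (0, 90) degrees")

    @property
    def pixel_mm(self) -> float:
        return self.fov / self.matrix

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_duration

    @property
    def frame_times(self) -> np.ndarray:
        """Frame-center times in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration


@dataclass(frozen=True)
class AIFModel:
    """Arterial input function sampled on a fine time grid (seconds, mM)."""

    time_grid: np.ndarray
    cb: np.ndarray             # whole-blood concentration
    hematocrit: float
    bolus_arrival: float

    def __post_init__(self):
        if not (0 <= self.hematocrit < 1):
            raise ValueError("hematocrit must lie in [0, 1)")

    @property
    def cp(self) -> np.ndarray:
        """Plasma concentration Cp = Cb / (1 - Hct)."""
        return self.cb / (1.0 - self.hematocrit)


def population_aif(protocol: ScanProtocol,
                   bolus_arrival: float = 150.0,
                   hematocrit: float = 0.45,
                   dt: float = 1.0,
                   peak: float = 3.0,
                   peak_time: float = 12.0,
                   alpha: float = 3.0,
                   washout_amps: tuple[float, float] = (0.55, 0.25),
                   washout_rates: tuple[float, float] = (6.0e-3, 2.5e-4),
                   ramp: float = 15.0) -> AIFModel:
    """Population AIF: gamma-variate first pass plus biexponential washout.

    The first pass peaks ``peak_time`` seconds after bolus arrival at
    ``peak`` mM whole-blood concentration; the recirculation/washout tail is
    a sum of two exponentials switched on by a smooth ramp.  All shape
    parameters are exposed so alternative population forms can be swapped in.
    """
    if not (0 <= hematocrit < 1):
        raise ValueError("hematocrit must lie in [0, 1)")
    t = np.arange(0.0, protocol.duration + dt / 2, dt)
    tau = t - bolus_arrival
    cb = np.zeros_like(t)
    pos = tau > 0
    tp = tau[pos]
    first = peak * (tp / peak_time) ** alpha * np.exp(alpha * (1 - tp / peak_time))
    tail = (1 - np.exp(-tp / ramp)) * sum(
        a * np.exp(-m * tp) for a, m in zip(washout_amps, washout_rates))
    cb[pos] = first + tail
    return AIFModel(time_grid=t, cb=cb, hematocrit=hematocrit,
                    bolus_arrival=bolus_arrival)


# ---------------------------------------------------------------------------
# extended Tofts model and SPGR signal
# ---------------------------------------------------------------------------

def etm_concentration(pk: TissueParameters, aif: AIFModel,
                      time_grid: np.ndarray | None = None) -> np.ndarray:
    """Tissue concentration C_t(t) of the extended Tofts model, in mM.

    C_t = vp*Cp + ktrans * (Cp (*) exp(-kep t)) with kep = ktrans/ve.  The
    convolution is evaluated on the AIF grid with an exact exponential
    integrator for piecewise-linear Cp (no quadrature error beyond the
    linear interpolation of Cp), then sampled at ``time_grid`` if given.
    """
    cp = aif.cp
    t = aif.time_grid
    conc = pk.vp * cp
    if pk.ktrans > 0:
        dt = float(t[1] - t[0])
        kep = pk.ktrans / pk.ve / 60.0      # 1/s
        ktrans_s = pk.ktrans / 60.0         # 1/s
        a = kep * dt
        if a < 1e-12:
            # kep ~ 0: plain running integral of Cp
            integral = np.concatenate(([0.0], np.cumsum((cp[1:] + cp[:-1]) / 2 * dt)))
        else:
            e = np.exp(-a)
            f_prev = dt * (1 - (1 + a) * e) / a**2
            f_curr = dt * ((1 - e) / a - (1 - (1 + a) * e) / a**2)
            # I[n] = e*I[n-1] + f_curr*cp[n] + f_prev*cp[n-1]
            integral = lfilter([f_curr, f_prev], [1.0, -e], cp)
            integral -= f_curr * cp[0] * e ** np.arange(len(cp))  # I[0] = 0
        conc = conc + ktrans_s * integral
    conc = np.maximum(conc, 0.0)
    if time_grid is not None:
        conc = np.interp(time_grid, t, conc)
    return conc


def spgr_signal(conc: np.ndarray, t10: float, protocol: ScanProtocol,
                m0: float = 1.0) -> np.ndarray:
    """SPGR steady-state signal for concentration curve ``conc`` (mM)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    if t10 <= 0:
        raise ValueError("t10 must be positive")
    r1_t = 1000.0 / t10 + protocol.r1 * conc       # 1/s
    e1 = np.exp(-protocol.tr / 1000.0 * r1_t)
    alpha = np.deg2rad(protocol.flip_angle)
    return m0 * np.sin(alpha) * (1 - e1) / (1 - np.cos(alpha) * e1)


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

#: the nine lesion transfer constants of the default experiment grid (1/min)
DEFAULT_KTRANS_GRID = (0.01, 0.04, 0.1, 0.2, 0.3, 0.4, 0.8, 1.2, 1.5)


def default_lesions(ktrans_values=DEFAULT_KTRANS_GRID, ve: float = 0.3,
                    vp: float = 0.001, t10: float = 1444.0):
    return [TissueParameters(k, ve, vp, t10) for k in ktrans_values]


@dataclass(frozen=True)
class PhantomGeometry:
    """Spatial layout: elliptical breast support with round lesions."""

    matrix: int = 192
    breast_semiaxes: tuple[float, float] = (0.42, 0.36)  # fraction of matrix
    lesion_diameter_mm: float = 8.0
    lesion_ring_fraction: float = 0.55   # lesion centers on this fraction of the support
    edge_px: float = 1.5   # anti-aliased support edge width (pixels); keeps
    #                        the object's spectrum inside the radially sampled disk


@dataclass
class DynamicPhantom:
    """Ground-truth dynamic object: labels, parameter maps and time series."""

    label_map: np.ndarray          # 0 air, 1 fibroglandular, 2+i lesion i
    ktrans_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    t10_map: np.ndarray
    m0_map: np.ndarray
    truth_series: np.ndarray       # complex, (n_frames, N, N)
    truth_ctc: np.ndarray          # mM, (n_frames, N, N)
    lesions: list[TissueParameters]
    protocol: ScanProtocol
    aif: AIFModel
    geometry: PhantomGeometry
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.truth_series.shape[0]

    @property
    def matrix(self) -> int:
        return self.label_map.shape[0]

    @property
    def support(self) -> np.ndarray:
        return self.label_map > 0

    def lesion_mask(self, index: int) -> np.ndarray:
        """Boolean mask of lesion ``index`` (0-based)."""
        return self.label_map == 2 + index

    def lesion_ctc(self, index: int) -> np.ndarray:
        """Ground-truth concentration curve of lesion ``index`` at frame centers."""
        return etm_concentration(self.lesions[index], self.aif,
                                 self.protocol.frame_times)

    def lesion_signal(self, index: int) -> np.ndarray:
        pk = self.lesions[index]
        return spgr_signal(self.lesion_ctc(index), pk.t10, self.protocol)


def build_phantom(geometry: PhantomGeometry | None = None,
                  lesions: list[TissueParameters] | None = None,
                  protocol: ScanProtocol | None = None,
                  aif: AIFModel | None = None,
                  seed: int | None = None) -> DynamicPhantom:
    """Assemble the dynamic reference object.

    Each lesion is a homogeneous disk whose time curve is generated by
    :func:`etm_concentration` followed by :func:`spgr_signal`; the
    fibroglandular background is static.  Lesions are laid out on a ring
    inside the breast support and must not overlap.
    """
    protocol = protocol or ScanProtocol()
    geometry = geometry or PhantomGeometry(matrix=protocol.matrix)
    if geometry.matrix != protocol.matrix:
        raise ValueError("geometry and protocol matrix sizes disagree")
    lesions = default_lesions() if lesions is None else list(lesions)
    aif = aif or population_aif(protocol)

    N = geometry.matrix
    yy, xx = np.meshgrid(np.arange(N) - N // 2, np.arange(N) - N // 2,
                         indexing="ij")
    ax = geometry.breast_semiaxes[0] * N
    ay = geometry.breast_semiaxes[1] * N
    rho = np.sqrt((xx / ax) ** 2 + (yy / ay) ** 2)
    support = rho <= 1.0
    # smooth m0 rolloff at the support boundary (erf profile over edge_px)
    from scipy.special import erf

    m0_map = 0.5 * (1 + erf((1 - rho) * np.sqrt(ax * ay) / geometry.edge_px))

    label = np.where(support, 1, 0).astype(np.int32)
    radius_px = geometry.lesion_diameter_mm / 2 / protocol.pixel_mm
    centers = _lesion_centers(len(lesions), geometry, N)
    masks = []
    for i, (cx, cy) in enumerate(centers):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
        if not disk.any():
            raise ValueError("lesion disk smaller than one pixel")
        if np.any(label[disk] >= 2):
            raise ValueError("lesion disks overlap")
        if not support[disk].all() or m0_map[disk].min() < 0.999:
            raise ValueError("lesion extends outside the breast support interior")
        label[disk] = 2 + i
        masks.append(disk)

    ktrans_map = np.zeros((N, N))
    ve_map = np.zeros((N, N))
    vp_map = np.zeros((N, N))
    t10_map = np.where(support, 1444.0, 0.0)
    for pk, disk in zip(lesions, masks):
        ktrans_map[disk] = pk.ktrans
        ve_map[disk] = pk.ve
        vp_map[disk] = pk.vp
        t10_map[disk] = pk.t10

    frame_times = protocol.frame_times
    n_frames = protocol.n_frames
    truth_ctc = np.zeros((n_frames, N, N))
    truth_series = np.zeros((n_frames, N, N), dtype=complex)
    # static tissue: constant baseline signal scaled by the smooth m0
    base = spgr_signal(np.zeros(1), 1444.0, protocol)[0]
    truth_series += base * m0_map
    for pk, disk in zip(lesions, masks):
        ctc = etm_concentration(pk, aif, frame_times)
        sig = spgr_signal(ctc, pk.t10, protocol)
        # lesion disks lie in the support interior where m0 = 1
        truth_series[:, disk] = sig[:, None]
        truth_ctc[:, disk] = ctc[:, None]
    return DynamicPhantom(label, ktrans_map, ve_map, vp_map, t10_map, m0_map,
                          truth_series, truth_ctc, lesions, protocol, aif,
                          geometry, seed)


def _lesion_centers(n: int, geometry: PhantomGeometry, N: int):
    """Place ``n`` lesion centers evenly on a ring inside the support."""
    if n == 0:
        return []
    ax = geometry.breast_semiaxes[0] * N * geometry.lesion_ring_fraction
    ay = geometry.breast_semiaxes[1] * N * geometry.lesion_ring_fraction
    if n == 1:
        return [(0.0, 0.0)]
    ang = 2 * np.pi * np.arange(n) / n
    return [(ax * np.cos(a), ay * np.sin(a)) for a in ang]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_phantom(phantom: DynamicPhantom, path: str) -> None:
    """Persist phantom maps and truth series (HDF5 + NIfTI + JSON sidecar)."""
    import os

    import h5py
    import nibabel as nib

    os.makedirs(path, exist_ok=True)
    with h5py.File(os.path.join(path, "phantom.h5"), "w") as f:
        f.create_dataset("truth_series", data=phantom.truth_series)
        f.create_dataset("truth_ctc", data=phantom.truth_ctc)
    affine = np.diag([phantom.protocol.pixel_mm] * 2 + [1.0, 1.0])
    for name in ("label_map", "ktrans_map", "ve_map", "vp_map", "t10_map", "m0_map"):
        arr = getattr(phantom, name).astype(np.float32)
        nib.save(nib.Nifti1Image(arr, affine), os.path.join(path, f"{name}.nii"))
    mag = np.abs(phantom.truth_series).transpose(1, 2, 0).astype(np.float32)
    nib.save(nib.Nifti1Image(mag, affine), os.path.join(path, "truth_magnitude.nii"))
    sidecar = {
        "protocol": dataclasses.asdict(phantom.protocol),
        "geometry": dataclasses.asdict(phantom.geometry),
        "lesions": [dataclasses.asdict(p) for p in phantom.lesions],
        "aif": {"hematocrit": phantom.aif.hematocrit,
                "bolus_arrival": phantom.aif.bolus_arrival},
        "seed": phantom.seed,
    }
    with open(os.path.join(path, "phantom.json"), "w") as f:
        json.dump(sidecar, f, indent=2)
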