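"""Pharmacokinetic analysis of reconstructed image series.

Converts SPGR magnitude series to concentration-time curves, fits the
extended Tofts model voxel-wise with bounded damped least squares, and
summarizes accuracy as percent-error maps, Bland-Altman tables and
Monte-Carlo statistics over noise realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .acquisition import add_complex_noise
from .phantom import AIFModel, DynamicPhantom, ScanProtocol, TissueParameters
from .recon import ImageSeries


# ---------------------------------------------------------------------------
# signal -> concentration
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationSeries:
    """Voxel-wise concentration curves with conversion diagnostics."""

    conc: np.ndarray            # (n_frames, ...) mM, clipped at 0
    clipped: int                # number of samples clipped to zero
    invalid: np.ndarray         # boolean mask of voxels with unphysical E1


def signal_to_concentration(series: ImageSeries | np.ndarray,
                            baseline_frames: int,
                            t10: float | np.ndarray,
                            protocol: ScanProtocol) -> ConcentrationSeries:
    """Invert the SPGR signal equation using a baseline-derived S0.

    S0 is the mean magnitude over the first ``baseline_frames`` frames; the
    ratio S/S0 determines E1 analytically, R1(t) = -ln(E1)/TR, and
    C = (R1 - 1/T10)/r1.  Voxels where the E1 solution leaves (0, 1) at any
    frame are flagged invalid; negative concentrations are clipped to zero
    and counted.
    """
    frames = series.frames if isinstance(series, ImageSeries) else series
    mag = np.abs(frames)
    if baseline_frames < 1 or baseline_frames > mag.shape[0]:
        raise ValueError("baseline_frames must be within the series")
    s0 = mag[:baseline_frames].mean(axis=0)
    alpha = np.deg2rad(protocol.flip_angle)
    tr_s = protocol.tr / 1000.0
    r10 = 1000.0 / np.asarray(t10, dtype=float)
    e10 = np.exp(-tr_s * r10)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mag / s0
        a = ratio * (1 - e10) / (1 - np.cos(alpha) * e10)
        e1 = (1 - a) / (1 - np.cos(alpha) * a)
        bad = ~np.isfinite(e1) | (e1 <= 0) | (e1 >= 1)
        e1 = np.where(bad, e10, e1)
        r1 = -np.log(e1) / tr_s
        conc = (r1 - r10) / protocol.r1
    invalid = bad.any(axis=0) | ~np.isfinite(s0) | (s0 <= 0)
    clipped = int(np.sum(conc < 0))
    conc = np.maximum(conc, 0.0)
    conc[:, invalid] = 0.0
    return ConcentrationSeries(conc=conc, clipped=clipped, invalid=invalid)


# ---------------------------------------------------------------------------
# extended Tofts fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Bounded damped-least-squares settings for the ETM fit.

    Bounds of [0, 1] apply to all three parameters with ktrans expressed in
    1/s (so the physiological range up to 1.5/min maps to 0.025).  Random
    multi-start initialization stabilizes the bounded fit.
    """

    xtol: float = 1e-6          # step tolerance
    ftol: float = 1e-8          # function tolerance
    n_restarts: int = 5
    bounds: tuple[float, float] = (0.0, 1.0)


@dataclass
class FitDiagnostics:
    converged: bool
    residual_norm: float
    n_evaluations: int


def _etm_eval_factory(aif: AIFModel, time_grid: np.ndarray):
    """Fast ETM forward model on the AIF grid, sampled at ``time_grid``."""
    cp = aif.cp
    t = aif.time_grid
    dt = float(t[1] - t[0])
    idx = np.clip(np.searchsorted(t, time_grid) - 1, 0, t.size - 2)
    frac = (time_grid - t[idx]) / dt
    powers = np.arange(t.size)

    def model(ktrans_s: float, ve: float, vp: float) -> np.ndarray:
        conc = vp * cp
        if ktrans_s > 0:
            kep = ktrans_s / max(ve, 1e-8)
            a = kep * dt
            if a < 1e-12:
                integral = np.concatenate(
                    ([0.0], np.cumsum((cp[1:] + cp[:-1]) / 2 * dt)))
            else:
                e = np.exp(-a)
                f_prev = dt * (1 - (1 + a) * e) / a**2
                f_curr = dt * ((1 - e) / a - (1 - (1 + a) * e) / a**2)
                integral = lfilter([f_curr, f_prev], [1.0, -e], cp)
                integral -= f_curr * cp[0] * e**powers
            conc = conc + ktrans_s * integral
        return conc[idx] * (1 - frac) + conc[idx + 1] * frac

    return model


def fit_etm(ctc: np.ndarray, aif: AIFModel, time_grid: np.ndarray,
            config: FitConfig = FitConfig(), seed: int = 0
            ) -> tuple[TissueParameters, FitDiagnostics]:
    """Fit the extended Tofts model to one concentration curve.

    Multi-start bounded Levenberg-Marquardt-type (trust-region) fit with the
    best residual kept; returns the parameters (ktrans back in 1/min) and
    convergence diagnostics.  An all-zero curve short-circuits to zeros.
    """
    ctc = np.asarray(ctc, dtype=float)
    if np.max(np.abs(ctc)) < 1e-12:
        return (TissueParameters(0.0, 1e-6, 0.0),
                FitDiagnostics(converged=True, residual_norm=0.0,
                               n_evaluations=0))
    model = _etm_eval_factory(aif, time_grid)

    def resid(x):
        return model(x[0], x[1], x[2]) - ctc

    rng = np.random.default_rng(seed)
    lo, hi = config.bounds
    best = None
    n_eval = 0
    for _ in range(config.n_restarts):
        # ktrans initial draw in (1/min)/60 keeps starts physiological
        x0 = np.array([rng.uniform(lo, hi) / 60.0,
                       rng.uniform(lo, hi),
                       rng.uniform(lo, hi)])
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=config.xtol, ftol=config.ftol)
        except Exception:
            continue
        n_eval += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return (TissueParameters(0.0, 1e-6, 0.0),
                FitDiagnostics(converged=False, residual_norm=float("nan"),
                               n_evaluations=n_eval))
    k, ve, vp = best.x
    ve = max(ve, 1e-8)
    # the fit bounds each parameter in [0, 1] separately; fold vp back into
    # the physical simplex (ve and ktrans statistics are unaffected)
    vp = min(vp, 1.0 - ve)
    params = TissueParameters(ktrans=k * 60.0, ve=ve, vp=vp)
    diag = FitDiagnostics(converged=bool(best.success),
                          residual_norm=float(np.sqrt(2 * best.cost)),
                          n_evaluations=n_eval)
    return params, diag


@dataclass
class FitResult:
    """Voxel-wise fitted parameter maps (ktrans in 1/min)."""

    ktrans_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    converged: np.ndarray       # boolean per voxel
    residual_norm: np.ndarray
    mask: np.ndarray            # voxels that were fitted
    label: str = ""


def fit_image(conc: ConcentrationSeries, aif: AIFModel,
              time_grid: np.ndarray, mask: np.ndarray,
              config: FitConfig = FitConfig(), seed: int = 0,
              label: str = "") -> FitResult:
    """Fit the ETM at every voxel of ``mask``; flagged voxels are skipped."""
    shape = mask.shape
    ktrans = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    resid = np.full(shape, np.nan)
    fit_mask = mask & ~conc.invalid
    coords = np.argwhere(fit_mask)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(coords))
    for (iy, ix), s in zip(coords, seeds):
        params, diag = fit_etm(conc.conc[:, iy, ix], aif, time_grid,
                               config, seed=int(s))
        ktrans[iy, ix] = params.ktrans
        ve[iy, ix] = params.ve
        vp[iy, ix] = params.vp
        conv[iy, ix] = diag.converged
        resid[iy, ix] = diag.residual_norm
    return FitResult(ktrans, ve, vp, conv, resid, fit_mask, label)


# ---------------------------------------------------------------------------
# error summaries
# ---------------------------------------------------------------------------

@dataclass
class ErrorSummary:
    """Per-lesion percent-error statistics (100*(fit-truth)/truth)."""

    table: pd.DataFrame
    maps: dict
    noise_tag: str = "0%"


def percent_error_map(fit: FitResult, phantom: DynamicPhantom,
                      noise_tag: str = "0%") -> ErrorSummary:
    """Voxel-wise percent-error maps inside the lesion masks plus ROI stats.

    Voxels with zero truth or flagged fits are excluded (and counted).
    """
    maps = {}
    for name, fitted, truth in (
            ("ktrans", fit.ktrans_map, phantom.ktrans_map),
            ("ve", fit.ve_map, phantom.ve_map)):
        err = np.full(truth.shape, np.nan)
        ok = (truth > 0) & np.isfinite(fitted)
        err[ok] = 100.0 * (fitted[ok] - truth[ok]) / truth[ok]
        maps[name] = err
    rows = []
    for i, pk in enumerate(phantom.lesions):
        roi = phantom.lesion_mask(i)
        row = {"lesion": i, "ktrans_true": pk.ktrans, "ve_true": pk.ve,
               "n_voxels": int(roi.sum()),
               "n_excluded": int(np.sum(roi & ~np.isfinite(maps["ktrans"])))}
        for name in ("ktrans", "ve"):
            vals = maps[name][roi]
            vals = vals[np.isfinite(vals)]
            row[f"{name}_pct_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{name}_pct_std"] = float(np.std(vals)) if vals.size else np.nan
        rows.append(row)
    return ErrorSummary(table=pd.DataFrame(rows), maps=maps,
                        noise_tag=noise_tag)


def bland_altman(fits: dict[str, FitResult] | list[FitResult],
                 phantom: DynamicPhantom, band: float = 10.0
                 ) -> pd.DataFrame:
    """Per-lesion agreement table for Bland-Altman plots.

    One row per (reconstruction arm, lesion, parameter) with the ROI mean
    and standard deviation of the fitted value and its percent error; the
    ``band`` column carries the +/-10% reference lines.
    """
    if isinstance(fits, list):
        fits = {f.label or str(i): f for i, f in enumerate(fits)}
    rows = []
    for arm, fit in fits.items():
        summary = percent_error_map(fit, phantom)
        for _, r in summary.table.iterrows():
            for name in ("ktrans", "ve"):
                rows.append({
                    "arm": arm, "lesion": int(r["lesion"]),
                    "parameter": name, "truth": r[f"{name}_true"],
                    "pct_mean": r[f"{name}_pct_mean"],
                    "pct_std": r[f"{name}_pct_std"],
                    "band": band,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo noise study
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloSummary:
    """Pixel-wise statistics of fitted parameters across noise realizations."""

    mean: dict                  # parameter -> map
    std: dict
    pct_error_of_mean: dict
    mean_ctc: np.ndarray        # ROI-mean concentration curve per realization mean
    n_realizations: int
    seeds: list
    failures: int = 0


def monte_carlo_run(phantom: DynamicPhantom, kspace, recon_fn, roi: np.ndarray,
                    aif: AIFModel, protocol: ScanProtocol,
                    n_realizations: int = 30, noise_fraction: float = 0.2,
                    base_seed: int = 0, baseline_frames: int | None = None,
                    fit_config: FitConfig = FitConfig(),
                    sigma: float | None = None) -> MonteCarloSummary:
    """Repeat noise -> reconstruct -> convert -> fit and aggregate.

    ``recon_fn`` maps a noisy :class:`KSpaceSeries` to an
    :class:`~radialdce.recon.ImageSeries`; ``sigma`` overrides the noise
    level to match another arm's absolute noise standard deviation.
    Individual realization failures are recorded, not fatal.
    """
    if baseline_frames is None:
        baseline_frames = max(1, int(phantom.aif.bolus_arrival
                                     // protocol.frame_duration) - 1)
    rng = np.random.default_rng(base_seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_realizations)]
    maps = {"ktrans": [], "ve": [], "vp": []}
    ctcs = []
    failures = 0
    t10 = phantom.lesions[0].t10 if phantom.lesions else 1444.0
    for s in seeds:
        try:
            noisy = add_complex_noise(kspace, noise_fraction, seed=s,
                                      sigma=sigma)
            rec = recon_fn(noisy)
            conc = signal_to_concentration(rec, baseline_frames, t10, protocol)
            ctcs.append(conc.conc[:, roi].mean(axis=1))
            fit = fit_image(conc, aif, protocol.frame_times, roi,
                            fit_config, seed=s)
            maps["ktrans"].append(fit.ktrans_map)
            maps["ve"].append(fit.ve_map)
            maps["vp"].append(fit.vp_map)
        except Exception:
            failures += 1
    if not maps["ktrans"]:
        raise RuntimeError("all Monte-Carlo realizations failed")
    mean, std, pct = {}, {}, {}
    truth = {"ktrans": phantom.ktrans_map, "ve": phantom.ve_map,
             "vp": phantom.vp_map}
    import warnings

    for name, stack in maps.items():
        arr = np.stack(stack)
        with warnings.catch_warnings(), np.errstate(divide="ignore",
                                                    invalid="ignore"):
            # voxels outside the fitted mask are all-NaN by construction
            warnings.simplefilter("ignore", RuntimeWarning)
            mean[name] = np.nanmean(arr, axis=0)
            std[name] = np.nanstd(arr, axis=0)
            pct[name] = 100.0 * (mean[name] - truth[name]) / truth[name]
    return MonteCarloSummary(mean=mean, std=std, pct_error_of_mean=pct,
                             mean_ctc=np.mean(ctcs, axis=0),
                             n_realizations=len(maps["ktrans"]),
                             seeds=seeds, failures=failures)
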