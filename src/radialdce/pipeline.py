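"""Experiment orchestration: phantom -> k-space -> solvers -> PK -> report.

Reproduces the validation-study grid (kinetic conditions x reconstruction
arms x noise arms) at configurable scale, with deterministic seeding, a
file manifest with content hashes, and figure/table generation.  The
command-line entry point exposes the stages as verbs
(``simulate``/``reconstruct``/``fit``/``evaluate``/``report``/``all``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import click
import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from . import acquisition as acq
from . import recon as rc
from . import pk as pkmod


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Serializable description of one validation experiment grid.

    Each kinetic condition is simulated as its own single-lesion phantom
    (one lesion at a fixed location, its transfer constant swept over
    ``ktrans_values``), matching the study design the solvers are judged
    against.
    """

    name: str = "desk-small"
    # geometry / protocol
    matrix: int = 48
    fov: float = 340.0 * 48 / 448 * 2      # mm
    n_frames: int = 128
    frame_duration: float = 5.0
    tr: float = 4.7
    te: float = 2.4
    flip_angle: float = 30.0
    r1: float = 4.9
    t10: float = 1444.0
    bolus_arrival: float = 150.0
    hematocrit: float = 0.45
    lesion_diameter_mm: float = 8.0
    # kinetics
    ktrans_values: tuple = ph.DEFAULT_KTRANS_GRID
    ve: float = 0.3
    vp: float = 0.001
    # acquisition
    n_coils: int = 4
    projections_per_frame: int = 8
    full_projections_per_frame: int = 152
    # reconstruction
    solvers: tuple = ("reference", "mocco_hr", "pcb_hr", "mocco_lr",
                      "pcb_lr", "cstv")
    lambda_mocco: float = 10.0
    lambda_cstv: float = 2.0
    max_iter: int = 100
    sense_iter: int = 15
    irls_epsilon: float = 1e-2
    inner_cg_iter: int = 10
    lr_rank: int = 3
    lr_kmax: float = 0.1
    lr_knot_spacing: int = 12
    # analysis
    noise_fractions: tuple = (0.0,)
    fit_restarts: int = 5
    # bookkeeping
    seed: int = 0
    output_dir: str = "results"
    save_images: bool = False

    # -- derived objects ---------------------------------------------------
    def protocol(self) -> ph.ScanProtocol:
        return ph.ScanProtocol(tr=self.tr, te=self.te,
                               flip_angle=self.flip_angle, r1=self.r1,
                               frame_duration=self.frame_duration,
                               n_frames=self.n_frames, matrix=self.matrix,
                               fov=self.fov)

    def geometry(self) -> ph.PhantomGeometry:
        return ph.PhantomGeometry(matrix=self.matrix,
                                  lesion_diameter_mm=self.lesion_diameter_mm)

    def aif(self) -> ph.AIFModel:
        return ph.population_aif(self.protocol(),
                                 bolus_arrival=self.bolus_arrival,
                                 hematocrit=self.hematocrit)

    @property
    def baseline_frames(self) -> int:
        return max(1, int(self.bolus_arrival // self.frame_duration) - 1)

    def recon_config(self, lam: float) -> rc.ReconConfig:
        return rc.ReconConfig(lam=lam, max_iter=self.max_iter,
                              irls_epsilon=self.irls_epsilon,
                              inner_cg_iter=self.inner_cg_iter)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        for key in ("ktrans_values", "solvers", "noise_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


PRESETS = {
    "smoke": dict(name="smoke", matrix=32, fov=340 * 32 / 448 * 3,
                  n_frames=32, bolus_arrival=40.0, n_coils=2,
                  full_projections_per_frame=56, ktrans_values=(0.3,),
                  solvers=("reference", "mocco_lr"), max_iter=30,
                  sense_iter=10, fit_restarts=2, save_images=True),
    "desk-small": dict(name="desk-small"),
    "desk": dict(name="desk", matrix=192, fov=340 * 192 / 448, n_coils=8,
                 full_projections_per_frame=302),
    "full": dict(name="full", matrix=448, fov=340.0, n_coils=16,
                 full_projections_per_frame=704),
}


def preset(name: str, **overrides) -> ExperimentConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ExperimentConfig(**kwargs)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _condition_seed(config: ExperimentConfig, kt: float, noise: float) -> int:
    h = hashlib.sha256(f"{config.seed}|{kt}|{noise}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def build_condition(config: ExperimentConfig, kt: float):
    """Phantom + coil maps + trajectories for one kinetic condition."""
    protocol = config.protocol()
    aif = config.aif()
    lesion = ph.TissueParameters(kt, config.ve, config.vp, config.t10)
    phantom = ph.build_phantom(config.geometry(), [lesion], protocol, aif,
                               seed=config.seed)
    coils = acq.simulate_coil_maps(config.n_coils, config.matrix,
                                   seed=config.seed, support=phantom.support)
    n_read = 2 * config.matrix
    traj = acq.golden_angle_trajectory(
        config.projections_per_frame * config.n_frames, n_read,
        config.projections_per_frame)
    return phantom, coils, traj


def reconstruct_condition(config: ExperimentConfig, kt: float,
                          noise: float = 0.0) -> dict:
    """Run every requested solver for one (condition, noise) cell."""
    phantom, coils, traj = build_condition(config, kt)
    enc = acq.EncodingSeries(coils, traj)
    kspace = acq.sample_kspace(phantom, coils, traj, enc)
    if noise > 0:
        kspace = acq.add_complex_noise(
            kspace, noise, seed=_condition_seed(config, kt, noise))
    out = {"phantom": phantom, "coils": coils, "trajectory": traj,
           "kspace": kspace, "recons": {}, "failures": {}}
    lr_basis = hr_basis = None
    for solver in config.solvers:
        try:
            if solver == "reference":
                full = acq.golden_angle_trajectory(
                    config.full_projections_per_frame * config.n_frames,
                    2 * config.matrix, config.full_projections_per_frame)
                encf = acq.EncodingSeries(coils, full, cache=False)
                ksf = acq.sample_kspace(phantom, coils, full, encf)
                if noise > 0:
                    ksf = acq.add_complex_noise(
                        ksf, 0.0, seed=_condition_seed(config, kt, noise) + 1,
                        sigma=kspace.noise_sigma)
                rec = rc.sense_reference(ksf, coils, full,
                                         max_iter=config.sense_iter)
            elif solver in ("mocco_hr", "pcb_hr"):
                if hr_basis is None:
                    hr_basis = rc.build_hr_basis(
                        phantom.lesion_signal(0).astype(complex),
                        config.n_frames)
                if solver == "mocco_hr":
                    rec = rc.mocco_reconstruct(
                        kspace, coils, traj, hr_basis,
                        config.recon_config(config.lambda_mocco), encoding=enc)
                else:
                    rec, _ = rc.pcb_reconstruct(
                        kspace, coils, traj, hr_basis,
                        config.recon_config(0.0), encoding=enc)
            elif solver in ("mocco_lr", "pcb_lr"):
                if lr_basis is None:
                    lr_basis = rc.learn_lr_basis(
                        kspace, coils, rank=config.lr_rank,
                        kmax=config.lr_kmax,
                        knot_spacing=config.lr_knot_spacing,
                        seed=config.seed, encoding=enc)
                if solver == "mocco_lr":
                    rec = rc.mocco_reconstruct(
                        kspace, coils, traj, lr_basis,
                        config.recon_config(config.lambda_mocco), encoding=enc)
                else:
                    rec, _ = rc.pcb_reconstruct(
                        kspace, coils, traj, lr_basis,
                        config.recon_config(0.0), encoding=enc)
            elif solver == "cstv":
                rec = rc.cstv_reconstruct(
                    kspace, coils, traj,
                    config.recon_config(config.lambda_cstv), encoding=enc)
            else:
                raise ValueError(f"unknown solver {solver!r}")
            out["recons"][solver] = rec
        except Exception as exc:  # stage failures isolate to the cell
            out["failures"][solver] = repr(exc)
    return out


def fit_condition(config: ExperimentConfig, cell: dict, kt: float,
                  noise: float) -> list[dict]:
    """PK-fit every reconstruction of a cell over the lesion ROI."""
    phantom = cell["phantom"]
    protocol = config.protocol()
    aif = phantom.aif
    roi = phantom.lesion_mask(0)
    fit_cfg = pkmod.FitConfig(n_restarts=config.fit_restarts)
    rows = []
    for solver, rec in cell["recons"].items():
        conc = pkmod.signal_to_concentration(rec, config.baseline_frames,
                                             config.t10, protocol)
        fit = pkmod.fit_image(conc, aif, protocol.frame_times, roi, fit_cfg,
                              seed=_condition_seed(config, kt, noise),
                              label=solver)
        summary = pkmod.percent_error_map(fit, phantom,
                                          noise_tag=f"{noise:.0%}")
        r = summary.table.iloc[0]
        rows.append({
            "ktrans_true": kt, "noise": noise, "solver": solver,
            "ktrans_pct_mean": r["ktrans_pct_mean"],
            "ktrans_pct_std": r["ktrans_pct_std"],
            "ve_pct_mean": r["ve_pct_mean"],
            "ve_pct_std": r["ve_pct_std"],
            "n_voxels": r["n_voxels"], "n_excluded": r["n_excluded"],
        })
    for solver, err in cell["failures"].items():
        rows.append({"ktrans_true": kt, "noise": noise, "solver": solver,
                     "error": err})
    return rows


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full grid and write summaries + manifest to disk."""
    os.makedirs(config.output_dir, exist_ok=True)
    rows = []
    provenance = []
    for kt in config.ktrans_values:
        for noise in config.noise_fractions:
            cell = reconstruct_condition(config, kt, noise)
            rows.extend(fit_condition(config, cell, kt, noise))
            for solver, rec in cell["recons"].items():
                provenance.append({"ktrans_true": kt, "noise": noise,
                                   **rec.provenance})
            if config.save_images:
                import h5py

                path = os.path.join(config.output_dir,
                                    f"recon_kt{kt}_n{noise:.2f}.h5")
                with h5py.File(path, "w") as f:
                    for solver, rec in cell["recons"].items():
                        f.create_dataset(solver, data=rec.frames)
                    f.create_dataset("truth", data=cell["phantom"].truth_series)
    table = pd.DataFrame(rows)
    table_path = os.path.join(config.output_dir, "summary.csv")
    table.to_csv(table_path, index=False)
    wide = summary_to_wide(table)
    wide_path = os.path.join(config.output_dir, "table1_style.csv")
    wide.to_csv(wide_path)
    cfg_path = os.path.join(config.output_dir, "config.yaml")
    config.to_yaml(cfg_path)
    prov_path = os.path.join(config.output_dir, "solver_provenance.json")
    with open(prov_path, "w") as f:
        json.dump(provenance, f, indent=1, default=str)
    files = [table_path, wide_path, cfg_path, prov_path]
    files += [os.path.join(config.output_dir, p)
              for p in os.listdir(config.output_dir) if p.endswith(".h5")]
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": {os.path.basename(p): _sha256(p) for p in sorted(set(files))},
        "cells": int(len(config.ktrans_values) * len(config.noise_fractions)),
        "failed": [r for r in rows if "error" in r and pd.notna(r.get("error"))],
    }
    man_path = os.path.join(config.output_dir, "manifest.json")
    with open(man_path, "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def summary_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long summary into the conditions-by-arms error table."""
    ok = table[table.get("ktrans_pct_mean").notna()] if "ktrans_pct_mean" in table else table
    wide = ok.pivot_table(index="ktrans_true",
                          columns=["solver", "noise"],
                          values=["ktrans_pct_mean", "ve_pct_mean"])
    return wide.round(2)


def report(output_dir: str) -> list[str]:
    """Deterministic figures/tables from the stored summary arrays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    man_path = os.path.join(output_dir, "manifest.json")
    if not os.path.exists(man_path):
        raise FileNotFoundError("run the experiment before reporting")
    summary_path = os.path.join(output_dir, "summary.csv")
    table = pd.read_csv(summary_path)
    made = []
    if table.empty or "ktrans_pct_mean" not in table:
        print("warning: empty manifest/summary; nothing to report")
        return made
    # Bland-Altman style: percent error vs true ktrans, +/-10% band
    for noise, sub in table.groupby("noise"):
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
        for ax, param in zip(axes, ("ktrans", "ve")):
            for solver, ss in sub.groupby("solver"):
                ax.errorbar(ss["ktrans_true"], ss[f"{param}_pct_mean"],
                            yerr=ss[f"{param}_pct_std"], marker="o",
                            capsize=2, label=solver, lw=1)
            ax.axhline(10, ls="--", c="k", lw=0.8)
            ax.axhline(-10, ls="--", c="k", lw=0.8)
            ax.set_xscale("log")
            ax.set_xlabel("true Ktrans (1/min)")
            ax.set_ylabel(f"{param} error (%)")
        axes[0].legend(fontsize=7)
        fig.suptitle(f"Percent error vs truth ({noise:.0%} noise)")
        fig.tight_layout()
        out = os.path.join(output_dir, f"bland_altman_{noise:.2f}.png")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        made.append(out)
    # curve panels from any stored reconstruction stacks
    h5s = sorted(p for p in os.listdir(output_dir) if p.endswith(".h5"))
    if h5s:
        import h5py

        cfg = ExperimentConfig.from_yaml(os.path.join(output_dir, "config.yaml"))
        t = (np.arange(cfg.n_frames) + 0.5) * cfg.frame_duration
        win = (t >= 150) & (t <= 400)
        if not win.any():
            win = slice(None)
        fig, ax = plt.subplots(figsize=(6, 4))
        with h5py.File(os.path.join(output_dir, h5s[0])) as f:
            truth = np.abs(f["truth"][...])
            mid = truth.shape[-1] // 2
            for key in f:
                mean_curve = np.abs(f[key][...]).reshape(cfg.n_frames, -1).mean(axis=1)
                ax.plot(t[win], mean_curve[win], label=key,
                        lw=2 if key == "truth" else 1,
                        c="k" if key == "truth" else None)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mean |signal| (a.u.)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        out = os.path.join(output_dir, "curves.png")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        made.append(out)
    return made


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
def cli():
    """Radial DCE-MRI reconstruction validation pipeline."""


def _load_config(config_path, preset_name, seed, out):
    if config_path:
        cfg = ExperimentConfig.from_yaml(config_path)
    else:
        cfg = preset(preset_name)
    if seed is not None:
        cfg.seed = seed
    if out:
        cfg.output_dir = out
    return cfg


_opts = [
    click.option("--config", "config_path", type=click.Path(exists=True),
                 default=None, help="YAML experiment configuration"),
    click.option("--preset", "preset_name", default="smoke",
                 type=click.Choice(sorted(PRESETS))),
    click.option("--seed", type=int, default=None),
    click.option("--out", default=None, help="output directory"),
]


def _with_opts(cmd):
    for opt in reversed(_opts):
        cmd = opt(cmd)
    return cmd


@cli.command("simulate")
@_with_opts
def cli_simulate(config_path, preset_name, seed, out):
    """Build the phantom(s) and write ground truth to disk."""
    cfg = _load_config(config_path, preset_name, seed, out)
    os.makedirs(cfg.output_dir, exist_ok=True)
    for kt in cfg.ktrans_values:
        phantom, coils, traj = build_condition(cfg, kt)
        ph.save_phantom(phantom, os.path.join(cfg.output_dir, f"phantom_kt{kt}"))
        kspace = acq.sample_kspace(phantom, coils, traj)
        acq.save_kspace(kspace, os.path.join(cfg.output_dir,
                                             f"kspace_kt{kt}.h5"))
    click.echo(f"saved {len(cfg.ktrans_values)} phantom(s) + k-space to "
               f"{cfg.output_dir}")


@cli.command("all")
@_with_opts
def cli_all(config_path, preset_name, seed, out):
    """Run the full grid and generate the report."""
    cfg = _load_config(config_path, preset_name, seed, out)
    manifest = run_experiment(cfg)
    made = report(cfg.output_dir)
    click.echo(json.dumps({"manifest": manifest["config_hash"],
                           "figures": made}, indent=2))


@cli.command("reconstruct")
@_with_opts
def cli_reconstruct(config_path, preset_name, seed, out):
    """Run the solvers only (stores image stacks)."""
    cfg = _load_config(config_path, preset_name, seed, out)
    cfg.save_images = True
    run_experiment(cfg)
    click.echo(f"reconstructions in {cfg.output_dir}")


@cli.command("fit")
@_with_opts
def cli_fit(config_path, preset_name, seed, out):
    """Run the grid and write the PK summary tables."""
    cfg = _load_config(config_path, preset_name, seed, out)
    run_experiment(cfg)
    click.echo(f"summaries in {cfg.output_dir}")


@cli.command("evaluate")
@click.option("--out", default="results")
def cli_evaluate(out):
    """Re-derive the wide error table from a stored summary."""
    table = pd.read_csv(os.path.join(out, "summary.csv"))
    wide = summary_to_wide(table)
    path = os.path.join(out, "table1_style.csv")
    wide.to_csv(path)
    click.echo(path)


@cli.command("report")
@click.option("--out", default="results")
def cli_report(out):
    """Figures from stored results."""
    made = report(out)
    click.echo("\n".join(made) if made else "nothing to report")


if __name__ == "__main__":
    cli()
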