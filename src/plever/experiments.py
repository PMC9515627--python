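"""Orchestration of the package's four computational experiments.

Each experiment evaluates the analytical models over a parameter grid
and/or validates them against seeded simulations, returning a tidy
DataFrame and (optionally) writing a CSV whose header records the
configuration hash and seed, so every run is reproducible from its config
alone.  Default grid resolutions are coarser than publication density to
keep a full run to a few CPU-minutes; ``dense=True`` restores fine grids.

Experiments:

- ``run_model1_share_grid`` — expected leverage vs protein share under
  constant-variance and constant-dispersion regimes.
- ``run_model1_idr_grid``  — expected leverage vs share and the index-of-
  dispersion ratio (ID_V fixed at 125).
- ``run_model1_validation`` — analytic E(L) against OLS slopes fitted to
  bivariate normal and lognormal cohorts at every grid point.
- ``run_model2_idr`` — model-implied vs simulated IDR over the leverage
  generative grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import model1, model2
from .estimation import dispersion_summary, fit_leverage
from .ratio_distribution import Model1Params
from .simulate import simulate_bivariate_lognormal, simulate_bivariate_normal

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "run_model1_share_grid",
    "run_model1_idr_grid",
    "run_model1_validation",
    "run_model2_idr",
    "run_fig2",
    "run_fig3",
    "run_fig4_validation",
    "run_fig5_7",
    "EXPERIMENTS",
]


@dataclass
class ExperimentConfig:
    """Grids, sample sizes, seed and output location for one experiment."""

    name: str = ""
    share_grid: list[float] = field(default_factory=lambda: list(np.round(np.arange(0.05, 0.96, 0.05), 3)))
    idr_grid: list[float] = field(default_factory=lambda: list(np.round(np.arange(0.2, 1.81, 0.2), 3)))
    rho_grid: list[float] = field(default_factory=lambda: [0.0, 0.3, 0.6, 0.9])
    muW_grid: list[float] = field(default_factory=lambda: [0.15, 0.2, 0.3])
    sigmaW_grid: list[float] = field(default_factory=lambda: [0.03, 0.05, 0.07])
    L_grid: list[float] = field(default_factory=lambda: [-1.0, -0.7, -0.4, -0.1])
    totals: float = 8700.0
    sigma_const: float = 500.0
    id_const: float = 100.0
    id_V: float = 125.0
    sigma_eps2: float = model2.DEFAULT_SIGMA_EPS2
    n: int = 20_000
    seed: int = 1
    outdir: str | None = None
    dense: bool = False

    def __post_init__(self) -> None:
        for name in ("share_grid", "rho_grid", "muW_grid", "sigmaW_grid", "L_grid", "idr_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.dense:
            self.share_grid = list(np.round(np.arange(0.02, 0.99, 0.02), 3))
            self.idr_grid = list(np.round(np.arange(0.1, 1.91, 0.1), 3))
            self.L_grid = list(np.round(np.arange(-1.0, -0.049, 0.05), 3))

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # scientific content only, not disk layout
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def write(self, df: pd.DataFrame, filename: str) -> Path | None:
        if self.outdir is None:
            return None
        outdir = Path(self.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / filename
        with open(path, "w") as fh:
            fh.write(f"# experiment={self.name} config_sha256={self.digest()} seed={self.seed}\n")
            df.to_csv(fh, index=False)
        logger.info("wrote %s (%d rows)", path, len(df))
        return path


def _reduced(cfg: ExperimentConfig) -> ExperimentConfig:
    return cfg


def run_model1_share_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Expected leverage vs protein share under both variance regimes.

    Panel "constant_variance" holds sigma_U = sigma_V fixed; panel
    "constant_ID" holds the index of dispersion of both nutrients fixed.
    Totals are fixed (8700 kJ by default).
    """
    t0 = time.perf_counter()
    frames = []
    for mode in ("constant_variance", "constant_ID"):
        grid = model1.leverage_grid(
            config.share_grid,
            None,
            config.rho_grid,
            mode,
            totals=config.totals,
            sigma_const=config.sigma_const,
            id_const=config.id_const,
        )
        grid.insert(0, "mode", mode)
        frames.append(grid)
    out = pd.concat(frames, ignore_index=True)
    logger.info("model1 share grid: %d points in %.1fs", len(out), time.perf_counter() - t0)
    config.write(out, "model1_share_grid.csv")
    return out


def run_model1_idr_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Expected leverage vs share and ID_U/ID_V with ID_V fixed."""
    t0 = time.perf_counter()
    out = model1.leverage_grid(
        config.share_grid,
        config.idr_grid,
        config.rho_grid,
        "free_IDR",
        totals=config.totals,
        id_V=config.id_V,
    )
    flagged = out[out["flag"] != ""]
    if len(flagged):
        logger.warning("%d flagged grid points (log undefined)", len(flagged))
    logger.info("model1 idr grid: %d points in %.1fs", len(out), time.perf_counter() - t0)
    config.write(out, "model1_idr_grid.csv")
    return out


def run_model1_validation(config: ExperimentConfig) -> pd.DataFrame:
    """Analytic E(L) vs simulated OLS slope per grid point, both intake models.

    For each (share, idr, rho) point a cohort of ``config.n`` subjects is
    simulated from the bivariate normal and the bivariate lognormal intake
    models (the latter only at correlations attainable by the copula) and
    the leverage regression fitted; the paired values validate the
    analytical null.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    rows = []
    t0 = time.perf_counter()
    for share in config.share_grid:
        for idr in config.idr_grid:
            for rho in config.rho_grid:
                t_point = time.perf_counter()
                params = model1.params_from_share(
                    share, "free_IDR", rho_UV=rho, totals=config.totals,
                    id_V=config.id_V, idr=idr,
                )
                try:
                    analytic = model1.expected_leverage(params).expected_L
                except ValueError:
                    logger.warning("skipping flagged point share=%s idr=%s rho=%s", share, idr, rho)
                    continue
                seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(2)]
                normal = simulate_bivariate_normal(params, config.n, seeds[0])
                sim_normal = fit_leverage(normal).L_hat
                try:
                    lognormal = simulate_bivariate_lognormal(params, config.n, seeds[1])
                    sim_lognormal = fit_leverage(lognormal).L_hat
                except ValueError:
                    sim_lognormal = np.nan
                rows.append(
                    {
                        "protein_share": share,
                        "idr": idr,
                        "rho_uv": rho,
                        "expected_L": analytic,
                        "sim_L_normal": sim_normal,
                        "sim_L_lognormal": sim_lognormal,
                        "n": config.n,
                        "n_excluded_normal": normal.provenance["n_excluded"],
                    }
                )
                logger.debug(
                    "point share=%s idr=%s rho=%s done in %.2fs",
                    share, idr, rho, time.perf_counter() - t_point,
                )
    out = pd.DataFrame(rows)
    logger.info("model1 validation: %d points in %.1fs", len(out), time.perf_counter() - t0)
    config.write(out, "model1_validation.csv")
    return out


def run_model2_idr(config: ExperimentConfig) -> pd.DataFrame:
    """Model-implied and simulated IDR over the leverage generative grid."""
    t0 = time.perf_counter()
    out = model2.idr_grid(
        config.L_grid,
        config.sigmaW_grid,
        config.muW_grid,
        sigma_eps2=config.sigma_eps2,
        simulate_n=config.n,
        seed=config.seed,
    )
    logger.info("model2 idr grid: %d points in %.1fs", len(out), time.perf_counter() - t0)
    config.write(out, "model2_idr_grid.csv")
    return out


# aliases naming the four experiments by their role in the published-figure
# layout the defaults emulate
run_fig2 = run_model1_share_grid
run_fig3 = run_model1_idr_grid
run_fig4_validation = run_model1_validation
run_fig5_7 = run_model2_idr

EXPERIMENTS = {
    "fig2": run_model1_share_grid,
    "fig3": run_model1_idr_grid,
    "fig4": run_model1_validation,
    "fig5": run_model2_idr,
}


def plot_experiment(df: pd.DataFrame, name: str, outdir) -> Path:
    """Optional convenience plot (PNG) alongside an experiment's CSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    if name in ("fig2", "fig3"):
        for (mode_or_rho), sub in df.groupby(df.columns[0] if name == "fig2" else "rho_uv"):
            sub = sub[sub["flag"] == ""] if "flag" in sub else sub
            ax.plot(sub["protein_share"], sub["expected_L"], ".", label=str(mode_or_rho))
        ax.set_xlabel("protein share of energy")
        ax.set_ylabel("expected L")
    elif name == "fig4":
        ax.plot(df["expected_L"], df["sim_L_normal"], ".", label="normal")
        ax.plot(df["expected_L"], df["sim_L_lognormal"], ".", label="lognormal")
        lims = [df["expected_L"].min(), df["expected_L"].max()]
        ax.plot(lims, lims, "k-", lw=0.5)
        ax.set_xlabel("analytic E(L)")
        ax.set_ylabel("simulated L")
    else:
        for muw, sub in df.groupby("mu_W"):
            ax.plot(sub["L"], sub["idr_model"], ".-", label=f"mu_W={muw}")
        ax.set_xlabel("leverage strength L")
        ax.set_ylabel("IDR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = outdir / f"{name}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
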