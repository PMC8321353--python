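"""Camera-count sweeps, area-increment tables and decay fits.

The experimental protocol: run the reconstructable-subset computation for a
list of camera counts (default 2, 4, 6, 8, 16, 32, 64, 128, 256, 360) with
equidistant ring placement, normalize areas to the 360-camera benchmark
(360 cameras, one per degree, leave adjacent images overlapping almost
completely, so their reconstruction is the most complete one achievable on
the ring), tabulate the increments between consecutive counts, and fit the
saturation behaviour with an n-phase approach-to-plateau curve

    |Ar|(n) = c0 - sum_i a_i * exp(-b_i * n),    a_i, b_i > 0, n phases.

Increment percentages follow the convention delta / previous-row value.
The fits are descriptive (curve-shape characterization), not part of the
area computation itself.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .camera import make_ring_setup
from .errors import FitError
from .mesh_io import TriangleMesh
from .reconstruct import ReconConfig, ReconstructionResult, reconstructable_subset

__all__ = [
    "SweepTable",
    "DecayFit",
    "run_camera_sweep",
    "delta_areas",
    "fit_decay",
    "report",
    "PAPER_COUNTS",
]

PAPER_COUNTS = (2, 4, 6, 8, 16, 32, 64, 128, 256, 360)


@dataclasses.dataclass
class SweepTable:
    """Normalized reconstructable areas per camera count.

    ``table`` columns: n, Ar_mm2, Ar_mm2_excl_top, norm, norm_excl_top
    (norms relative to the benchmark count, including/excluding the
    top-surface region).  ``delta_areas`` adds increment columns.
    """

    table: pd.DataFrame
    mesh_id: str
    fov: tuple[float, float]
    T: int
    benchmark: int
    results: dict[int, ReconstructionResult] = dataclasses.field(
        default_factory=dict, repr=False
    )


def run_camera_sweep(
    mesh: TriangleMesh,
    counts=PAPER_COUNTS,
    d: float = 30.0,
    h: float = 400.0,
    fov_spec=(36.0, 24.0),
    recon_config: ReconConfig | None = None,
    start_angle: float = 0.0,
    benchmark: int | None = None,
    mesh_id: str = "mesh",
) -> SweepTable:
    """One reconstructable-subset evaluation per camera count.

    ``benchmark`` defaults to the largest count; it must be in ``counts``.
    Deterministic for fixed inputs (the pipeline has no random element).
    """
    counts = sorted(int(c) for c in counts)
    benchmark = benchmark or counts[-1]
    if benchmark not in counts:
        raise ValueError("benchmark count must be part of the sweep")
    recon_config = recon_config or ReconConfig()
    results: dict[int, ReconstructionResult] = {}
    rows = []
    for n in counts:
        setup = make_ring_setup(M=n, d=d, h=h, fov_spec=fov_spec, start_angle=start_angle)
        res = reconstructable_subset(mesh, setup, recon_config)
        results[n] = res
        rows.append(
            {
                "n": n,
                "Ar_mm2": res.area,
                "Ar_mm2_excl_top": res.area_excluding(),
            }
        )
    df = pd.DataFrame(rows)
    bench = df.loc[df["n"] == benchmark].iloc[0]
    if bench["Ar_mm2"] <= 0:
        raise ValueError("benchmark reconstructable area is zero")
    df["norm"] = df["Ar_mm2"] / bench["Ar_mm2"]
    df["norm_excl_top"] = (
        df["Ar_mm2_excl_top"] / bench["Ar_mm2_excl_top"]
        if bench["Ar_mm2_excl_top"] > 0
        else np.nan
    )
    return SweepTable(
        table=df, mesh_id=mesh_id, fov=tuple(fov_spec), T=recon_config.T,
        benchmark=benchmark, results=results,
    )


def delta_areas(table, column: str = "norm") -> pd.DataFrame:
    """Consecutive increments of a normalized-area column.

    ``delta`` is the absolute increment from the previous row; ``delta_pct``
    expresses it as a percentage of the previous row's value.  Accepts a
    :class:`SweepTable`, a DataFrame with the given column, or a plain
    sequence of normalized areas.
    """
    if isinstance(table, SweepTable):
        df = table.table.copy()
    elif isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame({column: np.asarray(table, dtype=float)})
    if len(df) < 2:
        raise ValueError("need at least two rows to form increments")
    vals = df[column].to_numpy()
    delta = np.diff(vals, prepend=vals[0])
    prev = np.concatenate([[np.nan], vals[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(np.isnan(prev), 0.0, 100.0 * delta / prev)
    df["delta"] = delta
    df["delta_pct"] = pct
    return df


@dataclasses.dataclass
class DecayFit:
    """Fitted n-phase approach-to-plateau curve for |Ar|(n)."""

    n_phases: int
    plateau: float
    amplitudes: np.ndarray
    rates: np.ndarray
    residual_norm: float

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        out = np.full(n.shape, self.plateau)
        for a, b in zip(self.amplitudes, self.rates):
            out = out - a * np.exp(-b * n)
        return out


def _decay_residuals(theta, x, y, n_phases):
    c0 = theta[0]
    a = np.exp(np.clip(theta[1 : 1 + n_phases], -50.0, 50.0))
    b = np.exp(np.clip(theta[1 + n_phases :], -50.0, 50.0))
    model = c0 - (a[None, :] * np.exp(-np.outer(x, b))).sum(axis=1)
    return model - y


def fit_decay(table, n_phases: int = 2, column: str = "norm", seed: int = 0) -> DecayFit:
    """Least-squares fit of ``c0 - sum a_i exp(-b_i n)`` with positive
    amplitudes and rates (log-parametrized), deterministic multi-start.

    For ``n_phases = 3`` the starts include the best 2-phase solution with a
    vanishing third phase, so the 3-phase residual can never exceed the
    2-phase one (nested models).
    """
    if n_phases not in (2, 3):
        raise ValueError("n_phases must be 2 or 3")
    if isinstance(table, SweepTable):
        x = table.table["n"].to_numpy(dtype=float)
        y = table.table[column].to_numpy(dtype=float)
    elif isinstance(table, pd.DataFrame):
        x = table["n"].to_numpy(dtype=float)
        y = table[column].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in table)
    if len(x) < 2 * n_phases + 1:
        raise ValueError("need at least 2*n_phases + 1 data points")

    rng = np.random.default_rng(seed)
    spread = max(float(y.max() - y.min()), 1e-12)
    c0_init = float(y.max()) + 0.01 * spread

    starts = []
    base_rates = np.array([0.5, 0.1, 0.02, 0.005, 0.002])
    import itertools

    for combo in itertools.combinations(range(len(base_rates)), n_phases):
        rates = base_rates[list(combo)]
        amps = np.full(n_phases, spread / n_phases) + 1e-12
        starts.append(
            np.concatenate([[c0_init], np.log(amps), np.log(rates)])
        )
    for _ in range(8):
        rates = np.exp(rng.uniform(np.log(1e-3), np.log(1.0), size=n_phases))
        amps = np.maximum(rng.uniform(0.1, 1.0, size=n_phases) * spread, 1e-12)
        starts.append(np.concatenate([[c0_init], np.log(amps), np.log(rates)]))
    if n_phases == 3:
        two = fit_decay((x, y), n_phases=2, seed=seed)
        starts.append(
            np.concatenate(
                [
                    [two.plateau],
                    np.log(np.append(two.amplitudes, 1e-13)),
                    np.log(np.append(two.rates, 0.05)),
                ]
            )
        )

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                _decay_residuals, theta0, args=(x, y, n_phases), method="lm",
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("decay fit failed to converge from every start")
    c0 = float(best.x[0])
    return DecayFit(
        n_phases=n_phases,
        plateau=c0,
        amplitudes=np.exp(np.clip(best.x[1 : 1 + n_phases], -50.0, 50.0)),
        rates=np.exp(np.clip(best.x[1 + n_phases :], -50.0, 50.0)),
        residual_norm=float(np.linalg.norm(best.fun)),
    )


def report(tables: dict[str, SweepTable], fits: dict[str, DecayFit], out_dir) -> list[Path]:
    """Write one CSV per sweep, a combined fit plot and a JSON run log.

    Byte-deterministic for fixed inputs: no timestamps are embedded.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, sweep in tables.items():
        df = delta_areas(sweep)[["n", "Ar_mm2", "norm", "delta", "delta_pct"]]
        path = out_dir / f"sweep_{name}.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    grid = np.linspace(2, max(s.table["n"].max() for s in tables.values()), 200)
    for name, sweep in tables.items():
        (line,) = ax.plot(
            sweep.table["n"], sweep.table["norm"], "o", ms=4, label=name
        )
        fit = fits.get(name)
        if fit is not None:
            ax.plot(grid, fit.predict(grid), "-", color=line.get_color(), lw=1)
    ax.set_xlabel("number of cameras")
    ax.set_ylabel("normalized reconstructable area")
    ax.set_xscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    plot_path = out_dir / "sweep_fits.png"
    fig.savefig(plot_path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    written.append(plot_path)

    import reconsim

    log = {
        "package_version": reconsim.__version__,
        "sweeps": {
            name: {
                "mesh_id": s.mesh_id,
                "fov": list(s.fov),
                "T": s.T,
                "benchmark": s.benchmark,
                "counts": [int(n) for n in s.table["n"]],
            }
            for name, s in tables.items()
        },
        "fits": {
            name: {
                "n_phases": f.n_phases,
                "plateau": f.plateau,
                "amplitudes": list(map(float, f.amplitudes)),
                "rates": list(map(float, f.rates)),
                "residual_norm": f.residual_norm,
            }
            for name, f in fits.items()
        },
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    written.append(log_path)
    return written
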