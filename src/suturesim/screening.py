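"""Parameter-sweep experiments and phase diagrams.

Runs grids of simulations over two swept parameters (e.g. the factor
threshold ``v_c`` against surface tension ``sigma``, or growth speed ``c``
against efficacy ``alpha``), measures suture width and interdigitation
amplitude on the steady (or final) field, and assembles phase diagrams
with per-cell status flags.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import SimulationParams
from .morphometrics import SutureMeasurement, measure_field
from .simulator import Trajectory, detect_steady_state, run_simulation

__all__ = [
    "SweepSpec",
    "PhaseDiagram",
    "run_sweep",
    "monotonicity_report",
    "render_phase_diagram",
    "diagram_from_csv",
]

MEASUREMENT_COLUMNS = [
    "width_mean",
    "width_max",
    "max_amplitude",
    "skeleton_length",
]

CSV_COLUMNS = [
    "param1",
    "value1",
    "param2",
    "value2",
    "seed",
    *MEASUREMENT_COLUMNS,
    "flag",
]


@dataclass(frozen=True)
class SweepSpec:
    """Two-parameter sweep definition.

    ``seeds`` are the replicate seeds for the initial interface noise; the
    measurement is taken at the detected steady state when one exists,
    otherwise at ``t_end`` (cell flagged).
    """

    param1: str
    values1: tuple[float, ...]
    param2: str
    values2: tuple[float, ...]
    base: SimulationParams = field(default_factory=SimulationParams)
    seeds: tuple[int, ...] = (0, 1, 2)
    n_snapshots: int = 13
    steady_window: float | None = None
    steady_tol: float = 0.05

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclasses.fields(SimulationParams)}
        for name in (self.param1, self.param2):
            if name not in valid:
                raise ValueError(f"{name!r} is not a SimulationParams field")
        for label, values in (("values1", self.values1), ("values2", self.values2)):
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{label} must be non-empty")
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{label} must be strictly increasing")
        if not self.seeds:
            raise ValueError("at least one replicate seed required")

    @property
    def replicates(self) -> int:
        return len(self.seeds)


@dataclass
class PhaseDiagram:
    """Replicate-mean measurement grids over the swept value lists.

    Grids are indexed ``[i1, i2]`` matching ``values1`` x ``values2``; cells
    whose replicates all failed carry NaN and a flag.  ``records`` holds one
    tidy row per (cell, replicate).
    """

    param1: str
    values1: np.ndarray
    param2: str
    values2: np.ndarray
    width_mean: np.ndarray
    max_amplitude: np.ndarray
    flags: np.ndarray
    records: pd.DataFrame

    def __post_init__(self) -> None:
        shape = (len(self.values1), len(self.values2))
        for name in ("width_mean", "max_amplitude", "flags"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} grid shape {arr.shape} != {shape}")
        ok = self.flags == "steady"
        if np.any(~np.isfinite(self.width_mean[ok])):
            raise ValueError("non-finite measurement in an unflagged cell")

    def grid(self, measurement: str) -> np.ndarray:
        """Replicate-mean grid for any measurement column."""
        if measurement == "width_mean":
            return self.width_mean
        if measurement == "max_amplitude":
            return self.max_amplitude
        piv = self.records.pivot_table(
            index="value1", columns="value2", values=measurement, aggfunc="mean"
        )
        piv = piv.reindex(index=self.values1, columns=self.values2)
        return piv.to_numpy()


def _classify(trajectory: Trajectory, window: float, tol: float) -> tuple[Any, str]:
    """Pick the measurement snapshot and classify the run."""
    final = trajectory.final
    if not (final.u < 0.5).any(axis=1).all():
        return final, "fused"
    t_star = detect_steady_state(trajectory, window=window, tol=tol)
    if t_star is not None:
        times = trajectory.times
        idx = int(np.argmin(np.abs(times - t_star)))
        # measure at the end of the steady regime (the final state), which
        # by definition differs from the onset by < tol
        return trajectory.final, "steady"
    widths = trajectory.widths()
    mid = widths[len(widths) // 2]
    if np.isfinite(mid) and np.isfinite(widths[-1]) and widths[-1] > 1.2 * mid:
        return final, "unbounded"
    return final, "unsteady"


def run_sweep(spec: SweepSpec) -> PhaseDiagram:
    """Run every (cell, replicate) simulation and measure the outcome.

    Deterministic given the seed list.  Per-cell failures are recorded in
    the cell flag ('error'); the sweep continues.
    """
    base = spec.base
    window = spec.steady_window if spec.steady_window is not None else base.t_end / 4.0
    snapshot_times = np.linspace(0.0, base.t_end, spec.n_snapshots)
    rows: list[dict[str, Any]] = []
    n1, n2 = len(spec.values1), len(spec.values2)
    width_grid = np.full((n1, n2), np.nan)
    amp_grid = np.full((n1, n2), np.nan)
    flag_grid = np.full((n1, n2), "", dtype=object)
    for i1, v1 in enumerate(spec.values1):
        for i2, v2 in enumerate(spec.values2):
            cell_flags: list[str] = []
            cell_w: list[float] = []
            cell_a: list[float] = []
            for seed in spec.seeds:
                row: dict[str, Any] = {
                    "param1": spec.param1,
                    "value1": v1,
                    "param2": spec.param2,
                    "value2": v2,
                    "seed": seed,
                }
                try:
                    params = base.replace(
                        **{spec.param1: v1, spec.param2: v2, "seed": seed}
                    )
                    traj = run_simulation(params, snapshot_times=snapshot_times)
                    state, flag = _classify(traj, window, spec.steady_tol)
                    if flag == "fused":
                        row.update({c: np.nan for c in MEASUREMENT_COLUMNS})
                    else:
                        m = measure_field(state, params)
                        row.update(
                            width_mean=m.width_mean,
                            width_max=m.width_max,
                            max_amplitude=m.max_amplitude,
                            skeleton_length=m.skeleton_length,
                        )
                        cell_w.append(m.width_mean)
                        cell_a.append(m.max_amplitude)
                except Exception as exc:  # record and continue
                    flag = "error"
                    row.update({c: np.nan for c in MEASUREMENT_COLUMNS})
                    row["error"] = str(exc)
                row["flag"] = flag
                cell_flags.append(flag)
                rows.append(row)
            # cell flag: worst replicate outcome wins
            for bad in ("error", "fused", "unbounded", "unsteady"):
                if bad in cell_flags:
                    flag_grid[i1, i2] = bad
                    break
            else:
                flag_grid[i1, i2] = "steady"
            if cell_w:
                width_grid[i1, i2] = float(np.mean(cell_w))
                amp_grid[i1, i2] = float(np.mean(cell_a))
    records = pd.DataFrame(rows, columns=[*CSV_COLUMNS, "error"]
                           if any("error" in r for r in rows) else CSV_COLUMNS)
    return PhaseDiagram(
        param1=spec.param1,
        values1=np.asarray(spec.values1, dtype=float),
        param2=spec.param2,
        values2=np.asarray(spec.values2, dtype=float),
        width_mean=width_grid,
        max_amplitude=amp_grid,
        flags=flag_grid,
        records=records,
    )


def monotonicity_report(
    diagram: PhaseDiagram, axis: int, measurement: str = "width_mean"
) -> pd.DataFrame:
    """Trend of a measurement along one swept axis, per line of the grid.

    axis=0 follows ``values1`` (one line per value of param2), axis=1 the
    reverse.  Each line gets its Spearman sign (+1/0/-1) and whether it is
    weakly monotone; lines that are entirely flagged are excluded.
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    grid = diagram.grid(measurement)
    values = diagram.values1 if axis == 0 else diagram.values2
    if len(values) < 3:
        raise ValueError("monotonicity needs >= 3 values along the axis")
    if axis == 1:
        grid = grid.T
    lines = []
    for k in range(grid.shape[1]):
        line = grid[:, k]
        ok = np.isfinite(line)
        if ok.sum() < 3:
            lines.append(
                {"line": k, "spearman_sign": np.nan, "monotone": False, "excluded": True}
            )
            continue
        vals, meas = values[ok], line[ok]
        if np.ptp(meas) == 0:
            rho = 0.0
        else:
            rho = stats.spearmanr(vals, meas).statistic
            if not np.isfinite(rho):
                rho = 0.0
        diffs = np.diff(meas)
        monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
        lines.append(
            {
                "line": k,
                "spearman_sign": float(np.sign(rho)),
                "monotone": monotone,
                "excluded": False,
            }
        )
    report = pd.DataFrame(lines)
    included = report[~report["excluded"]]
    report.attrs["fraction_monotone"] = (
        float(included["monotone"].mean()) if len(included) else float("nan")
    )
    return report


def render_phase_diagram(diagram: PhaseDiagram, out: str | Path) -> dict[str, Path]:
    """Write heatmap PNGs and the tidy per-replicate CSV.

    Flagged cells are annotated with their flag string on the heatmaps and
    carry NaN measurements in the CSV (never fabricated numbers).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    csv_path = out / "sweep.csv"
    diagram.records.to_csv(csv_path, index=False)
    paths["csv"] = csv_path
    for measurement in ("width_mean", "max_amplitude"):
        grid = diagram.grid(measurement)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            grid,
            origin="lower",
            aspect="auto",
            extent=None,
            interpolation="nearest",
        )
        ax.set_xticks(range(len(diagram.values2)))
        ax.set_xticklabels([f"{v:g}" for v in diagram.values2], rotation=45)
        ax.set_yticks(range(len(diagram.values1)))
        ax.set_yticklabels([f"{v:g}" for v in diagram.values1])
        ax.set_xlabel(diagram.param2)
        ax.set_ylabel(diagram.param1)
        ax.set_title(measurement)
        for i1 in range(len(diagram.values1)):
            for i2 in range(len(diagram.values2)):
                flag = diagram.flags[i1, i2]
                if flag not in ("steady", ""):
                    ax.text(i2, i1, flag, ha="center", va="center", fontsize=6)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        png = out / f"{measurement}.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        paths[measurement] = png
    return paths


def diagram_from_csv(path: str | Path) -> PhaseDiagram:
    """Rebuild a PhaseDiagram from the tidy CSV written by render_phase_diagram."""
    records = pd.read_csv(path)
    param1 = records["param1"].iloc[0]
    param2 = records["param2"].iloc[0]
    values1 = np.sort(records["value1"].unique())
    values2 = np.sort(records["value2"].unique())
    n1, n2 = len(values1), len(values2)
    width_grid = np.full((n1, n2), np.nan)
    amp_grid = np.full((n1, n2), np.nan)
    flag_grid = np.full((n1, n2), "", dtype=object)
    for i1, v1 in enumerate(values1):
        for i2, v2 in enumerate(values2):
            cell = records[(records["value1"] == v1) & (records["value2"] == v2)]
            if cell.empty:
                continue
            flags = list(cell["flag"])
            for bad in ("error", "fused", "unbounded", "unsteady"):
                if bad in flags:
                    flag_grid[i1, i2] = bad
                    break
            else:
                flag_grid[i1, i2] = "steady"
            w = cell["width_mean"].dropna()
            a = cell["max_amplitude"].dropna()
            if len(w):
                width_grid[i1, i2] = float(w.mean())
            if len(a):
                amp_grid[i1, i2] = float(a.mean())
    return PhaseDiagram(
        param1=param1,
        values1=values1,
        param2=param2,
        values2=values2,
        width_mean=width_grid,
        max_amplitude=amp_grid,
        flags=flag_grid,
        records=records,
    )
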