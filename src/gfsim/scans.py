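"""Parameter scans, iso-latency band extraction, reversion searches and
latency calibration.

Every scan point is an independent deterministic simulation (build the
circuit with overrides, equilibrate, head-stimulate, measure), so grids are
order-independent and reproducible bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import CircuitSpec, apply_overrides
from .engine import SimConfig
from .protocols import HEAD_STIMULUS, run_head_stimulation

READOUTS = ("TTM", "DLM")

#: iso-latency band tolerance: points within +-1% of the target latency
ISO_TOL_FRACTION = 0.01


@dataclass
class ScanResult:
    """Latency grids over one or two named parameter axes.

    ``latency[readout]`` has shape ``(len(axis1),)`` for 1D scans and
    ``(len(axis1), len(axis2))`` for 2D scans; failed points (no spike)
    are NaN and additionally flagged in ``failed[readout]``.
    """

    axis_names: tuple[str, ...]
    axis_values: tuple[np.ndarray, ...]
    latency: dict[str, np.ndarray]
    failed: dict[str, np.ndarray]
    readouts: tuple[str, ...] = READOUTS

    @property
    def ndim(self) -> int:
        return len(self.axis_names)

    def to_dataframe(self) -> pd.DataFrame:
        if self.ndim == 1:
            df = pd.DataFrame({self.axis_names[0]: self.axis_values[0]})
            for r in self.readouts:
                df[f"latency_{r}_ms"] = self.latency[r]
                df[f"failed_{r}"] = self.failed[r]
            return df
        a1, a2 = np.meshgrid(*self.axis_values, indexing="ij")
        df = pd.DataFrame({self.axis_names[0]: a1.ravel(),
                           self.axis_names[1]: a2.ravel()})
        for r in self.readouts:
            df[f"latency_{r}_ms"] = self.latency[r].ravel()
            df[f"failed_{r}"] = self.failed[r].ravel()
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def grid_scan(circuit: CircuitSpec,
              axis1: tuple[str, np.ndarray],
              axis2: tuple[str, np.ndarray] | None = None,
              readouts: tuple[str, ...] = READOUTS,
              sim_config: SimConfig | None = None,
              base_overrides: dict | None = None) -> ScanResult:
    """Head-stimulation latency over a 1D or 2D parameter grid.

    ``axis1``/``axis2`` are (override path, values) pairs; see
    :func:`gfsim.circuit.apply_overrides` for the path grammar.  Points
    where a readout cell fails to spike are recorded as NaN, never raised.
    """
    name1, vals1 = axis1[0], np.asarray(axis1[1], dtype=np.float64)
    axes = [(name1, vals1)]
    if axis2 is not None:
        axes.append((axis2[0], np.asarray(axis2[1], dtype=np.float64)))
    shape = tuple(len(v) for _, v in axes)
    lat = {r: np.full(shape, np.nan) for r in readouts}
    failed = {r: np.zeros(shape, dtype=bool) for r in readouts}
    for idx in np.ndindex(*shape):
        overrides = dict(base_overrides or {})
        for (name, vals), i in zip(axes, idx):
            overrides[name] = vals[i]
        c = apply_overrides(circuit, overrides)
        res = run_head_stimulation(c, sim_config)
        for r in readouts:
            if res[r].spike_found:
                lat[r][idx] = res[r].latency_total
            else:
                failed[r][idx] = True
    return ScanResult(tuple(n for n, _ in axes), tuple(v for _, v in axes),
                      lat, failed, tuple(readouts))


def find_iso_latency(scan: ScanResult, target_latency: float,
                     readout: str = "TTM",
                     tol_fraction: float = ISO_TOL_FRACTION) -> list[tuple]:
    """Grid points whose latency is within +-tol_fraction of the target.

    Returns index tuples into the scan grid (possibly empty).
    """
    lat = scan.latency[readout]
    with np.errstate(invalid="ignore"):
        mask = np.abs(lat - target_latency) <= tol_fraction * target_latency
    return [tuple(ix) for ix in np.argwhere(mask)]


def iso_latency_contours(scan: ScanResult, target_latency: float,
                         readout: str = "TTM") -> list[np.ndarray]:
    """Marching-squares iso-latency polylines in axis units (2D scans).

    Each polyline is an (n, 2) array of (axis1, axis2) coordinates along the
    ``latency == target`` level set, suitable for overlay plotting.
    """
    if scan.ndim != 2:
        raise ValueError("contours require a 2D scan")
    from skimage import measure
    grid = scan.latency[readout]
    a1, a2 = scan.axis_values
    out = []
    for poly in measure.find_contours(np.nan_to_num(grid, nan=np.inf),
                                      target_latency):
        x = np.interp(poly[:, 0], np.arange(len(a1)), a1)
        y = np.interp(poly[:, 1], np.arange(len(a2)), a2)
        out.append(np.column_stack([x, y]))
    return out


@dataclass
class ReversionResult:
    path: str
    value: float                  # parameter value achieving the target
    fold_change: float            # default_value / value
    default_value: float
    achieved_latency: float
    reachable: bool = True
    message: str = ""


def _latency_at(circuit, path, value, readout, sim_config):
    res = run_head_stimulation(apply_overrides(circuit, {path: value}),
                               sim_config)[readout]
    return res.latency_total if res.spike_found else np.nan


def find_reversion_value(circuit: CircuitSpec, path: str, default_value: float,
                         target_latency: float, readout: str,
                         bracket: tuple[float, float],
                         sim_config: SimConfig | None = None,
                         rel_tol: float = 0.005,
                         max_iter: int = 60) -> ReversionResult:
    """Bisect one parameter to the value whose latency equals the target.

    Monotonicity of latency over the bracket is first verified by 5-point
    sampling; a target outside the sampled latency range is reported as
    unreachable (not an exception) — the outcome for every conductance
    parameter within its physiological scan range.  Convergence tolerance
    is 0.5% on the latency.
    """
    lo, hi = bracket
    probe = np.linspace(lo, hi, 5)
    lats = np.array([_latency_at(circuit, path, x, readout, sim_config)
                     for x in probe])
    if np.isnan(lats).any():
        ok = ~np.isnan(lats)
        if ok.sum() < 2:
            return ReversionResult(path, np.nan, np.nan, default_value, np.nan,
                                   False, "no spiking point in bracket")
        probe, lats = probe[ok], lats[ok]
    diffs = np.diff(lats)
    if not ((diffs <= 0).all() or (diffs >= 0).all()):
        return ReversionResult(path, np.nan, np.nan, default_value, np.nan,
                               False, "latency not monotone over bracket")
    if not (min(lats) <= target_latency <= max(lats)):
        return ReversionResult(path, np.nan, np.nan, default_value, np.nan,
                               False,
                               f"target {target_latency:.3f} ms outside the "
                               f"attainable range [{min(lats):.3f}, "
                               f"{max(lats):.3f}] ms")
    # bracket the target between adjacent probe points, then bisect
    k = int(np.nonzero((np.minimum(lats[:-1], lats[1:]) <= target_latency)
                       & (target_latency <= np.maximum(lats[:-1], lats[1:])))[0][0])
    xlo, xhi = float(probe[k]), float(probe[k + 1])
    flo = float(lats[k])
    x, lat = xlo, flo
    for _ in range(max_iter):
        x = 0.5 * (xlo + xhi)
        lat = _latency_at(circuit, path, x, readout, sim_config)
        if np.isfinite(lat) and abs(lat - target_latency) <= rel_tol * target_latency:
            break
        same_side = (np.isnan(lat) and np.isnan(flo)) or \
            (np.isfinite(lat) and np.isfinite(flo)
             and (lat - target_latency) * (flo - target_latency) > 0)
        if same_side:
            xlo, flo = x, lat
        else:
            xhi = x
    return ReversionResult(path, x, default_value / x, default_value, lat,
                           reachable=True)


@dataclass
class CalibrationResult:
    overrides: dict[str, float]
    residuals: dict[str, float]       # readout -> latency - target (ms)
    achieved: dict[str, float]
    converged: bool
    message: str = ""


def calibrate(circuit: CircuitSpec,
              free_params: dict[str, tuple[float, float]],
              targets: dict[str, float],
              sim_config: SimConfig | None = None,
              rel_tol: float = 0.02,
              sweeps: int = 4,
              grid: int = 9) -> CalibrationResult:
    """Deterministic bounded search matching head-stimulation latencies.

    ``free_params`` maps override paths to (lo, hi) bounds and ``targets``
    maps readouts ("TTM"/"DLM") to total latencies (ms).  A fixed number of
    coordinate sweeps is run in insertion order: each sweep line-searches
    one parameter on a refining grid against the summed squared latency
    error (non-spiking points are penalized heavily, enforcing the
    all-cells-spiking constraint).  Success requires every target matched
    within ``rel_tol`` (default 2%); otherwise the best-found overrides and
    residuals are reported with ``converged=False``.
    """
    paths = list(free_params)
    current = {}
    base = circuit

    def objective(ovr):
        res = run_head_stimulation(apply_overrides(base, ovr), sim_config)
        ach, err = {}, 0.0
        for r, tgt in targets.items():
            lr = res[r]
            lat = lr.latency_total if lr.spike_found else np.nan
            ach[r] = lat
            err += 100.0 if np.isnan(lat) else ((lat - tgt) / tgt) ** 2
        return err, ach

    best_err, best_ach = objective(current)
    for sweep in range(sweeps):
        for path in paths:
            lo, hi = free_params[path]
            if path in current:
                # refine around the current value
                span = (hi - lo) / (2.0 ** sweep)
                lo = max(lo, current[path] - span / 2)
                hi = min(free_params[path][1], current[path] + span / 2)
            for x in np.linspace(lo, hi, grid):
                trial = dict(current)
                trial[path] = float(x)
                err, ach = objective(trial)
                if err < best_err:
                    best_err, best_ach, current = err, ach, trial
    residuals = {r: best_ach[r] - targets[r] for r in targets}
    converged = all(np.isfinite(best_ach[r])
                    and abs(residuals[r]) <= rel_tol * targets[r]
                    for r in targets)
    msg = "" if converged else "targets not met within tolerance"
    return CalibrationResult(current, residuals, best_ach, converged, msg)
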