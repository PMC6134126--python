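"""File round-tripping: CSV with a ``# meta:`` JSON header, fit JSON,
tidy sweep tables and run manifests.

All formats are plain text and lossless at full float precision, so runs
are inspectable and diff-able.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .inference import FourierPRC, InferenceConfig, PhaseModelFit
from .oscillators import SimulationResult
from .sections import EventTimes
from .signals import DrivingSignal, TimeGrid

__all__ = [
    "write_signal", "read_signal",
    "write_events", "read_events",
    "write_simulation", "read_simulation",
    "write_fit", "read_fit",
    "write_prc_curve",
    "write_manifest",
]


def write_signal(signal: DrivingSignal, path) -> None:
    signal.to_csv(path)


def read_signal(path) -> DrivingSignal:
    return DrivingSignal.from_csv(path)


def write_events(events: EventTimes, path) -> None:
    events.to_csv(path)


def read_events(path) -> EventTimes:
    return EventTimes.from_csv(path)


def write_simulation(result: SimulationResult, path) -> None:
    """Columns (time, x, p[, phi_true]) plus a '# meta:' JSON header."""
    cols = {"time": result.grid.times}
    if result.observable is not None:
        cols["x"] = result.observable
    cols["p"] = result.driver.values
    if result.true_phase is not None:
        cols["phi_true"] = result.true_phase
    meta = dict(result.meta)
    meta.update(t0=result.grid.t0, dt=result.grid.dt,
                n_samples=result.grid.n_samples,
                columns=list(cols))
    with open(path, "w") as fh:
        fh.write("# meta: " + json.dumps(meta) + "\n")
        fh.write(",".join(cols) + "\n")
        buf = _io.StringIO()
        np.savetxt(buf, np.column_stack(list(cols.values())), fmt="%.17g",
                   delimiter=",")
        fh.write(buf.getvalue())


def read_simulation(path) -> SimulationResult:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# meta:"):
            raise InvalidParameterError(f"{path}: missing '# meta:' header")
        meta = json.loads(first[len("# meta:"):])
        data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
    grid = TimeGrid(t0=meta.pop("t0"), dt=meta.pop("dt"),
                    n_samples=meta.pop("n_samples"))
    columns = meta.pop("columns")
    by_name = {name: data[:, j] for j, name in enumerate(columns)}
    driver = DrivingSignal(grid=grid, values=by_name["p"],
                           meta={"kind": meta.get("driver_kind", "unknown")})
    return SimulationResult(grid=grid, driver=driver,
                            observable=by_name.get("x"),
                            true_phase=by_name.get("phi_true"), meta=meta)


def write_fit(result: PhaseModelFit, path) -> None:
    result.to_json(path)


def read_fit(path) -> PhaseModelFit:
    with open(path) as fh:
        d = json.load(fh)
    prc = FourierPRC.from_dict(d)
    config = InferenceConfig(n_harmonics=d["n_harmonics"],
                             n_iterations=d["n_iterations"],
                             n_periods=d["n_periods"])
    from .inference import IterationRecord
    trace = [IterationRecord(omega=np.nan, prc=prc, delta_psi=v)
             for v in d["delta_psi_trace"]]
    return PhaseModelFit(omega=d["omega"], prc=prc, phase=None, trace=trace,
                         config=config)


def write_prc_curve(prc, path, n_points: int = 512) -> None:
    """Two-column CSV (phi, Z) on a uniform phase grid."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pd.DataFrame({"phi": phi, "Z": np.asarray(prc(phi))}).to_csv(
        path, index=False, float_format="%.17g")


def write_manifest(path, **entries) -> None:
    """JSON manifest of a run (model, parameters, seeds, versions)."""
    import prcinfer
    payload = {"prcinfer_version": prcinfer.__version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
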