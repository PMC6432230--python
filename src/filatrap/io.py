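"""Run persistence: TSV logs, counter tables, XYZ snapshots, manifests.

All numeric logs are tab-separated with a single commented header line,
fixed column order, greppable and diffable.  Checkpoints (full state
including RNG streams and pending event times) use
``SystemState.save``/``load``; everything else is plain text.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import SimulationParams, save_config
from .state import SystemState, Counters
from .simulation import Trace

__all__ = ["write_trace", "read_trace", "write_counters", "read_counters",
           "write_events", "write_xyz", "write_manifest", "read_manifest"]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  float_format="%.17g")


def _read_tsv(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing commented header line")
        cols = header[1:].strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=cols,
                         float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def write_trace(trace: Trace, path: str | Path) -> None:
    _write_tsv(trace.to_dataframe(), Path(path))


def read_trace(path: str | Path) -> Trace:
    df = _read_tsv(Path(path))
    Nf = sum(c.startswith("j") for c in df.columns)
    jcols = [f"j{n + 1}" for n in range(Nf)]
    xcols = [f"X{n + 1}" for n in range(Nf)]
    rcols = [f"Rperp{n + 1}" for n in range(Nf)]
    ecols = ["U_bond", "U_bend", "U_wall_fixed", "U_wall_mobile",
             "F_w_bun", "F_w_m"]
    return Trace(
        t=df.t.to_numpy(), L=df.L.to_numpy(), Ldot=df.Ldot.to_numpy(),
        N1=df.N1.to_numpy(dtype=np.int64),
        j=df[jcols].to_numpy(dtype=np.int64),
        X=df[xcols].to_numpy(), R_perp=df[rcols].to_numpy(),
        E=df[ecols].to_numpy())


def write_counters(counters: Counters, path: str | Path) -> None:
    """Raw m-resolved counts plus the reservoir counters (as a comment)."""
    ms = np.arange(len(counters.Q)) - counters.m_offset
    sel = (counters.Q > 0) | (counters.attU > 0) | (counters.attW > 0)
    df = pd.DataFrame({
        "m": ms[sel], "Q": counters.Q[sel],
        "attU": counters.attU[sel], "attW": counters.attW[sel],
        "sucU": counters.sucU[sel], "sucW": counters.sucW[sel]})
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gc_counters\t" + "\t".join(str(int(v)) for v in counters.gc)
                 + "\n")
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_counters(path: str | Path) -> Counters:
    c = Counters()
    with open(path) as fh:
        gc_line = fh.readline()
        c.gc[:] = [int(v) for v in gc_line.split("\t")[1:]]
        header = fh.readline()
        cols = header[1:].strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=cols)
    for _, row in df.iterrows():
        i = int(row.m) + c.m_offset
        c.Q[i] = row.Q
        c.attU[i] = row.attU
        c.attW[i] = row.attW
        c.sucU[i] = row.sucU
        c.sucW[i] = row.sucW
    return c


def write_events(event_df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(event_df, Path(path))


def write_xyz(state: SystemState, path: str | Path, append: bool = False) -> None:
    """Coordinate snapshot in XYZ format (visualization only).

    Element tags encode the role: ``S`` seed, ``C`` filament member,
    ``O`` free monomer.
    """
    lines = []
    Nf = state.params.Nf
    n_atoms = state.Nt
    lines.append(str(n_atoms + 1))
    lines.append(f"t={state.t:.6g} L={state.L:.6g}")
    for n in range(1, Nf + 1):
        for k in range(int(state.jn[n])):
            i = state.fil[n, k]
            tag = "S" if k < 2 else "C"
            lines.append(f"{tag} {state.pos[i, 0]:.6f} {state.pos[i, 1]:.6f} "
                         f"{state.pos[i, 2]:.6f}")
    for a in range(state.N1):
        i = state.free_list[a]
        lines.append(f"O {state.pos[i, 0]:.6f} {state.pos[i, 1]:.6f} "
                     f"{state.pos[i, 2]:.6f}")
    # the mobile wall, as a pseudo-atom on the axis
    lines.append(f"W {state.L:.6f} 0.0 0.0")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def write_manifest(run_dir: str | Path, params: SimulationParams,
                   files: dict, extra: dict | None = None) -> Path:
    """Record resolved parameters, seed, version and the file inventory."""
    run_dir = Path(run_dir)
    manifest = {
        "filatrap_version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "params": params.to_dict(),
        "files": files,
    }
    if extra:
        manifest.update(extra)
    path = run_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def read_manifest(run_dir: str | Path) -> dict:
    with open(Path(run_dir) / "manifest.json") as fh:
        return json.load(fh)


def save_run(run_dir: str | Path, sim, trace: Trace | None,
             phases: dict | None = None) -> None:
    """Write the standard output set of a run into ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    save_config(sim.params, run_dir / "params.yaml")
    files["params.yaml"] = "resolved configuration"
    if trace is not None and len(trace):
        write_trace(trace, run_dir / "trace.tsv")
        files["trace.tsv"] = "observable time series"
    write_counters(sim.counters, run_dir / "counters.tsv")
    files["counters.tsv"] = "m-resolved residence/attempt/success counters"
    ev = sim.event_dataframe()
    if len(ev):
        write_events(ev, run_dir / "events.tsv")
        files["events.tsv"] = "reaction event log"
    sim.state.save(run_dir / "checkpoint.pkl")
    files["checkpoint.pkl"] = "binary checkpoint (state + RNG + clocks)"
    write_manifest(run_dir, sim.params, files, extra=phases or {})
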