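"""Plain-text readers and writers for traces, distributions and recovery curves.

Trace files are two whitespace-separated columns ``time_us intensity`` with
optional ``#`` comment lines; Bruker binary formats (DTA/DSC) are not
supported — convert to two-column text first.  Distribution files are CSV
with header ``r_nm,p_per_nm``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .dipolar_model import DeerTrace, DistanceDistribution, DistanceGrid
from .errors import InvalidParameterError


def read_trace(path: str | Path) -> DeerTrace:
    """Read a two-column DEER trace file.

    Comment lines start with ``#``.  The time axis is shifted to start at
    zero and the intensity is normalized by its value at the earliest time
    point, so pre-normalized and raw-count files are both accepted.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise InvalidParameterError(f"{path}: expected two columns (time_us, intensity)")
    t, v = data[:, 0], data[:, 1]
    order = np.argsort(t)
    t, v = t[order], v[order]
    if v[0] == 0:
        raise InvalidParameterError(f"{path}: intensity at earliest time is zero")
    return DeerTrace(t=t - t[0], v=v / v[0], meta={"source": str(path)})


def write_trace(path: str | Path, trace: DeerTrace, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# time_us  intensity\n")
        for ti, vi in zip(trace.t, trace.v):
            fh.write(f"{ti:.9g}  {vi:.9g}\n")


def read_distribution(path: str | Path) -> DistanceDistribution:
    """Read a distance distribution CSV with columns ``r_nm,p_per_nm``."""
    df = pd.read_csv(path)
    missing = {"r_nm", "p_per_nm"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {sorted(missing)}")
    grid = DistanceGrid(df["r_nm"].to_numpy(float))
    return DistanceDistribution.normalized(grid, df["p_per_nm"].to_numpy(float))


def write_distribution(path: str | Path, dist: DistanceDistribution) -> None:
    pd.DataFrame({"r_nm": dist.grid.r, "p_per_nm": dist.p}).to_csv(path, index=False)


def read_recovery_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a FRAP recovery CSV with columns ``time_s,intensity``."""
    df = pd.read_csv(path)
    missing = {"time_s", "intensity"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {sorted(missing)}")
    return df["time_s"].to_numpy(float), df["intensity"].to_numpy(float)


def read_config(path: str | Path) -> dict:
    """Read a flat ``key: value`` YAML config file mirroring the CLI flags."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"{path}: config must be a key-value mapping")
    return cfg


def structure_to_pdb(atoms) -> str:
    """Render a list of atom records as PDB-format text (ATOM records only)."""
    buf = _io.StringIO()
    for a in atoms:
        buf.write(
            "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
            "{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            "          {element:>2s}\n".format(
                serial=a.serial,
                name=f" {a.name:<3s}" if len(a.name) < 4 else a.name,
                altloc=a.altloc or " ",
                resname=a.resname,
                chain=a.chain,
                resnum=a.resnum,
                x=a.x,
                y=a.y,
                z=a.z,
                occ=a.occupancy,
                b=0.0,
                element=a.element,
            )
        )
    buf.write("END\n")
    return buf.getvalue()
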