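"""Text formats: PLUMED-dialect COLVAR/HILLS files, free-energy grids,
permeation profiles and I-V tables.

All writers emit self-describing headers and full-precision numbers
(%.17g), so ``read(write(x))`` reproduces ``x`` bit-exactly.  Parse
errors name the offending line.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import FESGrid, GridAxis
from .kmc import PermeationProfile
from .metad import Hill

__all__ = [
    "write_colvar",
    "read_colvar",
    "write_hills",
    "read_hills",
    "write_fes_grid",
    "read_fes_grid",
    "write_profile",
    "read_profile",
    "write_iv_table",
    "read_iv_table",
]

_FMT = "%.17g"


class FormatError(ValueError):
    """A malformed line in one of the text formats."""


def _fmt_row(values) -> str:
    return " ".join(_FMT % v for v in values)


# ---------------------------------------------------------------------------
# COLVAR
# ---------------------------------------------------------------------------


def write_colvar(path, times: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    """CV time series in the PLUMED COLVAR dialect.

    Header line ``#! FIELDS time <names>``, whitespace-delimited rows.
    """
    names = list(columns)
    arrays = [np.asarray(columns[n], dtype=float) for n in names]
    times = np.asarray(times, dtype=float)
    for n, a in zip(names, arrays):
        if a.shape != times.shape:
            raise ValueError(f"column {n!r} length does not match time")
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(names) + "\n")
        for i in range(times.size):
            fh.write(_fmt_row([times[i]] + [a[i] for a in arrays]) + "\n")


def read_colvar(path) -> pd.DataFrame:
    """Parse a COLVAR file; returns a DataFrame with a ``time`` column."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#! FIELDS"):
            raise FormatError(f"{path}:1: missing '#! FIELDS' header")
        names = header.split()[2:]
        if not names or names[0] != "time":
            raise FormatError(f"{path}:1: first field must be 'time'")
        rows = []
        prev_t = -np.inf
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(names):
                raise FormatError(
                    f"{path}:{ln}: expected {len(names)} fields, found {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric field") from exc
            if vals[0] < prev_t:
                raise FormatError(f"{path}:{ln}: non-monotone time stamp")
            prev_t = vals[0]
            rows.append(vals)
    return pd.DataFrame(rows, columns=names)


# ---------------------------------------------------------------------------
# HILLS
# ---------------------------------------------------------------------------


def write_hills(path, hills: Sequence[Hill], cv_names: Sequence[str]) -> None:
    """Hill list in the PLUMED HILLS dialect.

    Columns: time, centers, sigmas, height, biasf (1 for standard
    metadynamics) plus a trailing walker id column.
    """
    cv_names = list(cv_names)
    with open(path, "w") as fh:
        fh.write(
            "#! FIELDS time "
            + " ".join(cv_names)
            + " "
            + " ".join(f"sigma_{n}" for n in cv_names)
            + " height biasf walker\n"
        )
        for h in hills:
            if len(h.center) != len(cv_names):
                raise ValueError("hill dimensionality does not match cv_names")
            fh.write(
                _fmt_row(
                    [h.time, *h.center, *h.widths, h.height, 1.0, h.walker_id]
                )
                + "\n"
            )


def read_hills(path) -> tuple[list[Hill], list[str]]:
    """Parse a HILLS file; returns (hills, cv names)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#! FIELDS"):
            raise FormatError(f"{path}:1: missing '#! FIELDS' header")
        fields = header.split()[2:]
        if fields[0] != "time" or "height" not in fields:
            raise FormatError(f"{path}:1: not a HILLS header")
        n_cv = fields.index("height") - 1
        if n_cv % 2 != 0:
            raise FormatError(f"{path}:1: center/sigma columns do not pair up")
        n_cv //= 2
        names = fields[1 : 1 + n_cv]
        has_walker = "walker" in fields
        expected = len(fields)
        hills: list[Hill] = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != expected:
                raise FormatError(
                    f"{path}:{ln}: expected {expected} fields, found {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric field") from exc
            t = vals[0]
            center = tuple(vals[1 : 1 + n_cv])
            widths = tuple(vals[1 + n_cv : 1 + 2 * n_cv])
            height = vals[1 + 2 * n_cv]
            walker = int(vals[-1]) if has_walker else 0
            hills.append(Hill(center, widths, height, t, walker))
    return hills, names


# ---------------------------------------------------------------------------
# free-energy grids
# ---------------------------------------------------------------------------


def write_fes_grid(path, fes: FESGrid) -> None:
    """Header-annotated whitespace grid file.

    Axis specs and temperature live in comment lines; rows are the node
    coordinates followed by the free energy (NaN for unsampled nodes),
    in C (last-axis-fastest) order.
    """
    with open(path, "w") as fh:
        for ax in fes.axes:
            fh.write(
                f"# axis {ax.name} {_FMT % ax.minimum} {_FMT % ax.maximum} "
                f"{ax.n_bins} {ax.units or '-'}\n"
            )
        fh.write(f"# temperature {_FMT % fes.temperature}\n")
        fh.write("#! FIELDS " + " ".join(ax.name for ax in fes.axes) + " free_energy\n")
        centers = [ax.centers for ax in fes.axes]
        for idx in np.ndindex(fes.values.shape):
            coords = [centers[d][i] for d, i in enumerate(idx)]
            fh.write(_fmt_row(coords + [fes.values[idx]]) + "\n")


def read_fes_grid(path) -> FESGrid:
    path = Path(path)
    axes: list[GridAxis] = []
    temperature = 310.0
    values: list[float] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# axis"):
                parts = line.split()
                if len(parts) != 7:
                    raise FormatError(f"{path}:{ln}: malformed axis spec")
                name, lo, hi, nb, units = parts[2:7]
                axes.append(
                    GridAxis(name, float(lo), float(hi), int(nb),
                             "" if units == "-" else units)
                )
            elif line.startswith("# temperature"):
                temperature = float(line.split()[2])
            elif line.startswith("#"):
                continue
            else:
                parts = line.split()
                if len(parts) != len(axes) + 1:
                    raise FormatError(
                        f"{path}:{ln}: expected {len(axes) + 1} fields, "
                        f"found {len(parts)}"
                    )
                values.append(float(parts[-1]))
    if not axes:
        raise FormatError(f"{path}: no axis specs found")
    shape = tuple(ax.n_bins for ax in axes)
    arr = np.asarray(values, dtype=float)
    if arr.size != int(np.prod(shape)):
        raise FormatError(
            f"{path}: {arr.size} grid rows do not fill shape {shape}"
        )
    return FESGrid(tuple(axes), arr.reshape(shape), temperature)


# ---------------------------------------------------------------------------
# permeation profiles
# ---------------------------------------------------------------------------


def write_profile(path, profile: PermeationProfile) -> None:
    """Two/three-column text: z, W(z) and (when per-bin) D(z)."""
    D = np.asarray(profile.diffusion, dtype=float)
    per_bin = D.ndim > 0
    with open(path, "w") as fh:
        fh.write(f"# temperature {_FMT % profile.temperature}\n")
        z_in, z_out = profile.channel_span
        fh.write(f"# channel_span {_FMT % z_in} {_FMT % z_out}\n")
        if not per_bin:
            fh.write(f"# diffusion {_FMT % float(D)}\n")
        fh.write(
            "#! FIELDS z free_energy" + (" diffusion" if per_bin else "") + "\n"
        )
        for i in range(profile.z.size):
            row = [profile.z[i], profile.free_energy[i]]
            if per_bin:
                row.append(D[i])
            fh.write(_fmt_row(row) + "\n")


def read_profile(path) -> PermeationProfile:
    path = Path(path)
    temperature = 310.0
    span = None
    diffusion: float | np.ndarray = 0.5
    rows: list[list[float]] = []
    n_fields = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# temperature"):
                temperature = float(line.split()[2])
            elif line.startswith("# channel_span"):
                parts = line.split()
                span = (float(parts[2]), float(parts[3]))
            elif line.startswith("# diffusion"):
                diffusion = float(line.split()[2])
            elif line.startswith("#! FIELDS"):
                n_fields = len(line.split()) - 2
            elif line.startswith("#"):
                continue
            else:
                parts = line.split()
                if n_fields is not None and len(parts) != n_fields:
                    raise FormatError(
                        f"{path}:{ln}: expected {n_fields} fields, found {len(parts)}"
                    )
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: non-numeric field") from exc
    if not rows:
        raise FormatError(f"{path}: no profile rows")
    arr = np.asarray(rows)
    if arr.shape[1] == 3:
        diffusion = arr[:, 2]
    return PermeationProfile(
        z=arr[:, 0],
        free_energy=arr[:, 1],
        diffusion=diffusion,
        temperature=temperature,
        channel_span=span,
    )


# ---------------------------------------------------------------------------
# I-V tables
# ---------------------------------------------------------------------------


def write_iv_table(path, table: pd.DataFrame, slope_ps: float | None = None) -> None:
    with open(path, "w") as fh:
        if slope_ps is not None:
            fh.write(f"# slope_conductance_pS {_FMT % slope_ps}\n")
        fh.write("#! FIELDS " + " ".join(table.columns) + "\n")
        for _, row in table.iterrows():
            fh.write(_fmt_row(row.to_list()) + "\n")


def read_iv_table(path) -> tuple[pd.DataFrame, float | None]:
    path = Path(path)
    slope = None
    names: list[str] | None = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# slope_conductance_pS"):
                slope = float(line.split()[2])
            elif line.startswith("#! FIELDS"):
                names = line.split()[2:]
            elif line.startswith("#"):
                continue
            else:
                if names is None:
                    raise FormatError(f"{path}:{ln}: data before the FIELDS header")
                parts = line.split()
                if len(parts) != len(names):
                    raise FormatError(
                        f"{path}:{ln}: expected {len(names)} fields, found {len(parts)}"
                    )
                rows.append([float(p) for p in parts])
    if names is None:
        raise FormatError(f"{path}: missing FIELDS header")
    return pd.DataFrame(rows, columns=names), slope
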