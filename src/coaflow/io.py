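"""Field and waveform I/O.

Velocity fields are written either as legacy ASCII VTK structured-points
files (readable by ParaView) or as a flat ``.npz`` container with a JSON
header.  Waveforms round-trip through the tidy CSV written by
:meth:`coaflow.circuit.CycleWaveforms.to_csv`.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .circuit import CycleWaveforms
from .compare import VectorField

__all__ = ["write_vtk", "save_field", "load_field", "waveforms_from_csv"]


def write_vtk(path, field: VectorField, name: str = "velocity") -> None:
    """Write a vector field as a legacy ASCII VTK STRUCTURED_POINTS file."""
    shape = field.grid_shape
    dims = list(shape) + [1] * (3 - len(shape))
    spacing = list(field.spacing) + [1.0] * (3 - len(shape))
    origin = list(field.origin) + [0.0] * (3 - len(shape))
    data = field.data.reshape(-1, field.data.shape[-1], order="F")
    if data.shape[1] < 3:
        data = np.pad(data, ((0, 0), (0, 3 - data.shape[1])))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoaflow field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}\n")
        fh.write(f"POINT_DATA {data.shape[0]}\n")
        fh.write(f"VECTORS {name} float\n")
        np.savetxt(fh, data, fmt="%.8g")


def save_field(path, field: VectorField) -> None:
    """Save a field as .npz with an embedded JSON header."""
    header = json.dumps({"origin": field.origin.tolist(),
                         "spacing": field.spacing.tolist()})
    np.savez_compressed(path, data=field.data, mask=field.mask,
                        header=np.array(header))


def load_field(path) -> VectorField:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        return VectorField(origin=header["origin"], spacing=header["spacing"],
                           data=z["data"], mask=z["mask"].astype(bool))


def waveforms_from_csv(path, T: float = None) -> CycleWaveforms:
    """Rebuild a :class:`CycleWaveforms` from its tidy CSV representation."""
    df = pd.read_csv(path)
    wide = df.pivot_table(index=["time", "cycle"], columns="signal",
                          values="value").reset_index().sort_values("time")
    time = wide["time"].to_numpy()
    cycles = wide["cycle"].to_numpy().astype(int)
    signals = {c: wide[c].to_numpy() for c in wide.columns
               if c not in ("time", "cycle")}
    if T is None:
        last = cycles.max()
        tsel = time[cycles == last]
        T = float(tsel.max() - tsel.min())
    return CycleWaveforms(time=time, cycle_index=cycles, signals=signals,
                          T=T, steady=True)
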