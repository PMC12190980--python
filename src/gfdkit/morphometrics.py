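"""Structure-to-function scalar calculators for proteinoid geometries.

Fiber electrical behaviour scales with geometry: the ionic diffusion
timescale grows quadratically with fiber length (tau_d = k L^2 / D) and the
network conductance index grows with the number of junctions per unit
length (G = k N / L).  Both laws are proportionalities; the constants
default to 1 so only ratios are meaningful, which is how they are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InvalidParameterError, RecordingParseError


@dataclass(frozen=True)
class FiberGeometry:
    """Fiber dimensions (um) and effective ion diffusion coefficient (um^2/s)."""

    length: float
    width: float
    d_coeff: float = 1.0

    def __post_init__(self) -> None:
        if not (self.length >= 0 and self.width > 0):
            raise InvalidParameterError("length must be >= 0 and width > 0")
        if not self.d_coeff > 0:
            raise InvalidParameterError("d_coeff must be > 0")


@dataclass(frozen=True)
class NetworkTopology:
    """Fiber-network topology: junction count and mean fiber length (um)."""

    n_junctions: int
    mean_length: float

    def __post_init__(self) -> None:
        if self.n_junctions < 0:
            raise InvalidParameterError("n_junctions must be >= 0")
        if not self.mean_length > 0:
            raise InvalidParameterError("mean_length must be > 0")


def aspect_ratio(geom: FiberGeometry) -> float:
    """Length-to-width ratio; scale invariant."""
    return geom.length / geom.width


def diffusion_timescale(geom: FiberGeometry, k: float = 1.0) -> float:
    """Relative ionic diffusion timescale k L^2 / D (s for k=1, SI-consistent D)."""
    return k * geom.length**2 / geom.d_coeff


def conductance_index(topo: NetworkTopology, k: float = 1.0) -> float:
    """Relative network conductance index k N / L."""
    return k * topo.n_junctions / topo.mean_length


def read_dimension_table(path: str | Path) -> pd.DataFrame:
    """Read a dimension table CSV: id,kind,length_um,width_um[,n_junctions]."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise RecordingParseError(f"cannot parse dimension table {path}: {exc}") from exc
    required = {"id", "kind", "length_um", "width_um"}
    missing = required - set(df.columns)
    if missing:
        raise RecordingParseError(f"dimension table missing columns: {sorted(missing)}")
    return df


def summarize_dimensions(df: pd.DataFrame) -> pd.DataFrame:
    """Aspect ratio and relative diffusion timescale per tabulated structure."""
    out = df.copy()
    out["aspect_ratio"] = [
        aspect_ratio(FiberGeometry(row.length_um, row.width_um))
        for row in df.itertuples()
    ]
    out["tau_d_rel"] = [
        diffusion_timescale(FiberGeometry(row.length_um, row.width_um))
        for row in df.itertuples()
    ]
    if "n_junctions" in df.columns:
        out["conductance_index"] = [
            conductance_index(NetworkTopology(int(row.n_junctions), row.length_um))
            for row in df.itertuples()
        ]
    return out
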