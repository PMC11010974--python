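"""Six-step pre-gating of WBC events down to capped CD34+ cells.

The sequence: (1) FSC vs SSC scatter gate, (2) CD45 vs SSC gate,
(3) doublet exclusion on the FSC-A/FSC-H ratio, (4) dead-cell exclusion on
the viability dye, (5) a gate of interest (GOI) polygon that removes the
granulocyte cloud, and (6) selection of CD34-positive events. Patients with
large CD34+ yields are down-sampled to a fixed cap so no single sample
dominates the merged embedding.

Polygon membership is boundary-inclusive and uses the even-odd rule
(delegated to shapely on a validated simple polygon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .channels import CHANNELS
from .errors import ChannelMapError, GateError

__all__ = [
    "PolygonGate",
    "GateSequenceReport",
    "apply_polygon_gate",
    "exclude_doublets",
    "select_viable",
    "select_cd34_positive",
    "cap_cells",
    "pregate_patient",
]


@dataclass(frozen=True)
class PolygonGate:
    """Named closed polygon in a 2-D channel plane.

    Vertices are ordered; the polygon is implicitly closed (last vertex
    connects back to the first) and must be simple.
    """

    name: str
    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise GateError(
                f"gate {self.name!r}: a closed polygon needs >= 3 vertices, "
                f"got {len(verts)}"
            )
        poly = shapely.Polygon(verts)
        if not poly.is_valid:
            raise GateError(f"gate {self.name!r}: polygon is not simple")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for point arrays."""
        return shapely.intersects_xy(self.polygon, np.asarray(x), np.asarray(y))


@dataclass
class GateSequenceReport:
    """Per-step bookkeeping of the gating sequence."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"step {name!r}: output {n_out} exceeds input {n_in}")
        self.steps.append((name, n_in, n_out))

    @property
    def final_count(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_in", "n_out"])


def _require(table: pd.DataFrame, *channels: str) -> None:
    missing = [c for c in channels if c not in table.columns]
    if missing:
        raise ChannelMapError(f"event table lacks channel(s): {missing}")


def apply_polygon_gate(table: pd.DataFrame, gate: PolygonGate) -> pd.DataFrame:
    """Retain events whose (x, y) lie inside or on the gate polygon."""
    _require(table, gate.x_channel, gate.y_channel)
    keep = gate.contains(table[gate.x_channel].to_numpy(), table[gate.y_channel].to_numpy())
    return table.loc[keep]


def exclude_doublets(
    table: pd.DataFrame, max_hw_ratio_deviation: float = 0.3
) -> pd.DataFrame:
    """Retain singlets: FSC-A within (1 ± deviation) × FSC-H.

    Events with nonpositive FSC-H cannot form a ratio and are dropped.
    """
    _require(table, "FSC-A", "FSC-H")
    h = table["FSC-H"].to_numpy(dtype=float)
    a = table["FSC-A"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(h > 0, a / np.where(h > 0, h, 1.0), np.inf)
    keep = (h > 0) & (np.abs(ratio - 1.0) <= max_hw_ratio_deviation)
    return table.loc[keep]


def select_viable(table: pd.DataFrame, viability_threshold: float) -> pd.DataFrame:
    """Retain live events: viability-dye intensity strictly below threshold.

    Events exactly at the threshold count as dead (conservative convention).
    """
    _require(table, "VIABILITY")
    return table.loc[table["VIABILITY"].to_numpy() < viability_threshold]


def select_cd34_positive(
    table: pd.DataFrame, goi_gate: PolygonGate, cd34_threshold: float
) -> pd.DataFrame:
    """Apply the gate of interest, then keep events with CD34 above threshold."""
    _require(table, "CD34")
    gated = apply_polygon_gate(table, goi_gate)
    return gated.loc[gated["CD34"].to_numpy() > cd34_threshold]


def cap_cells(table: pd.DataFrame, cap: int, seed: int) -> pd.DataFrame:
    """Randomly down-sample to at most ``cap`` events (order-preserving).

    Tables at or below the cap pass through unchanged; larger tables yield a
    uniform random subset of exactly ``cap`` rows, reproducible under
    ``seed``.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if len(table) <= cap:
        return table
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(len(table), size=cap, replace=False))
    return table.iloc[pick]


def pregate_patient(
    table: pd.DataFrame,
    scatter_gate: PolygonGate,
    cd45_gate: PolygonGate,
    goi_gate: PolygonGate,
    viability_threshold: float,
    cd34_threshold: float,
    cap: int,
    seed: int,
    max_hw_ratio_deviation: float = 0.3,
) -> tuple[pd.DataFrame, GateSequenceReport]:
    """Run the full six-step sequence plus the cap on one patient table."""
    _require(table, *CHANNELS)
    report = GateSequenceReport()
    steps = [
        ("fsc_ssc", lambda t: apply_polygon_gate(t, scatter_gate)),
        ("cd45_ssc", lambda t: apply_polygon_gate(t, cd45_gate)),
        ("singlets", lambda t: exclude_doublets(t, max_hw_ratio_deviation)),
        ("viable", lambda t: select_viable(t, viability_threshold)),
        ("goi", lambda t: apply_polygon_gate(t, goi_gate)),
        ("cd34_positive", lambda t: t.loc[t["CD34"].to_numpy() > cd34_threshold]),
        ("cap", lambda t: cap_cells(t, cap, seed)),
    ]
    out = table
    for name, step in steps:
        n_in = len(out)
        out = step(out)
        report.record(name, n_in, len(out))
    return out, report
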