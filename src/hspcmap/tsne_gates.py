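"""Polygon gates on the t-SNE plane and HSPC phenotype assignment.

Gates are drawn once (on the remission-only view of a reference embedding)
and transferred verbatim — same vertices — to the combined and
active-disease views, so per-gate group contributions are comparable.
Each gate is then summarized by five-number statistics of the scaled marker
intensities and assigned an HSPC phenotype from its gate-level marker means
using the canonical CD34/CD38/CD45RA/CD123 combinations:

====================  ==========================================
HSC/MPP               CD34+ CD38−  CD45RA−
CLP                   CD34+ CD38−  CD45RA+
CMP                   CD34+ CD38+  CD45RA−  CD123 low
MEP                   CD34+ CD38+  CD45RA−  CD123−
GMP                   CD34+ CD38+  CD45RA+  CD123+
Other                 any remaining combination
====================  ==========================================

"low" means weakly positive: above the negativity cutoff but below a second
upper bound; in the CD45RA+ branch both "low" and bright CD123 count as
positive. HSC and MPP are merged (distinguishing them needs CD90, which is
not in the panel). PD-L1 is carried in the summaries but takes no part in
the decision table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import (
    CLASSIFICATION_MARKERS,
    GROUP_AD,
    GROUP_COL,
    GROUP_CR,
    MARKERS,
    TSNE1,
    TSNE2,
)
from .errors import GateAmbiguityError
from .pregating import PolygonGate

__all__ = [
    "TsneGateSet",
    "MarkerThresholds",
    "GateSummary",
    "UNGATED",
    "CELL_TYPES",
    "assign_gate_membership",
    "summarize_gate",
    "classify_hspc",
    "composition_report",
    "propose_gates",
]

UNGATED = "ungated"
CELL_TYPES = ("HSC/MPP", "CLP", "CMP", "MEP", "GMP", "Other")


@dataclass(frozen=True)
class TsneGateSet:
    """Named, disjoint polygon gates in (tSNE1, tSNE2) coordinates."""

    gates: dict[str, PolygonGate]
    provenance: str = ""

    @classmethod
    def from_vertices(
        cls, vertices: dict[str, list], provenance: str = ""
    ) -> "TsneGateSet":
        gates = {
            name: PolygonGate(name=name, x_channel=TSNE1, y_channel=TSNE2,
                              vertices=tuple((v[0], v[1]) for v in verts))
            for name, verts in vertices.items()
        }
        return cls(gates=gates, provenance=provenance)

    def to_vertices(self) -> dict[str, list[list[float]]]:
        return {n: [list(v) for v in g.vertices] for n, g in self.gates.items()}


@dataclass(frozen=True)
class MarkerThresholds:
    """Scaled-intensity cutoffs separating negative from positive calls.

    ``positive`` maps each marker to its negativity cutoff on the scaled
    (asinh) axis; ``cd123_low_upper`` closes the CD123 "low" band.
    """

    positive: dict[str, float]
    cd123_low_upper: float

    def __post_init__(self) -> None:
        missing = set(CLASSIFICATION_MARKERS) - set(self.positive)
        if missing:
            raise ValueError(f"thresholds missing marker(s): {sorted(missing)}")
        if self.cd123_low_upper <= self.positive["CD123"]:
            raise ValueError("cd123_low_upper must exceed the CD123 negativity cutoff")

    @classmethod
    def from_raw(
        cls,
        raw_positive: dict[str, float],
        raw_cd123_low_upper: float,
        cofactor: float,
    ) -> "MarkerThresholds":
        """Build scaled thresholds from raw-intensity cutoffs (asinh/cofactor)."""
        return cls(
            positive={m: float(np.arcsinh(v / cofactor)) for m, v in raw_positive.items()},
            cd123_low_upper=float(np.arcsinh(raw_cd123_low_upper / cofactor)),
        )

    def call(self, marker: str, mean: float) -> str:
        """'+'/'-' call for a marker mean; CD123 gets the three-level call."""
        if marker == "CD123":
            if mean <= self.positive["CD123"]:
                return "-"
            return "low" if mean <= self.cd123_low_upper else "+"
        return "+" if mean > self.positive[marker] else "-"


def assign_gate_membership(matrix: pd.DataFrame, gates: TsneGateSet) -> pd.Series:
    """Label each embedded cell with its containing gate or ``"ungated"``.

    Membership depends only on coordinates and vertices — applying
    CR-drawn gates to the AD view uses the identical polygons. Gates must
    be disjoint; a cell claimed by two gates raises
    :class:`GateAmbiguityError` naming the pair.
    """
    x = matrix[TSNE1].to_numpy(dtype=float)
    y = matrix[TSNE2].to_numpy(dtype=float)
    labels = np.full(len(matrix), UNGATED, dtype=object)
    claimed = np.zeros(len(matrix), dtype=bool)
    for name, gate in gates.gates.items():
        inside = gate.contains(x, y)
        clash = inside & claimed
        if clash.any():
            i = int(np.flatnonzero(clash)[0])
            raise GateAmbiguityError(
                f"cell {i} falls into both gate {labels[i]!r} and gate {name!r}; "
                "gates must be disjoint"
            )
        labels[inside] = name
        claimed |= inside
    return pd.Series(labels, index=matrix.index, name="gate")


@dataclass
class GateSummary:
    """Marker statistics and group composition of one embedding gate."""

    name: str
    n_total: int
    n_cr: int
    n_ad: int
    marker_stats: pd.DataFrame  # rows: (group, marker); cols: count/mean/...
    pct_of_cr: float  # % of all CR cells falling in this gate
    pct_of_ad: float
    cr_ad_ratio: float | None  # pct_of_cr / pct_of_ad; None when undefined
    ad_dominated: bool
    cell_type: str
    empty: bool = False


def _five_number(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {
        "count": values.size,
        "mean": values.mean(),
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_lo": lo,
        "whisker_hi": hi,
    }


def summarize_gate(
    matrix: pd.DataFrame,
    membership: pd.Series,
    gate_name: str,
    thresholds: MarkerThresholds,
) -> GateSummary:
    """Five-number marker summaries per group plus the phenotype call.

    The phenotype is assigned from the gate-level marker means pooled over
    both groups. The CR:AD ratio compares within-group percentage
    distributions (share of each group's cells falling into this gate);
    it is flagged undefined when the gate holds no AD cells.
    """
    in_gate = membership == gate_name
    cells = matrix.loc[in_gate]
    n_cr_total = int((matrix[GROUP_COL] == GROUP_CR).sum())
    n_ad_total = int((matrix[GROUP_COL] == GROUP_AD).sum())
    if len(cells) == 0:
        return GateSummary(
            name=gate_name, n_total=0, n_cr=0, n_ad=0,
            marker_stats=pd.DataFrame(), pct_of_cr=0.0, pct_of_ad=0.0,
            cr_ad_ratio=None, ad_dominated=False, cell_type="", empty=True,
        )
    n_cr = int((cells[GROUP_COL] == GROUP_CR).sum())
    n_ad = int((cells[GROUP_COL] == GROUP_AD).sum())
    rows = []
    for group in (GROUP_CR, GROUP_AD):
        sub = cells.loc[cells[GROUP_COL] == group]
        for marker in MARKERS:
            if len(sub) == 0:
                continue
            rows.append(
                {"group": group, "marker": marker,
                 **_five_number(sub[marker].to_numpy(dtype=float))}
            )
    stats = pd.DataFrame(rows).set_index(["group", "marker"]) if rows else pd.DataFrame()

    pct_cr = 100.0 * n_cr / n_cr_total if n_cr_total else 0.0
    pct_ad = 100.0 * n_ad / n_ad_total if n_ad_total else 0.0
    ratio = pct_cr / pct_ad if pct_ad > 0 else None
    means = {m: float(cells[m].mean()) for m in MARKERS}
    return GateSummary(
        name=gate_name, n_total=len(cells), n_cr=n_cr, n_ad=n_ad,
        marker_stats=stats, pct_of_cr=pct_cr, pct_of_ad=pct_ad,
        cr_ad_ratio=ratio,
        ad_dominated=(ratio is not None and ratio < 1.0) or (ratio is None and n_ad > 0),
        cell_type=classify_hspc(means, thresholds),
    )


def classify_hspc(means: dict[str, float], thresholds: MarkerThresholds) -> str:
    """Map gate-level marker means to an HSPC phenotype label.

    Implements the decision table in the module docstring; every
    combination of calls maps to exactly one of :data:`CELL_TYPES`. Cells
    reach this point pre-gated CD34+, so a CD34 mean below its cutoff only
    triggers a consistency warning.
    """
    if thresholds.call("CD34", means["CD34"]) == "-":
        warnings.warn(
            "gate-level CD34 mean falls below the CD34 cutoff although cells "
            "were pre-gated CD34+",
            stacklevel=2,
        )
    cd38 = thresholds.call("CD38", means["CD38"])
    cd45ra = thresholds.call("CD45RA", means["CD45RA"])
    cd123 = thresholds.call("CD123", means["CD123"])
    if cd38 == "-":
        return "CLP" if cd45ra == "+" else "HSC/MPP"
    if cd45ra == "-":
        return {"-": "MEP", "low": "CMP", "+": "Other"}[cd123]
    return "Other" if cd123 == "-" else "GMP"


def composition_report(
    matrix: pd.DataFrame, membership: pd.Series, cell_types: dict[str, str]
) -> pd.DataFrame:
    """Per-group percentage of gated CD34+ cells by assigned phenotype.

    Rows are groups, columns the phenotype labels (including "Other");
    percentages are taken over each group's gated (classified) cells and sum
    to 100 per row. Ungated cells are outside the classification.
    """
    gated = membership != UNGATED
    frame = pd.DataFrame(
        {
            GROUP_COL: matrix.loc[gated, GROUP_COL].to_numpy(),
            "cell_type": membership.loc[gated].map(cell_types).to_numpy(),
        }
    )
    counts = frame.value_counts([GROUP_COL, "cell_type"]).unstack(fill_value=0)
    counts = counts.reindex(columns=CELL_TYPES, fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def plot_gate_boxplots(
    matrix: pd.DataFrame,
    membership: pd.Series,
    gate_names: list[str],
    thresholds: MarkerThresholds,
    path,
) -> None:
    """Render per-gate boxplots of scaled marker intensities to a file.

    One panel per gate, one box per marker; the CD38 negativity cutoff is
    drawn as a reference line (the axis shared by all cutoffs up to marker).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, max(len(gate_names), 1), figsize=(3 * max(len(gate_names), 1), 3),
        squeeze=False,
    )
    for ax, name in zip(axes[0], gate_names):
        cells = matrix.loc[membership == name]
        ax.boxplot(
            [cells[m].to_numpy(dtype=float) for m in MARKERS],
            tick_labels=list(MARKERS), showfliers=False,
        )
        ax.axhline(thresholds.positive["CD38"], ls="--", lw=0.8, color="gray")
        ax.set_title(name, fontsize=9)
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding_density(
    matrix: pd.DataFrame, path, gates: "TsneGateSet | None" = None
) -> None:
    """Render the embedding as a 2-D density plot (PNG/SVG by extension).

    The density is normalized to the per-plot maximum; axis labels are
    omitted, as t-SNE coordinates carry no metric meaning. Gate outlines
    are overlaid when a gate set is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = matrix[TSNE1].to_numpy(dtype=float)
    y = matrix[TSNE2].to_numpy(dtype=float)
    hist, xe, ye = np.histogram2d(x, y, bins=100)
    from scipy import ndimage

    dens = ndimage.gaussian_filter(hist, 1.0)
    if dens.max() > 0:
        dens = dens / dens.max()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(
        dens.T, origin="lower", extent=(xe[0], xe[-1], ye[0], ye[-1]),
        cmap="viridis", aspect="auto",
    )
    if gates is not None:
        for name, gate in gates.gates.items():
            verts = np.array(gate.vertices + (gate.vertices[0],))
            ax.plot(verts[:, 0], verts[:, 1], lw=0.8, color="white")
            cx, cy = np.mean(gate.vertices, axis=0)
            ax.annotate(name, (cx, cy), color="white", fontsize=6, ha="center")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def propose_gates(
    matrix: pd.DataFrame,
    n_bins: int = 100,
    smooth_bins: float = 2.0,
    min_cells: int = 20,
    provenance: str = "watershed-proposal",
) -> TsneGateSet:
    """Propose polygon gates from local density maxima (convenience helper).

    Non-canonical: gates in this workflow are drawn and versioned by the
    analyst; this watershed segmentation of the embedding density merely
    offers a starting point. Each basin with at least ``min_cells`` cells
    becomes the convex hull of its cells, hulls are made pairwise disjoint
    by subtracting earlier gates and shrinking slightly.
    """
    import shapely
    from scipy import ndimage
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    x = matrix[TSNE1].to_numpy(dtype=float)
    y = matrix[TSNE2].to_numpy(dtype=float)
    hist, xe, ye = np.histogram2d(x, y, bins=n_bins)
    dens = ndimage.gaussian_filter(hist, smooth_bins)
    peaks = peak_local_max(dens, min_distance=3, exclude_border=False)
    markers = np.zeros_like(dens, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    basins = watershed(-dens, markers, mask=dens > 0)

    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, n_bins - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, n_bins - 1)
    cell_basin = basins[ix, iy]

    gates: dict[str, PolygonGate] = {}
    occupied = None
    k = 0
    for basin_id in range(1, basins.max() + 1):
        members = cell_basin == basin_id
        if members.sum() < min_cells:
            continue
        hull = shapely.MultiPoint(np.column_stack([x[members], y[members]])).convex_hull
        if occupied is not None:
            hull = hull.difference(occupied)
        hull = hull.buffer(-1e-9)
        if hull.is_empty or hull.geom_type != "Polygon" or hull.area <= 0:
            continue
        k += 1
        verts = tuple(hull.exterior.coords)[:-1]
        gates[f"gate {k}"] = PolygonGate(
            name=f"gate {k}", x_channel=TSNE1, y_channel=TSNE2, vertices=verts
        )
        occupied = hull if occupied is None else occupied.union(hull)
    return TsneGateSet(gates=gates, provenance=provenance)
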