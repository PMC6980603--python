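"""Collision-potential surfaces, strike susceptibility and zone counts.

The fitted model's per-cell collision potential CP (a probability in
[0, 1]) is combined with the relative breeding-pair density
BPDrel = BPDobs / BPDmax (BPDmax = 51, the lower border of the highest
density class) into the strike-susceptibility index

    SC = CP * BPDrel * 100      (percent, in [0, 100])

which is then binned into five susceptibility classes and intersected
with the turbine table to count planned turbines per zone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .brt import BRTModel, predict
from .delv import DELVStack
from .grid import GridSpec, Raster
from .landscape import BP_LOWER_BORDERS, BreedingDensityMap

BPD_MAX: int = max(BP_LOWER_BORDERS)  # 51, lower border of the top class

SC_CLASS_LABELS: tuple[str, ...] = ("0-20", "21-40", "41-60", "61-80", "81-100")
_SC_BIN_EDGES = (20.0, 40.0, 60.0, 80.0)


def predict_cp_raster(model: BRTModel, stack: DELVStack) -> Raster:
    """Per-cell collision potential from the DELV stack.

    The model's variables must be a subset of the stack's class names;
    cells with NaN in any used feature propagate NaN.
    """
    missing = [v for v in model.var_names if v not in stack.class_names]
    if missing:
        raise ValueError(f"stack lacks model variables: {', '.join(missing)}")
    X = stack.features_matrix(model.var_names)
    bad = np.isnan(X).any(axis=1)
    cp = np.full(X.shape[0], np.nan)
    if (~bad).any():
        cp[~bad] = predict(model, X[~bad], scale="probability")
    return Raster(stack.grid, cp.reshape(stack.grid.shape), name="collision_potential")


def relative_density(density_map: BreedingDensityMap, grid: GridSpec) -> Raster:
    """Per-cell BPDrel = lower class border of the covering quadrant / 51.

    Cells not covered by any quadrant get 0 (no breeding pairs recorded).
    """
    xs, ys = grid.cell_centers()
    lower = density_map.lower_border_at(xs.ravel(), ys.ravel()).reshape(grid.shape)
    return Raster(grid, lower / float(BPD_MAX), name="bpd_rel")


def strike_susceptibility(cp: Raster, bpd_rel: Raster) -> Raster:
    """SC = CP * BPDrel * 100, cellwise, on aligned grids."""
    if cp.grid != bpd_rel.grid:
        raise ValueError("collision-potential and density grids do not match")
    return Raster(cp.grid, cp.values * bpd_rel.values * 100.0, name="strike_susceptibility")


def classify_sc(sc: Raster) -> Raster:
    """Bin SC into 5 classes: [0,20], (20,40], (40,60], (60,80], (80,100].

    Returns an integer raster with classes 1..5 (NaN cells get 0).
    """
    values = sc.values
    cls = np.digitize(values, _SC_BIN_EDGES, right=True) + 1
    cls = np.where(np.isnan(values), 0, cls).astype(np.int16)
    return Raster(sc.grid, cls, name="sc_class")


def _trunc2(x: float) -> float:
    """Truncate (floor) to 2 decimals, the convention of the zone table."""
    return math.floor(x * 100.0 + 1e-9) / 100.0


@dataclass
class ZoneCountTable:
    """Turbines per planning status per susceptibility class.

    table has one row per (status, class) with count and percent of the
    status total (percent truncated to 2 decimals); above60 summarises
    turbines in classes above 60% susceptibility across all statuses.
    """

    table: pd.DataFrame
    status_totals: dict[str, int]
    above60_count: int
    above60_percent: float

    @classmethod
    def from_counts(cls, counts_by_status: dict[str, list[int]]) -> "ZoneCountTable":
        """Build the summary from raw per-class counts per status."""
        rows = []
        totals = {}
        above60 = 0
        grand_total = 0
        for status in sorted(counts_by_status):
            counts = list(counts_by_status[status])
            if len(counts) != len(SC_CLASS_LABELS):
                raise ValueError(
                    f"expected {len(SC_CLASS_LABELS)} class counts for {status!r}"
                )
            total = int(sum(counts))
            totals[status] = total
            grand_total += total
            above60 += int(counts[3] + counts[4])
            for label, count in zip(SC_CLASS_LABELS, counts):
                pct = _trunc2(100.0 * count / total) if total else 0.0
                rows.append(
                    {"status": status, "sc_class": label, "count": int(count), "percent": pct}
                )
        pct60 = _trunc2(100.0 * above60 / grand_total) if grand_total else 0.0
        return cls(pd.DataFrame(rows), totals, above60, pct60)

    @property
    def grand_total(self) -> int:
        return int(sum(self.status_totals.values()))

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["percent"] = out["percent"].map(lambda v: f"{v:.2f}")
        totals = pd.DataFrame(
            [
                {
                    "status": "all(>60%)",
                    "sc_class": ">60",
                    "count": self.above60_count,
                    "percent": f"{self.above60_percent:.2f}",
                }
            ]
        )
        pd.concat([out, totals], ignore_index=True).to_csv(path, index=False)


def count_turbines_by_class(
    turbines: pd.DataFrame, class_raster: Raster, statuses=None
) -> ZoneCountTable:
    """Count turbines per status per susceptibility class.

    Uses the susceptibility class of the cell containing each turbine;
    raises for turbines outside the raster extent.  statuses restricts
    (and orders) the statuses reported; by default every status present
    in the table is reported.
    """
    ids = turbines["id"].tolist() if "id" in turbines.columns else None
    cls = class_raster.sample(
        turbines["x"].to_numpy(), turbines["y"].to_numpy(), ids=ids
    ).astype(int)
    if np.any(cls == 0):
        i = int(np.argmax(cls == 0))
        label = ids[i] if ids is not None else f"index {i}"
        raise ValueError(f"turbine {label} falls on a no-data susceptibility cell")
    if statuses is None:
        statuses = sorted(turbines["status"].unique())
    counts = {}
    status_arr = turbines["status"].to_numpy()
    for status in statuses:
        sel = cls[status_arr == status]
        counts[status] = [int((sel == k).sum()) for k in range(1, 6)]
    return ZoneCountTable.from_counts(counts)


def point_density_raster(
    points: pd.DataFrame, bandwidth: float, grid: GridSpec
) -> Raster:
    """Gaussian-kernel smoothed point counts per cell.

    bandwidth is the kernel standard deviation in metres.  The raster
    integral (sum over cells) approximates the number of points, exactly
    so for points far from the edges.  An empty point set yields a zero
    raster with a warning.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(points) == 0:
        warnings.warn("empty point set: returning a zero density raster", stacklevel=2)
        return Raster(grid, np.zeros(grid.shape), name="point_density")
    x0, y0, x1, y1 = grid.bounds
    counts, _, _ = np.histogram2d(
        points["y"].to_numpy(),
        points["x"].to_numpy(),
        bins=(grid.n_rows, grid.n_cols),
        range=((y0, y1), (x0, x1)),
    )
    sigma_cells = bandwidth / grid.cell_size
    density = ndimage.gaussian_filter(counts, sigma=sigma_cells, mode="constant")
    return Raster(grid, density, name="point_density")
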