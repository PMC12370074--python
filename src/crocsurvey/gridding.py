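"""Checkerboard grid construction, spatial replicates and encounter histories.

The survey design divides a river ribbon (a projected-meter polygon) into a
lattice of square cells, keeps alternate cells in a checkerboard pattern, and
treats each ~200 m straight flight-path segment crossing a cell as one
spatial replicate (sampling occasion). Detections are georeferenced points;
after de-duplication of re-captures of the same animal across overlapping
image frames, each point is attributed to a cell (half-open membership) and
to the nearest replicate segment within that cell, yielding a cells x
replicates encounter history of 0 / 1 / not-surveyed.

All coordinates are projected meters (any UTM-like CRS); this module never
reprojects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon, box
from shapely.ops import substring

logger = logging.getLogger(__name__)

MAX_REPLICATES = 5
#: sentinel used in CSV round-trips for replicate slots that were never flown
NOT_SURVEYED = "NA"


class ConfigurationError(ValueError):
    """Invalid geometry or parameters for grid construction."""


@dataclass
class GridCell:
    """One retained checkerboard cell (axis-aligned square, projected meters)."""

    cell_id: int
    row: int
    col: int
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def area_km2(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0) / 1e6

    @property
    def geometry(self) -> Polygon:
        return box(self.x0, self.y0, self.x1, self.y1)

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership [x0, x1) x [y0, y1): boundary points belong
        to at most one cell."""
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class Grid:
    """Retained cells plus the lattice frame needed for point lookup."""

    cells: list[GridCell]
    origin: tuple[float, float]
    cell_size_m: float
    _index: dict[tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {(c.row, c.col): c.cell_id for c in self.cells}
        self._by_id = {c.cell_id: c for c in self.cells}

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def cell(self, cell_id: int) -> GridCell:
        return self._by_id[cell_id]

    def locate(self, x: float, y: float) -> int | None:
        """Cell id containing (x, y) under half-open membership, or None."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size_m))
        row = int(np.floor((y - self.origin[1]) / self.cell_size_m))
        return self._index.get((row, col))


@dataclass(frozen=True)
class DetectionPoint:
    """A single deduplicated animal detection in projected meters."""

    species: str
    x: float
    y: float
    mission_id: int
    path_id: int
    floating: bool = False


POINT_COLUMNS = ["species", "x", "y", "mission_id", "path_id", "floating"]


def points_to_frame(points: list[DetectionPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points], columns=POINT_COLUMNS)


@dataclass
class ReplicateSegment:
    """A ~200 m piece of flight path inside one cell: one sampling occasion."""

    path_index: int
    seg_index: int
    geometry: LineString


@dataclass
class EncounterHistory:
    """Detection/non-detection matrix over cells x replicate slots.

    ``values`` is float with 1.0 = detected, 0.0 = surveyed but not
    detected, NaN = replicate slot not surveyed. Not-surveyed slots are
    always trailing within a row (a cell has its first k slots surveyed).
    """

    species: str
    values: np.ndarray  # (n_cells, MAX_REPLICATES)
    cell_ids: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> np.ndarray:
        """Surveyed replicate count per cell."""
        return (~np.isnan(self.values)).sum(axis=1)

    def union(self, other: "EncounterHistory", species: str = "combined") -> "EncounterHistory":
        """Cell-wise OR of two aligned histories (the combined-species history)."""
        if not np.array_equal(self.cell_ids, other.cell_ids):
            raise ValueError("histories are not aligned on the same cells")
        if not np.array_equal(np.isnan(self.values), np.isnan(other.values)):
            raise ValueError("histories have different survey patterns")
        vals = np.fmax(self.values, other.values)
        return EncounterHistory(species, vals, self.cell_ids.copy())

    def to_frame(self, na_string: str = NOT_SURVEYED) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            columns=[f"rep_{j + 1}" for j in range(self.values.shape[1])],
        )
        df = df.map(lambda v: na_string if np.isnan(v) else int(v))
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def to_csv(self, path, na_string: str = NOT_SURVEYED) -> None:
        self.to_frame(na_string).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species: str, na_string: str = NOT_SURVEYED) -> "EncounterHistory":
        df = pd.read_csv(path, na_values=[na_string], keep_default_na=False)
        cell_ids = df["cell_id"].to_numpy(dtype=int)
        vals = df.drop(columns=["cell_id"]).to_numpy(dtype=float)
        return cls(species, vals, cell_ids)


def build_checkerboard_grid(
    river_ribbon: Polygon,
    cell_size_m: float = 200.0,
    coverage_threshold: float = 0.5,
    parity: int = 0,
    checkerboard: bool = True,
) -> Grid:
    """Lay a square lattice over the ribbon and keep alternate covered cells.

    A lattice cell is retained when (a) the ribbon covers at least
    ``coverage_threshold`` of its area and (b) ``(row + col) % 2 == parity``
    (the checkerboard rule; pass ``checkerboard=False`` to keep every
    covered cell). The lattice is anchored at the ribbon's lower-left
    bound, so the construction is deterministic.
    """
    if river_ribbon is None or river_ribbon.is_empty:
        raise ConfigurationError("river ribbon polygon is empty")
    if cell_size_m <= 0:
        raise ConfigurationError("cell_size_m must be positive")
    minx, miny, maxx, maxy = river_ribbon.bounds
    n_cols = max(1, int(np.ceil((maxx - minx) / cell_size_m - 1e-9)))
    n_rows = max(1, int(np.ceil((maxy - miny) / cell_size_m - 1e-9)))
    cells: list[GridCell] = []
    cell_area = cell_size_m * cell_size_m
    for row in range(n_rows):
        for col in range(n_cols):
            if checkerboard and (row + col) % 2 != parity % 2:
                continue
            x0 = minx + col * cell_size_m
            y0 = miny + row * cell_size_m
            square = box(x0, y0, x0 + cell_size_m, y0 + cell_size_m)
            covered = river_ribbon.intersection(square).area
            if covered / cell_area >= coverage_threshold:
                cells.append(
                    GridCell(len(cells), row, col, x0, y0, x0 + cell_size_m, y0 + cell_size_m)
                )
    if not cells:
        logger.warning(
            "no lattice cell reaches %.0f%% ribbon coverage; grid is empty",
            100 * coverage_threshold,
        )
    return Grid(cells, (minx, miny), cell_size_m)


def assign_replicates(
    paths: list[LineString],
    grid: Grid,
    segment_length_m: float = 200.0,
    max_replicates: int = MAX_REPLICATES,
) -> dict[int, list[ReplicateSegment]]:
    """Split each flight path's intersection with each cell into ~200 m
    segments and register them as the cell's replicate slots.

    Segments are ordered by path index then chainage along the path; at most
    ``max_replicates`` slots are kept per cell (overflow dropped with a
    warning, matching the 1-5 replicate design).
    """
    if paths:
        gxmin = min(p.bounds[0] for p in paths)
        gxmax = max(p.bounds[2] for p in paths)
        cells_bounds = [
            min((c.x0 for c in grid.cells), default=0),
            max((c.x1 for c in grid.cells), default=0),
        ]
        if grid.cells and (gxmin > cells_bounds[1] + 1e6 or gxmax < cells_bounds[0] - 1e6):
            logger.warning("paths and grid bounds are wildly disjoint; projection mismatch?")
    replicate_map: dict[int, list[ReplicateSegment]] = {c.cell_id: [] for c in grid.cells}
    for cell in grid.cells:
        cell_geom = cell.geometry
        for path_index, path in enumerate(paths):
            inter = path.intersection(cell_geom)
            if inter.is_empty:
                continue
            parts = [inter] if isinstance(inter, LineString) else [
                g for g in getattr(inter, "geoms", []) if isinstance(g, LineString)
            ]
            for part in parts:
                n_seg = max(1, int(np.ceil(part.length / segment_length_m - 1e-9)))
                for s in range(n_seg):
                    seg = substring(
                        part,
                        s * segment_length_m,
                        min((s + 1) * segment_length_m, part.length),
                    )
                    replicate_map[cell.cell_id].append(
                        ReplicateSegment(path_index, len(replicate_map[cell.cell_id]), seg)
                    )
    for cell_id, segs in replicate_map.items():
        if len(segs) > max_replicates:
            logger.warning(
                "cell %d has %d replicate segments; keeping the first %d",
                cell_id, len(segs), max_replicates,
            )
            replicate_map[cell_id] = segs[:max_replicates]
        for i, seg in enumerate(replicate_map[cell_id]):
            seg.seg_index = i
    return replicate_map


def dedupe_points(points: pd.DataFrame, radius_m: float = 5.0) -> pd.DataFrame:
    """Collapse same-species re-captures within ``radius_m`` to one point.

    Same-species points are single-linkage clustered at the given radius;
    each cluster is replaced by its centroid carrying the earliest mission
    (then path) id and that earliest point's floating flag. Cross-species
    points are never merged. The merge is iterated to a fixpoint so the
    operation is idempotent.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be non-negative")
    if points.empty:
        return points.copy()
    out = points.reset_index(drop=True).copy()
    while True:
        merged_any = False
        frames = []
        for _, sub in out.groupby("species", sort=True):
            sub = sub.reset_index(drop=True)
            xy = sub[["x", "y"]].to_numpy(dtype=float)
            parent = np.arange(len(sub))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            if radius_m > 0 and len(sub) > 1:
                tree = cKDTree(xy)
                for i, j in tree.query_pairs(radius_m):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
                        merged_any = True
            labels = np.array([find(i) for i in range(len(sub))])
            rows = []
            for lab in np.unique(labels):
                members = sub[labels == lab]
                first = members.sort_values(["mission_id", "path_id"]).iloc[0]
                rows.append(
                    {
                        "species": first["species"],
                        "x": members["x"].mean(),
                        "y": members["y"].mean(),
                        "mission_id": first["mission_id"],
                        "path_id": first["path_id"],
                        "floating": first["floating"],
                    }
                )
            frames.append(pd.DataFrame(rows, columns=POINT_COLUMNS))
        out = pd.concat(frames, ignore_index=True)
        if not merged_any:
            return out


def build_encounter_history(
    points: pd.DataFrame,
    grid: Grid,
    replicate_map: dict[int, list[ReplicateSegment]],
    species_filter: str,
) -> EncounterHistory:
    """Assemble the cells x replicates detection history for one species
    (or ``"combined"`` for all species pooled).

    A point contributes a 1 to the slot of the nearest replicate segment in
    its cell (ties broken by lower path then segment index). Points outside
    every retained cell are excluded and counted in the log, mirroring the
    field rule that detections beyond the habitat boundary are dropped.
    """
    cell_ids = np.array([c.cell_id for c in grid.cells], dtype=int)
    id_to_row = {cid: i for i, cid in enumerate(cell_ids)}
    values = np.full((len(cell_ids), MAX_REPLICATES), np.nan)
    for cid, segs in replicate_map.items():
        if cid in id_to_row:
            values[id_to_row[cid], : len(segs)] = 0.0
    if species_filter != "combined":
        points = points[points["species"] == species_filter]
    n_outside = 0
    for _, pt in points.iterrows():
        cid = grid.locate(float(pt["x"]), float(pt["y"]))
        if cid is None or cid not in id_to_row or not replicate_map.get(cid):
            n_outside += 1
            continue
        segs = replicate_map[cid]
        from shapely.geometry import Point as _P

        p = _P(float(pt["x"]), float(pt["y"]))
        dists = [(seg.geometry.distance(p), seg.path_index, seg.seg_index, k)
                 for k, seg in enumerate(segs)]
        _, _, _, slot = min(dists)
        values[id_to_row[cid], slot] = 1.0
    if n_outside:
        logger.info("%d detections fell outside every surveyed cell and were excluded", n_outside)
    surveyed = ~np.isnan(values)
    keep = surveyed.any(axis=1)
    return EncounterHistory(species_filter, values[keep], cell_ids[keep])


def grid_to_geojson(grid: Grid, properties: dict[int, dict] | None = None) -> dict:
    """Grid cells as a GeoJSON FeatureCollection of Polygon features."""
    feats = []
    for c in grid.cells:
        props = {"cell_id": c.cell_id, "row": c.row, "col": c.col, "area_km2": c.area_km2}
        if properties and c.cell_id in properties:
            props.update(properties[c.cell_id])
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [
                            [c.x0, c.y0],
                            [c.x1, c.y0],
                            [c.x1, c.y1],
                            [c.x0, c.y1],
                            [c.x0, c.y0],
                        ]
                    ],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def points_to_geojson(points: pd.DataFrame) -> dict:
    feats = []
    for _, pt in points.iterrows():
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(pt["x"]), float(pt["y"])]},
                "properties": {
                    "species": pt["species"],
                    "mission_id": int(pt["mission_id"]),
                    "path_id": int(pt["path_id"]),
                    "floating": bool(pt["floating"]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
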