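"""Aligned raster grids for niche modeling.

A study landscape is a stack of named environmental layers sharing one
grid geometry (all layers resampled to a common ~250 m projected grid).
Coordinates are projected meters; row 0 is the top of the grid.

Cell ownership uses half-open intervals [left, right) x (top, bottom]:
a point on a shared vertical edge belongs to the cell on the right, a
point on a shared horizontal edge to the cell below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class AlignmentError(ValueError):
    """Raised when layers do not share one grid geometry."""


class OutOfBoundsError(ValueError):
    """Raised when points fall outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an aligned raster grid (projected meters, row 0 at top)."""

    n_cols: int
    n_rows: int
    cell_size: float
    origin_x: float
    origin_y: float  # top-left corner
    nodata_flag: float = -9999.0
    crs_label: str = "UTM 48N"

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as (X, Y) arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cells owning the given points (edge -> right/lower)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        # row interval is (top - (r+1)*c, top - r*c]; a point on the shared
        # horizontal edge has (origin_y - y)/c integral and floors to the
        # lower cell's row, as required.
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        return row, col

    def approx_equal(self, other: "GridSpec", rtol: float = 1e-6) -> bool:
        if (self.n_cols, self.n_rows) != (other.n_cols, other.n_rows):
            return False
        scale = max(abs(self.cell_size), 1.0)
        return (
            abs(self.cell_size - other.cell_size) <= rtol * scale
            and abs(self.origin_x - other.origin_x) <= rtol * max(abs(self.origin_x), scale)
            and abs(self.origin_y - other.origin_y) <= rtol * max(abs(self.origin_y), scale)
        )


@dataclass
class Layer:
    """One named environmental layer on a grid.

    ``values`` is a masked array (mask True = nodata). Continuous layers
    hold floats; categorical layers hold integer codes.
    """

    name: str
    values: np.ma.MaskedArray
    kind: str = "continuous"  # "continuous" | "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        v = np.ma.asarray(self.values).astype(float)
        if v.ndim != 2:
            raise ValueError("layer values must be 2-D")
        if self.kind == "categorical":
            data = v.compressed()
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError(f"categorical layer {self.name!r} has non-integer codes")
        else:
            if not np.all(np.isfinite(v.compressed())):
                raise ValueError(f"continuous layer {self.name!r} has non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RasterStack:
    """Ordered collection of aligned layers with unique names.

    A cell masked in any layer is masked stack-wide for modeling.
    """

    spec: GridSpec
    layers: list[Layer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for l in self.layers:
            if l.shape != (self.spec.n_rows, self.spec.n_cols):
                raise AlignmentError(f"layer {l.name!r} shape {l.shape} does not match grid")

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def combined_mask(self) -> np.ndarray:
        """Boolean mask, True where ANY layer is nodata."""
        mask = np.zeros((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for l in self.layers:
            mask |= np.ma.getmaskarray(l.values)
        return mask

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack(self.spec, [self[n] for n in names])

    def add(self, layer: Layer) -> None:
        if layer.name in self:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        if layer.shape != (self.spec.n_rows, self.spec.n_cols):
            raise AlignmentError(f"layer {layer.name!r} shape {layer.shape} does not match grid")
        self.layers.append(layer)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path, name: str | None = None, kind: str = "continuous") -> tuple[GridSpec, Layer]:
    """Read one ESRI ASCII grid (.asc). Accepts xllcorner or xllcenter headers."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
            "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: missing required header field {key!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    else:
        raise IOError(f"{path}: missing corner/center header fields")
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise IOError(f"{path}: data shape {data.shape} does not match header")
    spec = GridSpec(
        n_cols=n_cols,
        n_rows=n_rows,
        cell_size=cell,
        origin_x=xll,
        origin_y=yll + n_rows * cell,
        nodata_flag=nodata,
    )
    values = np.ma.masked_values(data, nodata)
    import os

    layer_name = name if name is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return spec, Layer(layer_name, values, kind=kind)


def write_ascii_grid(path, spec: GridSpec, layer: Layer) -> None:
    """Write one layer as an ESRI ASCII grid."""
    filled = np.ma.filled(layer.values, spec.nodata_flag)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin_x!r}\n")
        fh.write(f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {spec.nodata_flag!r}\n")
        np.savetxt(fh, filled, fmt="%.10g")


def load_stack(paths: list, names: list[str] | None = None, kinds: list[str] | None = None) -> RasterStack:
    """Load aligned ASCII grids into one stack.

    Grids whose geometry differs from the first by more than 1e-6 relative
    tolerance are rejected with an :class:`AlignmentError` naming the layer.
    """
    if not paths:
        raise ValueError("no raster paths given")
    if names is not None and len(names) != len(paths):
        raise ValueError("names must match paths")
    if kinds is not None and len(kinds) != len(paths):
        raise ValueError("kinds must match paths")
    spec0: GridSpec | None = None
    layers: list[Layer] = []
    for idx, path in enumerate(paths):
        name = names[idx] if names is not None else None
        kind = kinds[idx] if kinds is not None else "continuous"
        spec, layer = read_ascii_grid(path, name=name, kind=kind)
        if spec0 is None:
            spec0 = spec
        elif not spec.approx_equal(spec0):
            raise AlignmentError(
                f"layer {layer.name!r} ({path}) is not aligned with the first grid: "
                f"{spec} vs {spec0}"
            )
        layers.append(layer)
    assert spec0 is not None
    return RasterStack(spec0, layers)


def write_stack(stack: RasterStack, directory, suffix: str = ".asc") -> list[str]:
    """Write every layer of a stack as <directory>/<name>.asc; returns paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for layer in stack.layers:
        path = os.path.join(str(directory), layer.name + suffix)
        write_ascii_grid(path, stack.spec, layer)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Derived-layer transforms


def aspect_index(aspect_degrees):
    """Fold compass aspect onto a 0-180 sun-exposure index: |aspect - 180|.

    0 = due south (adret), 180 = due north. Input must lie in [0, 360).
    """
    a = np.asarray(aspect_degrees, dtype=float)
    if np.any((a < 0) | (a >= 360)):
        raise ValueError("aspect must lie in [0, 360)")
    out = np.abs(a - 180.0)
    return float(out) if np.isscalar(aspect_degrees) else out


def distance_layer(targets: np.ndarray, spec: GridSpec, name: str = "distance") -> Layer:
    """Euclidean distance (m, cell center to cell center) to the nearest target cell.

    ``targets`` is a boolean grid marking target cells (e.g. rasterized
    rivers, roads or settlements); target cells get distance 0.
    """
    targets = np.asarray(targets, dtype=bool)
    if targets.shape != (spec.n_rows, spec.n_cols):
        raise ValueError("target grid shape does not match spec")
    if not targets.any():
        raise ValueError("distance_layer requires at least one target cell")
    dist = ndimage.distance_transform_edt(~targets, sampling=spec.cell_size)
    return Layer(name, np.ma.asarray(dist), kind="continuous")


def extract_values(stack: RasterStack, x, y, ids=None):
    """Cell values of the stack at points, one row per point.

    Returns ``(values, masked_flags)`` where ``values`` is a (n_points,
    n_layers) float array (NaN where a point hits nodata) and
    ``masked_flags`` marks rows hitting a cell masked in any layer.
    Raises :class:`OutOfBoundsError` listing offending point ids if any
    point falls outside the grid extent.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    row, col = stack.spec.index_of(x, y)
    bad = (row < 0) | (row >= stack.spec.n_rows) | (col < 0) | (col >= stack.spec.n_cols)
    if bad.any():
        if ids is None:
            ids = np.arange(len(x))
        bad_ids = [str(i) for i, b in zip(np.asarray(ids), bad) if b]
        raise OutOfBoundsError(f"points outside grid extent: {', '.join(bad_ids)}")
    values = np.empty((len(x), len(stack.layers)), dtype=float)
    flags = np.zeros(len(x), dtype=bool)
    for j, layer in enumerate(stack.layers):
        cell = layer.values[row, col]
        m = np.ma.getmaskarray(cell)
        values[:, j] = np.ma.filled(cell, np.nan)
        flags |= m
    return values, flags
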