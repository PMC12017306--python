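"""Morphology skeletons: SWC I/O, hull metrics, dendritic path lengths,
recording-field registration and hexagonal dendrite-density fits.

A skeleton is a soma-rooted tree of 3D nodes with SWC semantics.  The
hex-density fit tiles the planar-projected arbor with a hexagonal grid
(bipolar-cell axon-terminal spacing, 16 um center-to-center by default),
sums dendritic cable length per hexagon, and fits a truncated-Gaussian
radial profile whose scale and cutoff parameterize the ganglion-cell
dendritic pooling kernels of the population model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Polygon
from shapely.strtree import STRtree

__all__ = [
    "MorphologySkeleton",
    "DendriteDensityFit",
    "read_swc",
    "write_swc",
    "hull_metrics",
    "dendritic_distance",
    "register_field",
    "skeleton_template_stack",
    "hex_density_fit",
    "fit_radial_profile",
]


@dataclass
class MorphologySkeleton:
    """Soma-rooted neurite tree with SWC node semantics.

    ``ids``, ``xyz`` (um), ``radius`` and ``parent`` are parallel arrays;
    the root has parent -1.  ``region`` tags the retinal location class
    of synthetic cells ("nasal" or "temporal").
    """

    ids: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    soma_id: int = 1
    region: str = ""
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.radius = np.asarray(self.radius, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("node coordinates must be finite")
        if np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("skeleton must have exactly one root")

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            pos = {i: p for i, p in zip(self.ids, self.xyz)}
            g.add_nodes_from(self.ids)
            for i, par in zip(self.ids, self.parent):
                if par != -1:
                    g.add_edge(i, par,
                               weight=float(np.linalg.norm(pos[i] - pos[par])))
            if len(g) > 1 and not nx.is_tree(g):
                raise ValueError("skeleton graph must be a tree")
            self._graph = g
        return self._graph

    def segments(self) -> np.ndarray:
        """(n_edges, 2, 3) array of parent-child coordinate pairs."""
        idx = {i: k for k, i in enumerate(self.ids)}
        segs = [
            (self.xyz[idx[par]], self.xyz[idx[i]])
            for i, par in zip(self.ids, self.parent) if par != -1
        ]
        return np.asarray(segs)

    @property
    def total_length(self) -> float:
        segs = self.segments()
        if len(segs) == 0:
            return 0.0
        return float(np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1).sum())


def read_swc(path: str, region: str = "") -> MorphologySkeleton:
    """Read a standard 7-column SWC file (id, type, x, y, z, radius, parent)."""
    rows = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split()
            rows.append((int(p[0]), float(p[2]), float(p[3]), float(p[4]),
                         float(p[5]), int(p[6])))
    ids = np.array([r[0] for r in rows])
    xyz = np.array([r[1:4] for r in rows], dtype=float)
    radius = np.array([r[4] for r in rows])
    parent = np.array([r[5] for r in rows])
    soma = ids[parent == -1][0]
    return MorphologySkeleton(ids, xyz, radius, parent, soma_id=int(soma),
                              region=region)


def write_swc(path: str, skel: MorphologySkeleton) -> None:
    with open(path, "w") as f:
        f.write("# id type x y z radius parent\n")
        for i, p, r, par in zip(skel.ids, skel.xyz, skel.radius, skel.parent):
            t = 1 if i == skel.soma_id else 3
            f.write(f"{i} {t} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f} {r:.3f} {par}\n")


def hull_metrics(skel: MorphologySkeleton) -> tuple[float, float]:
    """Convex-hull area (um^2) of the z-projected skeleton and the diameter
    (um) of a circle of equivalent area."""
    pts = skel.xyz[:, :2]
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError("degenerate (collinear) skeleton") from e
    area = float(hull.volume)  # 2-D ConvexHull: volume == area
    return area, float(2.0 * np.sqrt(area / np.pi))


def dendritic_distance(skel: MorphologySkeleton, point: np.ndarray) -> float:
    """Path length (um) along the arbor from a point's nearest node to the soma."""
    point = np.asarray(point, dtype=float)
    node = int(skel.ids[np.argmin(np.linalg.norm(skel.xyz - point, axis=1))])
    try:
        return float(nx.shortest_path_length(skel.graph, node, skel.soma_id,
                                             weight="weight"))
    except nx.NetworkXNoPath as e:
        raise ValueError("node disconnected from soma") from e


def _rasterize(skel: MorphologySkeleton, origin: np.ndarray, shape: tuple,
               pixel_um: float, z_step: float) -> np.ndarray:
    """Deposit skeleton cable into a (z, y, x) occupancy stack."""
    stack = np.zeros(shape)
    nz, ny, nx_ = shape
    for a, b in skel.segments():
        n = max(2, int(np.linalg.norm(b - a) / (pixel_um / 2)) + 1)
        for p in np.linspace(a, b, n):
            ix = int(round((p[0] - origin[0]) / pixel_um))
            iy = int(round((p[1] - origin[1]) / pixel_um))
            iz = int(round((p[2] - origin[2]) / z_step))
            if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx_:
                stack[iz, iy, ix] += 1.0
    return stack


def _clip01_percentile(img: np.ndarray, lo: float = 20, hi: float = 90) -> np.ndarray:
    a, b = np.percentile(img, [lo, hi])
    if b <= a:
        return np.zeros_like(img)
    return np.clip((img - a) / (b - a), 0.0, 1.0)


def skeleton_template_stack(skel: MorphologySkeleton, expected_pos: np.ndarray,
                            pixel_um: float = 1.0, crop_um: float = 250.0,
                            z_step: float = 2.0, blur_um: float = 2.0,
                            n_layers: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Blurred, normalized skeleton raster around the expected position.

    Returns ``(stack, origin)`` with stack indexed (z, y, x) and origin the
    um-coordinate of voxel (0, 0, 0).
    """
    origin = np.asarray(expected_pos, dtype=float) - np.array(
        [crop_um / 2, crop_um / 2, (n_layers // 2) * z_step])
    shape = (n_layers, int(crop_um / pixel_um), int(crop_um / pixel_um))
    stack = _rasterize(skel, origin, shape, pixel_um, z_step)
    stack = gaussian_filter(stack,
                            sigma=(0.5, blur_um / pixel_um, blur_um / pixel_um))
    if stack.max() > 0:
        stack = stack / stack.max()
    return stack, origin


def register_field(field_movie: np.ndarray, skel: MorphologySkeleton,
                   expected_pos: np.ndarray, pixel_um: float = 1.0,
                   crop_um: float = 250.0, z_step: float = 2.0,
                   blur_um: float = 2.0, penalty: float = 1e-4) -> np.ndarray:
    """Locate a recording field on a reconstructed skeleton.

    The time-averaged field is percentile-clipped (20th/90th) to [0, 1] and
    slid over every xy position of every z layer of a blurred skeleton
    raster cropped ~250 um around the expected position.  The loss is the
    MSE plus ``penalty`` times the Euclidean distance (um) from the
    expected position; the argmin xyz (um, field top-left corner) is
    returned.
    """
    field = field_movie.mean(axis=0) if field_movie.ndim == 3 else field_movie
    field = _clip01_percentile(field)
    fh, fw = field.shape

    stack, origin = skeleton_template_stack(skel, expected_pos, pixel_um,
                                            crop_um, z_step, blur_um)

    best, best_loss = None, np.inf
    nz, ny, nx_ = stack.shape
    if ny < fh or nx_ < fw:
        raise ValueError("field larger than skeleton crop: empty overlap")
    # sliding-window MSE via the expansion (f - w)^2 = f^2 - 2 f w + w^2
    from numpy.lib.stride_tricks import sliding_window_view

    f2 = float((field**2).sum())
    for iz in range(nz):
        win = sliding_window_view(stack[iz], (fh, fw))
        mse = (f2 - 2 * np.einsum("abij,ij->ab", win, field)
               + (win**2).sum(axis=(2, 3))) / (fh * fw)
        oy, ox = np.unravel_index(np.argmin(mse), mse.shape)
        for yy, xx in [(oy, ox)] + list(zip(*np.where(mse <= mse[oy, ox] + 1e-12))):
            pos = origin + np.array([xx * pixel_um, yy * pixel_um, iz * z_step])
            loss = mse[yy, xx] + penalty * np.linalg.norm(pos - expected_pos)
            if loss < best_loss:
                best_loss, best = loss, pos
    return best


@dataclass
class DendriteDensityFit:
    """Hexagonal dendritic-length profile and its truncated-Gaussian fit."""

    hex_spacing: float
    centers: np.ndarray        # (n_hex, 2) um relative to soma
    lengths: np.ndarray        # dendritic cable length per hexagon, um
    scale: float               # Gaussian scale of the radial profile, um
    cutoff: float              # truncation radius, um
    amplitude: float
    converged: bool = True


def _hex_polygon(cx: float, cy: float, spacing: float) -> Polygon:
    r = spacing / np.sqrt(3.0)  # circumradius of a flat-to-flat=spacing hexagon
    ang = np.pi / 6 + np.arange(6) * np.pi / 3
    return Polygon(np.c_[cx + r * np.cos(ang), cy + r * np.sin(ang)])


def hex_density_fit(skel: MorphologySkeleton, hex_spacing: float = 16.0,
                    cutoff_grid_step: float = 8.0) -> DendriteDensityFit:
    """Dendritic length per hexagon and a truncated-Gaussian radial fit.

    A pointy-top hexagonal grid (center-to-center ``hex_spacing``) is
    centered on the soma; each planar-projected skeleton segment is clipped
    exactly against the hexagon polygons and its length apportioned.  The
    radial profile (length vs hexagon-center radius) is fitted with
    ``A exp(-r^2 / (2 scale^2))`` for r <= cutoff and 0 beyond, with the
    cutoff searched on a grid and (A, scale) by least squares per cutoff.
    """
    soma = skel.xyz[skel.ids == skel.soma_id][0][:2]
    pts = skel.xyz[:, :2] - soma
    r_max = float(np.linalg.norm(pts, axis=1).max()) + hex_spacing

    # axial hexagonal lattice: rows spaced by spacing*sqrt(3)/2, offset by half
    centers = []
    dy = hex_spacing * np.sqrt(3) / 2
    n_rows = int(np.ceil(r_max / dy)) + 1
    n_cols = int(np.ceil(r_max / hex_spacing)) + 1
    for row in range(-n_rows, n_rows + 1):
        off = 0.5 * hex_spacing if row % 2 else 0.0
        for col in range(-n_cols, n_cols + 1):
            cx, cy = col * hex_spacing + off, row * dy
            if np.hypot(cx, cy) <= r_max:
                centers.append((cx, cy))
    centers = np.asarray(centers)
    hexes = [_hex_polygon(cx, cy, hex_spacing) for cx, cy in centers]
    tree = STRtree(hexes)

    lengths = np.zeros(len(hexes))
    for a, b in skel.segments():
        seg = LineString([a[:2] - soma, b[:2] - soma])
        if seg.length == 0:
            continue
        for k in tree.query(seg):
            inter = shapely.intersection(hexes[k], seg)
            if not inter.is_empty:
                lengths[k] += inter.length

    radii = np.linalg.norm(centers, axis=1)
    if not np.any(lengths > 0):
        return DendriteDensityFit(hex_spacing, centers, lengths, 0.0, hex_spacing,
                                  0.0, converged=False)
    res = fit_radial_profile(radii, lengths, cutoff_grid_step=cutoff_grid_step,
                             min_cutoff=hex_spacing)
    if res is None:
        return DendriteDensityFit(hex_spacing, centers, lengths, 0.0, hex_spacing,
                                  0.0, converged=False)
    amp, scale, cutoff = res
    return DendriteDensityFit(hex_spacing, centers, lengths, float(scale),
                              float(cutoff), float(amp))


def fit_radial_profile(radii: np.ndarray, values: np.ndarray,
                       cutoff_grid_step: float = 8.0,
                       min_cutoff: float = 8.0) -> tuple[float, float, float] | None:
    """Fit ``A exp(-r^2 / (2 scale^2))``, zero beyond a cutoff radius.

    The cutoff is searched on a grid; amplitude and scale by least squares
    per cutoff.  Returns ``(amplitude, scale, cutoff)`` or None if no
    start converges.
    """
    radii = np.asarray(radii, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(radii)
    r_sorted, y_sorted = radii[order], values[order]
    r_max = r_sorted[-1] + cutoff_grid_step
    best = None
    for c in np.arange(min_cutoff, r_max + cutoff_grid_step, cutoff_grid_step):
        def model(r, A, s):
            return np.where(r <= c, A * np.exp(-r**2 / (2 * s**2)), 0.0)
        try:
            p0 = (float(y_sorted.max()),
                  max(min_cutoff, r_sorted[y_sorted > 0].max() / 2))
            popt, _ = curve_fit(model, r_sorted, y_sorted, p0=p0,
                                bounds=([0, 1.0], [np.inf, np.inf]), maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        sse = float(((model(r_sorted, *popt) - y_sorted) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, c, popt)
    if best is None:
        return None
    _, cutoff, (amp, scale) = best
    return float(amp), float(scale), float(cutoff)
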