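"""Parametric 2D tooth–mandible cross-section geometry and structured quad meshing.

The model domain is a panoramic (mesial–distal) section of the anterior
mandible containing one or three teeth (canine, lateral incisor, central
incisor), each built from stylized primitives: an elliptical crown (enamel
shell over dentin over a pulp chamber) sitting on a gingival line, and a
tapered trapezoidal root (dentin core with a pulp canal, wrapped by a
cementum layer and a periodontal-ligament layer) embedded in trabecular
bone.  A cortical plate of fixed thickness (2 mm by default) spans the
bottom of the domain; the remaining bone volume is trabecular fill.

Meshing is rasterized: a structured axis-aligned grid of 4-node
quadrilaterals covers the domain, each cell is labeled by classifying its
centroid, and cells falling outside the anatomy (above the gingiva, between
crowns) are dropped.  This guarantees well-shaped elements and fully
deterministic region labels at any resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RegionLabel",
    "GeometryParams",
    "Geometry",
    "Mesh",
    "build_geometry",
    "generate_mesh",
    "tag_boundaries",
    "rectangular_mesh",
]


class RegionLabel(IntEnum):
    """Tissue regions of the tooth–mandible section."""

    ENAMEL = 0
    DENTIN = 1
    PULP = 2
    CEMENTUM = 3
    PDL = 4
    GINGIVA = 5
    CORTICAL = 6
    TRABECULAR = 7

    @property
    def label(self) -> str:
        return self.name.lower()


#: Sentinel for points outside the anatomy (omitted from the mesh).
OUTSIDE = -1

REGION_NAMES = tuple(r.name.lower() for r in RegionLabel)


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the stylized tooth–mandible section (lengths in mm).

    ``root_taper`` is the fractional narrowing of the root from the alveolar
    crest to the apex: the root half-width at the tip is
    ``root_half_width * (1 - root_taper)``.
    """

    n_teeth: int = 3
    domain_width: float = 48.0
    domain_height: float = 30.0
    crown_height: float = 14.0
    crown_half_width: float = 5.5
    root_length: float = 11.0
    root_half_width: float = 3.4
    root_taper: float = 0.55
    pdl_thickness: float = 0.4
    cementum_thickness: float = 0.25
    gingiva_thickness: float = 2.0
    cortical_bottom_thickness: float = 2.0
    element_size: float = 0.2

    def __post_init__(self) -> None:
        if self.n_teeth not in (1, 3):
            raise ValueError(f"n_teeth must be 1 or 3, got {self.n_teeth}")
        for name in (
            "domain_width", "domain_height", "crown_height", "crown_half_width",
            "root_length", "root_half_width", "pdl_thickness",
            "cementum_thickness", "gingiva_thickness",
            "cortical_bottom_thickness", "element_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.root_taper < 1.0:
            raise ValueError(f"root_taper must be in (0, 1), got {self.root_taper}")
        depth_available = (
            self.domain_height
            - self.crown_height
            - self.cortical_bottom_thickness
        )
        if self.root_length >= depth_available:
            raise ValueError(
                f"root_length {self.root_length} exceeds available bone depth "
                f"{depth_available} (domain_height - crown_height - cortical layer)"
            )

    @property
    def crest_y(self) -> float:
        """y of the gingival line / alveolar crest (crowns above, roots below)."""
        return self.domain_height - self.crown_height

    @property
    def tooth_centers(self) -> np.ndarray:
        """x-coordinates of tooth axes, evenly spaced across the domain."""
        n = self.n_teeth
        return self.domain_width * (2 * np.arange(n) + 1) / (2 * n)


class Geometry:
    """Deterministic point → :class:`RegionLabel` classifier for the section.

    Calling the object with coordinate arrays returns an int array of region
    codes, with :data:`OUTSIDE` for points outside the anatomy.
    """

    # crown shell fractions of the normalized elliptical radius
    _ENAMEL_INNER = 0.78
    _PULP_OUTER = 0.35
    # pulp canal: fraction of the dentin core half-width; canal stops short
    # of the apex by this fraction of root length
    _CANAL_FRACTION = 0.25
    _CANAL_APEX_MARGIN = 0.2

    def __init__(self, params: GeometryParams):
        self.params = params

    def __call__(self, x, y):
        return self.classify(x, y)

    def classify(self, x, y) -> np.ndarray:
        """Classify points; scalars or arrays, broadcast together."""
        p = self.params
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x, y = np.broadcast_arrays(x, y)
        out = np.full(x.shape, OUTSIDE, dtype=np.int8)

        in_domain = (x >= 0) & (x <= p.domain_width) & (y >= 0) & (y <= p.domain_height)
        crest = p.crest_y

        # bone matrix below the gingival line
        below_crest = in_domain & (y < crest)
        out[below_crest & (y < p.cortical_bottom_thickness)] = RegionLabel.CORTICAL
        trab = below_crest & (y >= p.cortical_bottom_thickness)
        out[trab & (y >= crest - p.gingiva_thickness)] = RegionLabel.GINGIVA
        out[trab & (y < crest - p.gingiva_thickness)] = RegionLabel.TRABECULAR

        for xc in p.tooth_centers:
            dx = np.abs(x - xc)
            self._paint_crown(out, dx, y, in_domain)
            self._paint_root(out, dx, y, in_domain)
        return out

    def _paint_crown(self, out, dx, y, in_domain) -> None:
        p = self.params
        dy = y - p.crest_y
        above = in_domain & (dy >= 0)
        r = np.sqrt(
            (dx / p.crown_half_width) ** 2 + (dy / p.crown_height) ** 2,
            where=above, out=np.full(dx.shape, np.inf),
        )
        inside = above & (r <= 1.0)
        out[inside & (r > self._ENAMEL_INNER)] = RegionLabel.ENAMEL
        out[inside & (r <= self._ENAMEL_INNER) & (r > self._PULP_OUTER)] = RegionLabel.DENTIN
        out[inside & (r <= self._PULP_OUTER)] = RegionLabel.PULP

    def _paint_root(self, out, dx, y, in_domain) -> None:
        p = self.params
        crest = p.crest_y
        tip_y = crest - p.root_length
        in_band = in_domain & (y < crest) & (y >= tip_y)
        # depth fraction from crest (0) to apex (1)
        f = np.clip((crest - y) / p.root_length, 0.0, 1.0)
        w_dentin = p.root_half_width * (1.0 - p.root_taper * f)
        w_cem = w_dentin + p.cementum_thickness
        w_pdl = w_cem + p.pdl_thickness
        out[in_band & (dx < w_pdl)] = RegionLabel.PDL
        out[in_band & (dx < w_cem)] = RegionLabel.CEMENTUM
        out[in_band & (dx < w_dentin)] = RegionLabel.DENTIN
        canal = (
            in_band
            & (dx < self._CANAL_FRACTION * w_dentin)
            & (f < 1.0 - self._CANAL_APEX_MARGIN)
        )
        out[canal] = RegionLabel.PULP


def build_geometry(params: GeometryParams) -> Geometry:
    """Build the deterministic region classifier for the given parameters."""
    return Geometry(params)


@dataclass
class Mesh:
    """Structured 4-node quadrilateral mesh with per-element region labels.

    nodes: (n_nodes, 2) coordinates in mm; elements: (n_elems, 4) node
    indices in counter-clockwise order; region: (n_elems,) int codes from
    :class:`RegionLabel`; node_sets: named node-index arrays.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_size: float | None = None
    _adjacency_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def region_mask(self, label: RegionLabel) -> np.ndarray:
        return self.region == int(label)

    @property
    def trabecular_mask(self) -> np.ndarray:
        return self.region_mask(RegionLabel.TRABECULAR)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        """Areas via the shoelace formula (positive for CCW elements)."""
        xy = self.nodes[self.elements]
        x, y = xy[..., 0], xy[..., 1]
        xs, ys = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * ys - xs * y, axis=1)

    def adjacency_pairs(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_pairs, 2) element indices sharing an edge, optionally restricted
        to elements where ``mask`` is True (both members)."""
        key = "all" if mask is None else hash(mask.tobytes())
        if key not in self._adjacency_cache:
            pairs = _edge_adjacency(self.elements)
            if mask is not None:
                pairs = pairs[mask[pairs[:, 0]] & mask[pairs[:, 1]]]
            self._adjacency_cache[key] = pairs
        return self._adjacency_cache[key]


def _edge_adjacency(elements: np.ndarray) -> np.ndarray:
    """Pairs of elements sharing a full edge (two nodes)."""
    ne = elements.shape[0]
    e0 = elements
    e1 = np.roll(elements, -1, axis=1)
    a = np.minimum(e0, e1).ravel()
    b = np.maximum(e0, e1).ravel()
    owner = np.repeat(np.arange(ne), 4)
    order = np.lexsort((b, a))
    a, b, owner = a[order], b[order], owner[order]
    same = (a[:-1] == a[1:]) & (b[:-1] == b[1:])
    return np.column_stack([owner[:-1][same], owner[1:][same]])


def generate_mesh(geometry: Geometry, params: GeometryParams | None = None) -> Mesh:
    """Rasterize the geometry into a structured quad mesh.

    Each grid cell is labeled by classifying its centroid; cells outside the
    anatomy are omitted and unused nodes dropped.  Boundary node sets are
    tagged on the result (see :func:`tag_boundaries`).
    """
    p = params or geometry.params
    h = p.element_size
    feature = min(p.pdl_thickness, p.cementum_thickness)
    if h > max(p.crown_half_width, p.root_half_width, p.gingiva_thickness,
               p.cortical_bottom_thickness):
        logger.warning(
            "element_size %.3g mm exceeds every feature dimension; "
            "regions thinner than one element rasterize to nearest label", h)
    elif h > 5 * feature:
        logger.info("element_size %.3g mm is coarse relative to the thinnest "
                    "layer (%.3g mm)", h, feature)

    nx = max(1, round(p.domain_width / h))
    ny = max(1, round(p.domain_height / h))
    xs = np.linspace(0.0, p.domain_width, nx + 1)
    ys = np.linspace(0.0, p.domain_height, ny + 1)
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    labels = geometry.classify(CX.ravel(), CY.ravel())

    keep = labels != OUTSIDE
    ij = np.nonzero(keep)[0]
    i, j = np.divmod(ij, ny)
    # grid node index (i, j) -> i * (ny + 1) + j; CCW connectivity
    n00 = i * (ny + 1) + j
    n10 = (i + 1) * (ny + 1) + j
    n11 = (i + 1) * (ny + 1) + j + 1
    n01 = i * (ny + 1) + j + 1
    conn = np.column_stack([n00, n10, n11, n01])

    used, inv = np.unique(conn, return_inverse=True)
    conn = inv.reshape(conn.shape).astype(np.int64)
    gx, gy = np.divmod(used, ny + 1)
    nodes = np.column_stack([xs[gx], ys[gy]])

    mesh = Mesh(
        nodes=nodes,
        elements=conn,
        region=labels[keep].astype(np.int8),
        element_size=h,
    )
    return tag_boundaries(mesh, p)


def tag_boundaries(mesh: Mesh, params: GeometryParams) -> Mesh:
    """Tag the bottom/left/right boundary node sets and, for each tooth, a
    small load node set at the crown tip (a 3-grid-column-wide cap).

    Raises ``ValueError`` if any tooth yields an empty load set, which
    indicates a geometry/mesh mismatch.
    """
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    ymin = y.min()
    sets = {
        "bottom": np.nonzero(np.isclose(y, ymin))[0],
        "left_edge": np.nonzero(np.isclose(x, x.min()))[0],
        "right_edge": np.nonzero(np.isclose(x, x.max()))[0],
    }
    h = params.element_size
    load_sets = []
    for t, xc in enumerate(params.tooth_centers):
        cand = np.nonzero(np.abs(x - xc) <= 1.55 * h)[0]
        if cand.size == 0:
            raise ValueError(f"no mesh nodes near tooth {t} center x={xc:.3g}")
        chosen = []
        for xv in np.unique(np.round(x[cand], 9)):
            col = cand[np.isclose(x[cand], xv)]
            chosen.append(col[np.argmax(y[col])])
        top = np.array(sorted(chosen))
        # keep only nodes actually at the occlusal surface (near the crown tip)
        top = top[y[top] >= y[top].max() - 2.5 * h]
        if top.size == 0:
            raise ValueError(f"empty load node set for tooth {t}")
        load_sets.append(top)
    sets["load_nodes_per_tooth"] = load_sets
    mesh.node_sets = sets
    return mesh


def rectangular_mesh(
    width: float,
    height: float,
    element_size: float,
    region: RegionLabel = RegionLabel.TRABECULAR,
) -> Mesh:
    """Plain rectangular single-region mesh (patch tests, bar studies).

    Node sets: bottom/left/right edges plus a single-entry
    ``load_nodes_per_tooth`` holding all top-edge nodes.
    """
    nx = max(1, round(width / element_size))
    ny = max(1, round(height / element_size))
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    i, j = i.ravel(), j.ravel()
    n00 = i * (ny + 1) + j
    conn = np.column_stack([n00, n00 + (ny + 1), n00 + ny + 2, n00 + 1])
    mesh = Mesh(
        nodes=nodes,
        elements=conn.astype(np.int64),
        region=np.full(conn.shape[0], int(region), dtype=np.int8),
        element_size=element_size,
    )
    x, y = nodes[:, 0], nodes[:, 1]
    mesh.node_sets = {
        "bottom": np.nonzero(np.isclose(y, 0.0))[0],
        "left_edge": np.nonzero(np.isclose(x, 0.0))[0],
        "right_edge": np.nonzero(np.isclose(x, width))[0],
        "load_nodes_per_tooth": [np.nonzero(np.isclose(y, height))[0]],
    }
    return mesh
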