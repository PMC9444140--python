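"""Structured axisymmetric (r, z) mesh of the four-region phantom.

Regions are concentric cylindrical shells: capillary lumen, endothelium,
basal lamina and parenchyma.  Region boundaries are forced onto mesh
faces exactly; cell measures use the axisymmetric volume
2*pi*r*dr*dz, so discrete region volumes match the closed-form
cylinder/annulus values to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GeometryConfig, EndFeetLayout

#: Region codes, radially ordered.
LUMEN, ENDO, BL, TISSUE = 0, 1, 2, 3
REGION_NAMES = {LUMEN: "lumen", ENDO: "endothelium", BL: "basal_lamina",
                TISSUE: "parenchyma"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}


class MeshingError(ValueError):
    """Resolution too coarse or geometry degenerate for meshing."""


def _allocate_radial(nr: int) -> tuple[int, int, int, int]:
    """Split ``nr`` radial cells over the four shells.

    Weights favour the lumen (flow profile accuracy) and parenchyma
    (gradient resolution); every shell gets at least four cells so the
    100 nm basal lamina is always resolved.
    """
    if nr < 16:
        raise MeshingError("nr < 16: need at least four radial cells per "
                           "layer (lumen, endothelium, basal lamina, parenchyma)")
    weights = np.array([0.40, 0.13, 0.07, 0.40])
    raw = weights * nr
    counts = np.maximum(np.floor(raw).astype(int), 4)
    # distribute the remainder by largest fractional part
    order = np.argsort(-(raw - np.floor(raw)))
    idx = 0
    while counts.sum() < nr:
        counts[order[idx % 4]] += 1
        idx += 1
    while counts.sum() > nr:
        big = int(np.argmax(counts))
        counts[big] -= 1
        if counts[big] < 4:
            raise MeshingError("nr too small to keep four cells per layer")
    return tuple(int(c) for c in counts)


@dataclass
class Mesh:
    """Cell-centred structured axisymmetric grid with region labels."""

    r_faces: np.ndarray          # (nr+1,)
    z_faces: np.ndarray          # (nz+1,)
    region_of_ring: np.ndarray   # (nr,) region code per radial ring
    geometry: GeometryConfig

    r_centers: np.ndarray = field(init=False)
    z_centers: np.ndarray = field(init=False)
    cell_volumes: np.ndarray = field(init=False)     # (nr, nz)
    radial_face_areas: np.ndarray = field(init=False)  # (nr+1, nz) 2*pi*r*dz
    axial_face_areas: np.ndarray = field(init=False)   # (nr,) pi*(ro^2-ri^2)

    def __post_init__(self):
        self.r_faces = np.asarray(self.r_faces, dtype=float)
        self.z_faces = np.asarray(self.z_faces, dtype=float)
        if np.any(np.diff(self.r_faces) <= 0) or np.any(np.diff(self.z_faces) <= 0):
            raise MeshingError("face coordinates must be strictly increasing")
        self.r_centers = 0.5 * (self.r_faces[1:] + self.r_faces[:-1])
        self.z_centers = 0.5 * (self.z_faces[1:] + self.z_faces[:-1])
        dz = np.diff(self.z_faces)
        ring_area = np.pi * (self.r_faces[1:] ** 2 - self.r_faces[:-1] ** 2)
        self.cell_volumes = ring_area[:, None] * dz[None, :]
        self.radial_face_areas = 2.0 * np.pi * self.r_faces[:, None] * dz[None, :]
        self.axial_face_areas = ring_area

    @property
    def nr(self) -> int:
        return len(self.r_faces) - 1

    @property
    def nz(self) -> int:
        return len(self.z_faces) - 1

    @property
    def cell_region(self) -> np.ndarray:
        """(nr, nz) region code per cell."""
        return np.broadcast_to(self.region_of_ring[:, None],
                               (self.nr, self.nz))

    def ring_slice(self, region: int) -> slice:
        idx = np.where(self.region_of_ring == region)[0]
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def interface_face_index(self, inner_region: int) -> int:
        """Radial face index of the interface on the outer side of a region."""
        return self.ring_slice(inner_region).stop

    def region_volume(self, region: int) -> float:
        return float(self.cell_volumes[self.region_of_ring == region, :].sum())

    def region_mask(self, region) -> np.ndarray:
        if isinstance(region, str):
            region = REGION_CODES[region]
        return self.cell_region == region


def build_mesh(geom: GeometryConfig, nr: int = 60, nz: int = 120) -> Mesh:
    """Discretise the phantom with ``nr`` radial and ``nz`` axial cells.

    Radial faces are forced onto the three internal region boundaries
    and the outer surface; spacing is uniform within each shell.
    """
    if nz < 4:
        raise MeshingError("nz < 4")
    for name, h in (("endothelium", geom.h_end), ("basal lamina", geom.h_bl),
                    ("lumen", geom.R0), ("parenchyma", geom.L_surround)):
        if h <= 0:
            raise MeshingError(f"degenerate layer: {name} has non-positive "
                               "thickness")
    n_l, n_e, n_b, n_t = _allocate_radial(nr)
    bounds = [0.0, geom.R0, geom.r_endo_outer, geom.r_bl_outer, geom.r_outer]
    pieces = []
    for (r0, r1), n in zip(zip(bounds[:-1], bounds[1:]), (n_l, n_e, n_b, n_t)):
        pieces.append(np.linspace(r0, r1, n + 1)[:-1])
    r_faces = np.concatenate(pieces + [[bounds[-1]]])
    z_faces = np.linspace(0.0, geom.L_capillary, nz + 1)
    region_of_ring = np.concatenate([
        np.full(n_l, LUMEN), np.full(n_e, ENDO),
        np.full(n_b, BL), np.full(n_t, TISSUE)]).astype(int)
    return Mesh(r_faces=r_faces, z_faces=z_faces,
                region_of_ring=region_of_ring, geometry=geom)


def make_endfeet_mask(layout: EndFeetLayout, mesh: Mesh) -> np.ndarray:
    """Classify the basal-lamina|parenchyma interface facets.

    Returns a boolean array of length ``nz``: True where the facet lies
    under an astrocyte end-foot, False in a free-diffusion cleft.  The
    requested total end-foot facet count (rounded to the nearest facet)
    is distributed over ``n_bands`` stripes by largest remainder, each
    stripe centred in its axial segment, so the realised coverage
    matches the request to within one facet.
    """
    nz = mesh.nz
    n_bands = layout.n_bands
    if n_bands > nz:
        raise MeshingError(f"n_bands={n_bands} exceeds nz={nz}")
    total = int(round(layout.coverage_fraction * nz))
    base, rem = divmod(total, n_bands)
    per_band = np.full(n_bands, base, dtype=int)
    # spread the remainder symmetrically from the ends inward
    order = np.argsort([min(k, n_bands - 1 - k) for k in range(n_bands)])
    for k in range(rem):
        per_band[order[k]] += 1
    seg = nz / n_bands
    mask = np.zeros(nz, dtype=bool)
    for k in range(n_bands):
        width = per_band[k]
        center = (k + 0.5) * seg
        start = int(round(center - width / 2.0))
        start = max(0, min(start, nz - width))
        mask[start:start + width] = True
    return mask


def coverage_fraction(mask: np.ndarray, mesh: Mesh) -> float:
    """Realised end-feet coverage of the BL|parenchyma interface, percent.

    Uses axisymmetric facet areas 2*pi*R*dz (the interface radius is
    common to all facets, so this reduces to an axial length fraction
    on a uniform grid, but the area weighting is kept for generality).
    """
    i_face = mesh.interface_face_index(BL)
    areas = mesh.radial_face_areas[i_face, :]
    pct = 100.0 * areas[np.asarray(mask, bool)].sum() / areas.sum()
    return float(min(max(pct, 0.0), 100.0))
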