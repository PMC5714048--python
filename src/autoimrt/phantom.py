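"""Deterministic synthetic structure sets for end-to-end testing.

No clinical data ships with (or is needed by) this package: the phantoms
below emulate the *topology* a head-and-neck (or generic multi-level) plan
must handle — nested target levels, a posterior serial organ, lateral
parallel organs abutting the lowest target level, a convex body contour —
with purely geometric primitives. They make no claim of anatomical realism
and contain no CT intensities.

All randomness is a small jitter of organ centres drawn from a single
``numpy`` Generator keyed by the seed; organ placement order is fixed, so
a given seed reproduces the same masks bit for bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import roi_algebra as ra
from .roi_algebra import Grid, Mask
from .structures import StructureSet


class PhantomError(RuntimeError):
    """Organ placement failed to respect body clearance after retries."""


#: minimum clearance between any organ and the skin surface, mm
BODY_CLEARANCE_MM = 5.0
_MAX_RETRIES = 10

DEFAULT_GRID = Grid(shape=(128, 128, 96), spacing=(2.0, 2.0, 2.0))


@dataclass
class PhantomSpec:
    grid: Grid = field(default_factory=lambda: DEFAULT_GRID)
    seed: int = 0
    jitter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.jitter_mm < 0:
            raise ValueError("jitter_mm must be non-negative")


class _Builder:
    def __init__(self, spec: PhantomSpec):
        self.grid = spec.grid
        self.rng = np.random.default_rng(spec.seed)
        self.jitter = spec.jitter_mm
        self.coords = self.grid.coordinates()  # (*shape, 3), mm
        self.center = self.grid.center_mm()
        self.clearance_zone: np.ndarray | None = None  # body eroded by clearance

    def _jitter(self) -> np.ndarray:
        # always draw, even at jitter 0, to keep the stream layout stable
        off = self.rng.uniform(-1.0, 1.0, size=3)
        return off * self.jitter

    def ellipsoid(self, center_off: np.ndarray, semi_axes) -> np.ndarray:
        rel = (self.coords - (self.center + center_off)) / np.asarray(semi_axes, dtype=float)
        return (rel ** 2).sum(axis=-1) <= 1.0

    def cylinder_z(self, center_off, radius, z_lo_off, z_hi_off) -> np.ndarray:
        c = self.center + np.asarray(center_off, dtype=float)
        rel = self.coords[..., :2] - c[:2]
        radial = (rel ** 2).sum(axis=-1) <= radius ** 2
        z = self.coords[..., 2]
        return radial & (z >= self.center[2] + z_lo_off) & (z <= self.center[2] + z_hi_off)

    def place(self, make, *, jittered: bool = True) -> np.ndarray:
        """Build an organ, re-drawing jitter if it breaks body clearance."""
        for _ in range(_MAX_RETRIES):
            off = self._jitter() if jittered else np.zeros(3)
            data = make(off)
            if self.clearance_zone is None or not np.any(data & ~self.clearance_zone):
                return data
        raise PhantomError("organ unplaceable inside the body contour after retries")


def make_hn_phantom(spec: PhantomSpec | None = None) -> StructureSet:
    """Head-and-neck-like phantom with the full HN.6 required ROI roster.

    Geometry: an elliptic-cylinder body; nested CTV70 ⊂ CTV63 ⊂ CTV56
    (the lowest level extended laterally toward the parotid regions); a
    posterior cord cylinder with a superior brainstem continuation;
    lateral parotid ellipsoids; a geometric mandible arc, larynx, oral
    cavity and cochlea spheres. Axes: +x patient left, +y posterior,
    +z superior.
    """
    spec = spec or PhantomSpec()
    b = _Builder(spec)
    g = b.grid
    s = StructureSet(g)

    # body: elliptic cylinder over the full longitudinal extent
    body = b.ellipsoid(np.zeros(3), (80.0, 62.0, 1e9))
    s.add(Mask("external", g, body))
    erosion = ra.contract(Mask("_body", g, body), BODY_CLEARANCE_MM)
    b.clearance_zone = erosion.data

    # nested target levels; nesting is guaranteed by construction
    ctv70 = b.place(lambda off: b.ellipsoid(np.array([15.0, 5.0, -10.0]) + off, (22.0, 18.0, 24.0)))
    m70 = Mask("CTV70", g, ctv70)
    node63 = b.place(lambda off: b.ellipsoid(np.array([-5.0, 8.0, -5.0]) + off, (26.0, 20.0, 28.0)))
    ctv63 = ra.expand(m70, 8.0).data | node63
    ctv63 &= b.clearance_zone
    m63 = Mask("CTV63", g, ctv63)
    # lateral nodal extensions toward the parotid regions
    node_l = b.place(lambda off: b.ellipsoid(np.array([42.0, 5.0, 5.0]) + off, (14.0, 16.0, 28.0)))
    node_r = b.place(lambda off: b.ellipsoid(np.array([-42.0, 5.0, 5.0]) + off, (14.0, 16.0, 28.0)))
    ctv56 = ra.expand(m63, 6.0).data | node_l | node_r
    ctv56 &= b.clearance_zone
    s.add(m70)
    s.add(m63)
    s.add(Mask("CTV56", g, ctv56))

    z_top = (g.shape[2] - 1) * g.spacing[2] / 2.0  # half-extent from centre
    cord = b.place(lambda off: b.cylinder_z(np.array([0.0, 42.0, 0.0]) + off, 5.0, -z_top, z_top),
                   jittered=False)
    s.add(Mask("cord", g, cord))
    bs = b.place(lambda off: b.cylinder_z(np.array([0.0, 30.0, 0.0]) + off, 6.0, 0.35 * z_top, z_top - 6.0),
                 jittered=False)
    s.add(Mask("brain_stem", g, bs))

    lt_par = b.place(lambda off: b.ellipsoid(np.array([55.0, 8.0, 10.0]) + off, (10.0, 13.0, 18.0)))
    rt_par = b.place(lambda off: b.ellipsoid(np.array([-55.0, 8.0, 10.0]) + off, (10.0, 13.0, 18.0)))
    s.add(Mask("lt_parotid", g, lt_par))
    s.add(Mask("rt_parotid", g, rt_par))

    larynx = b.place(lambda off: b.ellipsoid(np.array([0.0, -18.0, -52.0]) + off, (12.0, 11.0, 15.0)))
    s.add(Mask("larynx", g, larynx))

    def mandible(off: np.ndarray) -> np.ndarray:
        c = b.center + np.concatenate([off[:2], [0.0]]) + np.array([0.0, -6.0, 0.0])
        rel = b.coords[..., :2] - c[:2]
        r = np.sqrt((rel ** 2).sum(axis=-1))
        z = b.coords[..., 2]
        anterior = rel[..., 1] < 0  # anterior half-arc
        return ((r >= 36.0) & (r <= 46.0) & anterior
                & (z >= b.center[2] - 32.0 + off[2]) & (z <= b.center[2] - 14.0 + off[2]))

    s.add(Mask("mandible", g, b.place(mandible)))

    lt_coch = b.place(lambda off: b.ellipsoid(np.array([38.0, 18.0, 52.0]) + off, (4.0, 4.0, 4.0)))
    rt_coch = b.place(lambda off: b.ellipsoid(np.array([-38.0, 18.0, 52.0]) + off, (4.0, 4.0, 4.0)))
    s.add(Mask("lt_cochlea", g, lt_coch))
    s.add(Mask("rt_cochlea", g, rt_coch))

    oral = b.place(lambda off: b.ellipsoid(np.array([0.0, -28.0, -18.0]) + off, (15.0, 13.0, 13.0)))
    s.add(Mask("oral_cavity", g, oral))
    return s


def make_generic_phantom(
    levels: list[int] | None = None, spec: PhantomSpec | None = None
) -> StructureSet:
    """Concentric multi-level phantom: 1–3 nested targets, two lateral OARs.

    ``levels`` are prescription levels in Gy (highest first); target names
    are ``CTV{level}``. Defaults to the three-level 60/50/40 pattern that
    matches the bundled ``generic3`` template.
    """
    levels = levels if levels is not None else [60, 50, 40]
    if not 1 <= len(levels) <= 3:
        raise ValueError("generic phantom supports 1 to 3 dose levels")
    if sorted(levels, reverse=True) != list(levels):
        raise ValueError("levels must be given highest first")
    spec = spec or PhantomSpec()
    b = _Builder(spec)
    g = b.grid
    s = StructureSet(g)

    body = b.ellipsoid(np.zeros(3), (85.0, 70.0, 1e9))
    s.add(Mask("external", g, body))
    b.clearance_zone = ra.contract(Mask("_body", g, body), BODY_CLEARANCE_MM).data

    radii = [18.0, 30.0, 42.0][: len(levels)]
    # one shared jittered centre keeps all levels concentric
    for _ in range(_MAX_RETRIES):
        off = b.rng.uniform(-1.0, 1.0, 3) * b.jitter
        if not np.any(b.ellipsoid(off, (radii[-1],) * 3) & ~b.clearance_zone):
            break
    else:
        raise PhantomError("target unplaceable inside the body contour after retries")
    for level, radius in zip(levels, radii):
        data = b.ellipsoid(off, (radius, radius, radius)) & b.clearance_zone
        s.add(Mask(f"CTV{level}", g, data))

    oar_l = b.place(lambda o: b.ellipsoid(np.array([58.0, 0.0, 0.0]) + o, (12.0, 14.0, 20.0)))
    oar_r = b.place(lambda o: b.ellipsoid(np.array([-58.0, 0.0, 0.0]) + o, (12.0, 14.0, 20.0)))
    s.add(Mask("oar_left", g, oar_l))
    s.add(Mask("oar_right", g, oar_r))
    return s
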