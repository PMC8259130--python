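"""Synthetic phantoms: effective 2D transmission maps and scene plans.

Each phantom is a map of effective transmission ``f(y, z)`` on a regular
grid, with background exactly 1 and finite support.  Contrast in the real
instrument comes mostly from reflection and diffraction outside the
collection NA of the detection objective, not from the Fresnel transmission
coefficient (a polystyrene bead in water has f = 0.99), so phantoms specify
``f`` directly: beads have a dark rim and a bright central spot, cells a
smooth absorbing body with optional granules, algal colonies a chain of
ellipses.  ``transmission_from_index`` is available for index-defined
phantoms.

Object thickness never enters: the random-phase cross terms carrying the
accumulated phase through the object are dropped by the phase-matching
approximation of the power model, so only the 2D effective transmission
survives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TransmissionMap",
    "ObjectSpec",
    "ScenePlan",
    "transmission_from_index",
    "make_bead",
    "make_cell",
    "make_alga_colony",
    "make_scene",
    "SPEED_RANGE_CM_S",
]

#: Typical per-object flow speeds in the microfluidic channel (cm/s).
SPEED_RANGE_CM_S = (10.0, 25.0)

F_MAX = 1.3  # bright spots may exceed 1, never beyond this


@dataclass
class TransmissionMap:
    """Effective transmission f(y, z) on a regular grid.

    ``values[i, j]`` is f at ``z = (i - origin[0]) * pitch_z`` and
    ``y = (j - origin[1]) * pitch_y`` relative to the object centre.
    Background is exactly 1; f in [0, 1.3].
    """

    values: np.ndarray
    pitch_y: float
    pitch_z: float
    origin: tuple[float, float]  # (row, col) index of the object centre

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D grid")
        if self.values.min() < 0 or self.values.max() > F_MAX:
            raise ValueError(f"transmission values must lie in [0, {F_MAX}]")

    @property
    def z_coords(self) -> np.ndarray:
        return (np.arange(self.values.shape[0]) - self.origin[0]) * self.pitch_z

    @property
    def y_coords(self) -> np.ndarray:
        return (np.arange(self.values.shape[1]) - self.origin[1]) * self.pitch_y

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.8g")

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.values.astype(np.float32))


@dataclass
class ObjectSpec:
    """One object in a scene: class, geometry, kinematics and timing."""

    kind: Literal["bead", "cell", "alga_colony"]
    diameter: float  # um; for alga_colony this is the colony length
    speed: float  # cm/s
    arrival_time: float  # us, time the object centre crosses the slit
    lateral_offset: float = 0.0  # um along the scan axis
    width: float | None = None  # um, alga_colony only
    n_granules: int = 0
    granule_contrast: float = 0.4
    granule_diameter: float = 1.5
    bright_spot: bool = False
    rim_transmission: float = 0.5
    body_transmission: float = 0.85
    center_transmission: float = 1.15
    n_cells: int = 1  # alga_colony only
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        lo, hi = SPEED_RANGE_CM_S
        if not (lo <= self.speed <= hi):
            raise ValueError(f"speed must lie in [{lo}, {hi}] cm/s")
        if self.n_granules < 0:
            raise ValueError("n_granules must be non-negative")


@dataclass
class ScenePlan:
    """Ordered, non-overlapping sequence of objects with truth labels."""

    objects: list[ObjectSpec]
    seed: int

    def __post_init__(self) -> None:
        times = [o.arrival_time for o in self.objects]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("arrival times must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [o.label for o in self.objects]

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "objects": [
                {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in vars(o).items()}
                for o in self.objects
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ScenePlan":
        payload = json.loads(text)
        return cls(
            objects=[ObjectSpec(**o) for o in payload["objects"]],
            seed=payload["seed"],
        )


def transmission_from_index(delta_n: float, n0: float) -> float:
    """Fresnel-style effective power transmission for a projected index
    step ``delta_n`` on background index ``n0``:

        f = 4 n0 (n0 + dn) / (2 n0 + dn)^2

    Equals 1 at dn = 0 and decreases monotonically; dn must be
    non-negative (cells and beads are denser than water).
    """
    delta_n = np.asarray(delta_n, dtype=float)
    if np.any(delta_n < 0):
        raise ValueError("delta_n must be non-negative")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    out = 4.0 * n0 * (n0 + delta_n) / (2.0 * n0 + delta_n) ** 2
    return float(out) if out.ndim == 0 else out


def _radial_grid(diameter: float, pitch: float, margin: float = 1.0):
    half = diameter / 2.0 + margin
    n = int(np.ceil(half / pitch))
    coords = np.arange(-n, n + 1) * pitch
    zz, yy = np.meshgrid(coords, coords, indexing="ij")
    return coords, zz, yy, float(n)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_bead(
    diameter: float,
    rim_transmission: float = 0.5,
    center_transmission: float = 1.15,
    pitch: float = 0.32,
    body_transmission: float = 0.75,
) -> TransmissionMap:
    """Polystyrene-bead phantom: dark rim (large-angle scattering at the
    curved boundary), dimmed body, bright central spot (small-angle forward
    diffraction through the bead centre).

    The rim is an annulus of width ``min(0.8 um, diameter/8)`` at the
    boundary; the bright spot has diameter ``diameter/4`` (within the
    central third).  Outside the disk f is exactly 1.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not (0 < rim_transmission <= 1):
        raise ValueError("rim_transmission must lie in (0, 1]")
    if center_transmission < 1:
        raise ValueError("center_transmission must be >= 1")
    if pitch > diameter / 4:
        raise ValueError("pitch too coarse: need at least 4 samples across the bead")

    R = diameter / 2.0
    rim_w = min(0.8, R / 4.0)
    r_spot = diameter / 8.0
    _, zz, yy, _ = _radial_grid(diameter, pitch)
    r = np.hypot(zz, yy)

    f = np.ones_like(r)
    inside = r <= R
    # body level, darkening into the rim over the annulus width
    t = _smoothstep((r - (R - rim_w)) / rim_w)
    f_in = body_transmission * (1 - t) + rim_transmission * t
    # bright spot blended over a 0.3 um shoulder
    s = _smoothstep((r_spot + 0.3 - r) / 0.3)
    f_in = f_in * (1 - s) + center_transmission * s
    f[inside] = f_in[inside]
    c = (f.shape[0] - 1) / 2.0
    return TransmissionMap(values=f, pitch_y=pitch, pitch_z=pitch, origin=(c, c))


def make_cell(
    diameter: float,
    n_granules: int,
    granule_diameter: float = 1.5,
    granule_contrast: float = 0.4,
    seed: int = 0,
    pitch: float = 0.32,
    body_transmission: float = 0.85,
) -> TransmissionMap:
    """Cell phantom: smooth absorbing disk with ``n_granules`` circular
    granules, alternately bright (+contrast) and dark (-contrast) relative
    to the body.  Granule placement is seeded and reproducible; granules are
    kept inside 85% of the radius and non-overlapping (bounded retries).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if n_granules > 0 and granule_diameter >= diameter:
        raise ValueError("granules must fit inside the cell")

    R = diameter / 2.0
    _, zz, yy, _ = _radial_grid(diameter, pitch)
    r = np.hypot(zz, yy)
    f = np.where(r <= R, body_transmission, 1.0)

    rng = np.random.default_rng(seed)
    g_r = granule_diameter / 2.0
    placed: list[tuple[float, float]] = []
    max_r = 0.85 * R - g_r
    if n_granules > 0 and max_r <= 0:
        raise ValueError("granules must fit inside the cell")
    # centres at least 1.5 radii apart: granules stay individually
    # resolvable but may touch, as intracellular granules do
    min_sep = 1.5 * g_r
    for i in range(n_granules):
        for _ in range(400):
            rho = max_r * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            cz, cy = rho * np.cos(phi), rho * np.sin(phi)
            if all(np.hypot(cz - pz, cy - py) >= min_sep for pz, py in placed):
                placed.append((cz, cy))
                break
        else:
            raise RuntimeError(
                f"could not place granule {i + 1}/{n_granules} without overlap"
            )
        sign = 1.0 if i % 2 == 0 else -1.0
        level = np.clip(body_transmission + sign * granule_contrast, 0.0, F_MAX)
        f[np.hypot(zz - placed[-1][0], yy - placed[-1][1]) <= g_r] = level

    c = (f.shape[0] - 1) / 2.0
    return TransmissionMap(values=f, pitch_y=pitch, pitch_z=pitch, origin=(c, c))


def make_alga_colony(
    n_cells: int,
    cell_length: float = 10.0,
    cell_width: float = 4.0,
    pitch: float = 0.32,
    body_transmission: float = 0.8,
) -> TransmissionMap:
    """Colonial-alga phantom: ``n_cells`` ellipses (long axis along the flow
    direction z) laid side by side along the scan direction y, the linear
    colony habit of *Scenedesmus*-like green algae.  Footprint length along
    y is approximately ``n_cells * cell_width``.
    """
    if n_cells not in (1, 2, 4, 8):
        raise ValueError("n_cells must be one of 1, 2, 4, 8")

    span_y = n_cells * cell_width
    half_y = span_y / 2.0 + 1.0
    half_z = cell_length / 2.0 + 1.0
    ny = int(np.ceil(half_y / pitch))
    nz = int(np.ceil(half_z / pitch))
    y = np.arange(-ny, ny + 1) * pitch
    z = np.arange(-nz, nz + 1) * pitch
    zz, yy = np.meshgrid(z, y, indexing="ij")

    f = np.ones_like(zz)
    centers = (np.arange(n_cells) - (n_cells - 1) / 2.0) * cell_width
    for cy in centers:
        inside = (zz / (cell_length / 2.0)) ** 2 + (
            (yy - cy) / (cell_width / 2.0)
        ) ** 2 <= 1.0
        f[inside] = body_transmission
    return TransmissionMap(
        values=f, pitch_y=pitch, pitch_z=pitch, origin=(nz, ny)
    )


@dataclass
class MixtureClass:
    """One class in a synthetic mixture."""

    label: str
    count: int
    kind: Literal["bead", "cell", "alga_colony"] = "bead"
    diameter_mean: float = 10.0
    diameter_cv: float = 0.03
    n_granules: int = 0
    granule_contrast: float = 0.4
    granule_diameter: float = 1.5
    bright_spot: bool = False
    rim_transmission: float = 0.5
    body_transmission: float = 0.85
    center_transmission: float = 1.15
    n_cells: int = 1
    width: float | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"class {self.label!r} needs count >= 1, got {self.count}")


def make_scene(
    classes: Sequence[MixtureClass],
    seed: int,
    spacing_us: tuple[float, float] = (500.0, 620.0),
    start_us: float = 1000.0,
    lateral_sigma_um: float = 1.5,
) -> ScenePlan:
    """Draw a labelled scene: per-object diameters (lognormal-free normal
    with the class CV, clipped at 3 sigma), speeds uniform on 10-25 cm/s,
    lateral offsets, and strictly increasing arrival times spaced so that
    interrogation windows (transmission event plus the two velocimetry
    dips) never overlap.

    Object order is a seeded shuffle of the class roster, so mixtures are
    interleaved in time.  Identical (classes, seed) give identical plans.
    """
    if any(c.count < 1 for c in classes):
        raise ValueError("every class needs count >= 1")
    rng = np.random.default_rng(seed)
    roster: list[MixtureClass] = []
    for c in classes:
        roster.extend([c] * c.count)
    order = rng.permutation(len(roster))

    lo, hi = SPEED_RANGE_CM_S
    t = start_us
    objects: list[ObjectSpec] = []
    for k, idx in enumerate(order):
        c = roster[idx]
        d = c.diameter_mean * (1 + np.clip(rng.normal(0, c.diameter_cv), -3 * c.diameter_cv, 3 * c.diameter_cv))
        speed = rng.uniform(lo, hi)
        offset = float(np.clip(rng.normal(0, lateral_sigma_um), -4, 4))
        objects.append(
            ObjectSpec(
                kind=c.kind,
                diameter=float(d),
                speed=float(speed),
                arrival_time=float(t),
                lateral_offset=offset,
                n_granules=c.n_granules,
                granule_contrast=c.granule_contrast,
                granule_diameter=c.granule_diameter,
                bright_spot=c.bright_spot,
                rim_transmission=c.rim_transmission,
                body_transmission=c.body_transmission,
                center_transmission=c.center_transmission,
                n_cells=c.n_cells,
                width=c.width,
                label=c.label,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        t += rng.uniform(*spacing_us)
    return ScenePlan(objects=objects, seed=seed)


def render_object(spec: ObjectSpec, pitch: float = 0.32) -> TransmissionMap:
    """Render the transmission map for one ObjectSpec."""
    if spec.kind == "bead":
        center = spec.center_transmission if spec.bright_spot else max(1.0, spec.body_transmission)
        if not spec.bright_spot:
            # no bright spot: the centre stays at the body level
            m = make_bead(
                spec.diameter,
                rim_transmission=spec.rim_transmission,
                center_transmission=1.0,
                pitch=pitch,
                body_transmission=spec.body_transmission,
            )
            return m
        return make_bead(
            spec.diameter,
            rim_transmission=spec.rim_transmission,
            center_transmission=center,
            pitch=pitch,
            body_transmission=spec.body_transmission,
        )
    if spec.kind == "cell":
        return make_cell(
            spec.diameter,
            n_granules=spec.n_granules,
            granule_diameter=spec.granule_diameter,
            granule_contrast=spec.granule_contrast,
            seed=spec.seed,
            pitch=pitch,
            body_transmission=spec.body_transmission,
        )
    if spec.kind == "alga_colony":
        width = spec.width if spec.width is not None else spec.diameter / max(spec.n_cells, 1)
        return make_alga_colony(
            spec.n_cells,
            cell_length=spec.diameter,
            cell_width=width,
            pitch=pitch,
            body_transmission=spec.body_transmission,
        )
    raise ValueError(f"unknown object kind {spec.kind!r}")
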