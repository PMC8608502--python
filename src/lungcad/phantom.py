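"""Synthetic thoracic CT phantoms with known lung and nodule ground truth.

A phantom is a declarative :class:`PhantomSpec` rasterized onto a desk-scale
anisotropic grid: a soft-tissue body ellipsoid (default 40 HU) on an air
background (−1000 HU), two low-attenuation lung ellipsoids (−850 HU), bright
random-walk vessel tubes (50 HU) confined to the lungs, spherical nodules
with partial-volume shading at their boundary, and additive Gaussian noise.
The noise-free lung rasterization is returned as the segmentation truth;
juxtapleural nodules carve a matching notch into it, mirroring what dense
tissue attached to the pleura does to the air-like lung region on a real
scan.

Randomness is split into named substreams (vessels, nodule companions,
noise) derived from one seed, so changing the vessel count never changes the
noise realisation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .core import BinaryMask, CTVolume, clamp_hu
from .errors import ValidationError

PLACEMENTS = ("isolated", "juxtapleural", "juxtavascular")


@dataclass
class GroundTruthNodule:
    """One annotated nodule: world-mm center (z, y, x), radius, HU, placement."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    hu: float
    placement: str = "isolated"

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(v) for v in self.center_mm)
        if self.radius_mm <= 0:
            raise ValidationError(f"nodule radius_mm must be positive, got {self.radius_mm}")
        if self.placement not in PLACEMENTS:
            raise ValidationError(
                f"placement must be one of {PLACEMENTS}, got {self.placement!r}"
            )


def _default_nodules() -> list[GroundTruthNodule]:
    # positioned for the default geometry below (grid center (63, 63.5, 63.5))
    return [
        GroundTruthNodule(center_mm=(73.0, 68.5, 35.5), radius_mm=5.0, hu=-200.0,
                          placement="isolated"),
        GroundTruthNodule(center_mm=(63.0, 63.5, 115.5), radius_mm=4.0, hu=-200.0,
                          placement="juxtapleural"),
        GroundTruthNodule(center_mm=(55.0, 57.5, 39.5), radius_mm=4.0, hu=-200.0,
                          placement="juxtavascular"),
    ]


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic chest volume.

    Defaults give a 64×128×128 grid at (2, 1, 1) mm — desk-scale but
    anisotropic like clinical CT — holding two ~160 ml lungs, eight vessels,
    and one nodule of each placement class at 650 HU contrast over lung.
    """

    grid_shape: tuple[int, int, int] = (64, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.0, 1.0, 1.0)
    background_hu: float = -1000.0
    body_semi_axes_mm: tuple[float, float, float] = (58.0, 52.0, 58.0)
    body_hu: float = 40.0
    lung_semi_axes_mm: tuple[float, float, float] = (45.0, 35.0, 24.0)
    lung_offset_x_mm: float = 28.0
    lung_hu: float = -850.0
    vessel_count: int = 8
    vessel_radius_mm: tuple[float, float] = (0.8, 1.5)
    vessel_hu: float = 50.0
    nodules: list[GroundTruthNodule] = field(default_factory=_default_nodules)
    noise_sd_hu: float = 20.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.body_semi_axes_mm = tuple(float(s) for s in self.body_semi_axes_mm)
        self.lung_semi_axes_mm = tuple(float(s) for s in self.lung_semi_axes_mm)
        self.vessel_radius_mm = tuple(float(s) for s in self.vessel_radius_mm)
        self.nodules = [
            n if isinstance(n, GroundTruthNodule) else GroundTruthNodule(**n)
            for n in self.nodules
        ]
        self.validate()

    # --- geometry helpers -------------------------------------------------
    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.spacing_mm)

    @property
    def lung_centers_mm(self) -> list[np.ndarray]:
        c = self.center_mm
        off = np.array([0.0, 0.0, self.lung_offset_x_mm])
        return [c - off, c + off]

    def _lung_f(self, point_mm) -> float:
        """Min over both lungs of the ellipsoid implicit value (<1 inside)."""
        semi = np.asarray(self.lung_semi_axes_mm)
        p = np.asarray(point_mm, dtype=float)
        return min(float(np.sum(((p - c) / semi) ** 2)) for c in self.lung_centers_mm)

    def validate(self) -> None:
        if self.noise_sd_hu < 0:
            raise ValidationError("noise_sd_hu must be >= 0")
        if any(s <= 0 for s in self.spacing_mm) or any(n < 4 for n in self.grid_shape):
            raise ValidationError("grid_shape/spacing_mm out of range")
        body = np.asarray(self.body_semi_axes_mm)
        lung = np.asarray(self.lung_semi_axes_mm)
        # sample the lung ellipsoid surface; every point must fall inside the body
        theta = np.linspace(0.0, np.pi, 13)
        phi = np.linspace(0.0, 2 * np.pi, 25)
        tt, pp = np.meshgrid(theta, phi)
        unit = np.stack(
            [np.cos(tt), np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp)], axis=-1
        ).reshape(-1, 3)
        for c in self.lung_centers_mm:
            surface = c + unit * lung
            f_body = np.sum(((surface - self.center_mm) / body) ** 2, axis=1)
            if np.any(f_body >= 1.0):
                raise ValidationError("lungs: lung ellipsoids not strictly inside body")
        for i, nod in enumerate(self.nodules):
            if nod.hu <= self.lung_hu:
                raise ValidationError(f"nodules[{i}].hu: must exceed lung HU {self.lung_hu}")
            f = self._lung_f(nod.center_mm)
            if nod.placement == "juxtapleural":
                reach = nod.radius_mm / float(np.min(lung))
                if not ((1.0 - reach) ** 2 <= f <= (1.0 + reach) ** 2):
                    raise ValidationError(
                        f"nodules[{i}].center_mm: juxtapleural center not on a lung boundary"
                    )
            elif f >= 1.0:
                raise ValidationError(f"nodules[{i}].center_mm: center not inside a lung")

    # --- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PhantomSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def _coord_grids(shape, spacing):
    z = (np.arange(shape[0]) * spacing[0])[:, None, None]
    y = (np.arange(shape[1]) * spacing[1])[None, :, None]
    x = (np.arange(shape[2]) * spacing[2])[None, None, :]
    return z, y, x


def _ellipsoid(shape, spacing, center, semi) -> np.ndarray:
    z, y, x = _coord_grids(shape, spacing)
    return (
        ((z - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((x - center[2]) / semi[2]) ** 2
    ) < 1.0


def _stamp_sphere(target: np.ndarray, spacing, center_mm, radius_mm, pad_mm=0.0):
    """Set True inside a sphere, touching only a local box. Returns nothing."""
    shape = target.shape
    sp = np.asarray(spacing)
    c = np.asarray(center_mm)
    lo = np.maximum(np.floor((c - radius_mm - pad_mm) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((c + radius_mm + pad_mm) / sp).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    z, y, x = _coord_grids(tuple(hi - lo), tuple(sp))
    d2 = (z + lo[0] * sp[0] - c[0]) ** 2 + (y + lo[1] * sp[1] - c[1]) ** 2 + (
        x + lo[2] * sp[2] - c[2]
    ) ** 2
    target[box] |= d2 <= radius_mm ** 2


def _sphere_fraction(shape, spacing, center_mm, radius_mm, ramp_mm) -> tuple:
    """Partial-volume fraction field of a sphere on a local box.

    Returns (box slices, fraction array); fraction ramps linearly from 1 to 0
    across ``ramp_mm`` centred on the sphere surface.
    """
    sp = np.asarray(spacing)
    c = np.asarray(center_mm)
    extent = radius_mm + ramp_mm + float(sp.max())
    lo = np.maximum(np.floor((c - extent) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((c + extent) / sp).astype(int) + 1, shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    z, y, x = _coord_grids(tuple(hi - lo), tuple(sp))
    d = np.sqrt(
        (z + lo[0] * sp[0] - c[0]) ** 2
        + (y + lo[1] * sp[1] - c[1]) ** 2
        + (x + lo[2] * sp[2] - c[2]) ** 2
    )
    frac = np.clip(0.5 + (radius_mm - d) / ramp_mm, 0.0, 1.0)
    return box, frac


def _draw_vessels(vessel_mask, lung_mask, spec: PhantomSpec, rng: np.random.Generator):
    lung_idx = np.argwhere(lung_mask)
    if lung_idx.size == 0:
        return
    sp = np.asarray(spec.spacing_mm)
    # honour the "isolated" placement class: vessels keep a clearance of
    # one ramp width (~2 mm) from isolated nodules so those stay unattached
    exclusions = [
        (np.asarray(n.center_mm), n.radius_mm + 2.0)
        for n in spec.nodules
        if n.placement == "isolated"
    ]

    def excluded(p):
        return any(np.linalg.norm(p - c) < r for c, r in exclusions)

    for _ in range(spec.vessel_count):
        start = lung_idx[rng.integers(len(lung_idx))] * sp
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(*spec.vessel_radius_mm)
        point = start.astype(float)
        for _step in range(80):  # ~80 mm max tube length
            idx = np.round(point / sp).astype(int)
            if np.any(idx < 0) or np.any(idx >= np.asarray(spec.grid_shape)):
                break
            if not lung_mask[tuple(idx)] or excluded(point):
                break
            _stamp_sphere(vessel_mask, spec.spacing_mm, point, radius)
            direction = direction + rng.normal(scale=0.25, size=3)
            direction /= np.linalg.norm(direction)
            point = point + direction  # 1 mm steps
    vessel_mask &= lung_mask


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[CTVolume, BinaryMask, list[GroundTruthNodule]]:
    """Rasterize a phantom; returns (volume, lung truth mask, nodule truth).

    Deterministic for a fixed (spec, seed); distinct seeds differ only in
    the vessel and noise draws.
    """
    spec.validate()
    shape, spacing = spec.grid_shape, spec.spacing_mm
    vol = np.full(shape, spec.background_hu, dtype=np.float64)

    body = _ellipsoid(shape, spacing, spec.center_mm, spec.body_semi_axes_mm)
    vol[body] = spec.body_hu
    lung = np.zeros(shape, dtype=bool)
    for c in spec.lung_centers_mm:
        lung |= _ellipsoid(shape, spacing, c, spec.lung_semi_axes_mm)
    vol[lung] = spec.lung_hu
    lung_truth = lung.copy()

    vessel_mask = np.zeros(shape, dtype=bool)
    _draw_vessels(vessel_mask, lung, spec, np.random.default_rng((int(seed), 2)))

    # companion vessels that make juxtavascular nodules juxtavascular
    rng_companion = np.random.default_rng((int(seed), 3))
    for nod in spec.nodules:
        if nod.placement != "juxtavascular":
            continue
        direction = rng_companion.normal(size=3)
        direction /= np.linalg.norm(direction)
        point = np.asarray(nod.center_mm) + direction * nod.radius_mm
        for _step in range(20):
            idx = np.round(point / np.asarray(spacing)).astype(int)
            if np.any(idx < 0) or np.any(idx >= np.asarray(shape)) or not lung[tuple(idx)]:
                break
            _stamp_sphere(vessel_mask, spacing, point, 1.2)
            point = point + direction
        vessel_mask &= lung
    vol[vessel_mask] = spec.vessel_hu

    ramp = float(np.mean(spacing))
    for nod in spec.nodules:
        box, frac = _sphere_fraction(shape, spacing, nod.center_mm, nod.radius_mm, ramp)
        vol[box] = frac * nod.hu + (1.0 - frac) * vol[box]
        if nod.placement == "juxtapleural":
            notch = np.zeros(shape, dtype=bool)
            _stamp_sphere(notch, spacing, nod.center_mm, nod.radius_mm)
            lung_truth &= ~notch

    if spec.noise_sd_hu > 0:
        noise_rng = np.random.default_rng((int(seed), 1))
        vol = vol + noise_rng.normal(0.0, spec.noise_sd_hu, size=shape)

    volume = CTVolume(
        voxels=clamp_hu(vol),
        spacing=spacing,
        origin=(0.0, 0.0, 0.0),
        source_id=f"phantom(seed={seed})",
    )
    return volume, BinaryMask(values=lung_truth.astype(np.uint8)), list(spec.nodules)


def isolated_nodule_spec(
    n_nodules: int = 10,
    seed: int = 0,
    diameter_range_mm: tuple[float, float] = (6.0, 16.0),
    nodule_hu: float = -200.0,
    noise_sd_hu: float = 20.0,
    **spec_overrides,
) -> PhantomSpec:
    """A detection-benchmark spec: well-separated isolated nodules only.

    Nodule centers are drawn (deterministically per ``seed``) inside the
    lungs with a 3 mm clearance from the lung surface and at least 12 mm
    plus the two radii between centers.
    """
    base = PhantomSpec(nodules=[], noise_sd_hu=noise_sd_hu, **spec_overrides)
    rng = np.random.default_rng((int(seed), 4))
    semi = np.asarray(base.lung_semi_axes_mm)
    placed: list[GroundTruthNodule] = []
    attempts = 0
    while len(placed) < n_nodules:
        attempts += 1
        if attempts > 20000:
            raise ValidationError(
                f"could not place {n_nodules} separated nodules; reduce count or sizes"
            )
        radius = rng.uniform(*diameter_range_mm) / 2.0
        lung_center = base.lung_centers_mm[int(rng.integers(2))]
        inner = semi - radius - 3.0
        if np.any(inner <= 0):
            continue
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) > 1.0:
            continue
        center = lung_center + u * inner
        if any(
            np.linalg.norm(center - np.asarray(p.center_mm)) < p.radius_mm + radius + 12.0
            for p in placed
        ):
            continue
        placed.append(
            GroundTruthNodule(center_mm=tuple(center), radius_mm=float(radius),
                              hu=float(nodule_hu), placement="isolated")
        )
    base.nodules = placed
    base.validate()
    return base


TRUTH_COLUMNS = ["z_mm", "y_mm", "x_mm", "radius_mm", "hu", "placement"]


def write_truth(nodules: list[GroundTruthNodule], path: str | os.PathLike) -> None:
    """Export nodule ground truth as CSV."""
    rows = [
        {"z_mm": n.center_mm[0], "y_mm": n.center_mm[1], "x_mm": n.center_mm[2],
         "radius_mm": n.radius_mm, "hu": n.hu, "placement": n.placement}
        for n in nodules
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth(path: str | os.PathLike) -> list[GroundTruthNodule]:
    frame = pd.read_csv(path, float_precision="round_trip")
    return [
        GroundTruthNodule(
            center_mm=(row["z_mm"], row["y_mm"], row["x_mm"]),
            radius_mm=float(row["radius_mm"]),
            hu=float(row["hu"]),
            placement=str(row["placement"]),
        )
        for _, row in frame.iterrows()
    ]
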