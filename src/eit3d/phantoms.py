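"""Ground-truth conductivity phantoms.

Two families:

* acrylic inclusion phantoms — near-insulating spheres/cylinders/cubes in a
  saline background (350 uS/cm background, 0.0001 uS/cm inclusions);
* maize-ear gradient phantoms — conductivity decaying exponentially from a
  centre, with an in-plane decay scale modulated sinusoidally along z:

      f(x)   = exp(-x / s)
      s(z)   = 1 + a * sin(b z + c)
      Es     = exp(-Dxy*s(z)/bs1 - Dxy*s(z)/bs2 - Dz/bs3)
      sigma  = sigma_max * Es

  ``Dxy`` is the in-plane Euclidean distance of an element centroid to the
  phantom centre and ``Dz`` the axial distance. Note that ``Dxy`` appears in
  both of the first two exponent terms by design of the source model; the
  two terms simply combine into a single in-plane rate 1/bs1 + 1/bs2.

All distances and centres are centimetres; conductivities are uS/cm on the
spec surface and converted to S/m inside the generated fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fem import ConductivityField, US_PER_CM
from .geometry import CM, CylinderSpec
from .mesh import Mesh

KINDS = ("sphere", "cylinder", "cube")


@dataclass(frozen=True)
class Shape:
    """An inclusion primitive (cm units).

    sphere: size = (radius,); cylinder: size = (radius, height), axis along z;
    cube: size = (edge,) axis-aligned.
    """

    kind: str
    center: tuple[float, float, float]
    size: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if any(s <= 0 for s in self.size):
            raise ValueError("shape size parameters must be positive")
        n_expected = {"sphere": 1, "cylinder": 2, "cube": 1}[self.kind]
        if len(self.size) != n_expected:
            raise ValueError(f"{self.kind} expects {n_expected} size parameter(s)")

    def contains(self, points_cm: np.ndarray) -> np.ndarray:
        d = points_cm - np.asarray(self.center)
        if self.kind == "sphere":
            return (d**2).sum(axis=1) <= self.size[0] ** 2
        if self.kind == "cylinder":
            r, h = self.size
            return (d[:, 0] ** 2 + d[:, 1] ** 2 <= r**2) & (np.abs(d[:, 2]) <= h / 2)
        half = self.size[0] / 2
        return np.all(np.abs(d) <= half, axis=1)


@dataclass(frozen=True)
class AcrylicPhantomSpec:
    shapes: tuple[Shape, ...]
    sigma_background: float = 350.0  # uS/cm
    sigma_inclusion: float = 0.0001  # uS/cm

    def __post_init__(self) -> None:
        if self.sigma_background <= 0 or self.sigma_inclusion <= 0:
            raise ValueError("conductivities must be positive")


@dataclass(frozen=True)
class MaizePhantomSpec:
    center: tuple[float, float, float] = (0.0, 0.0, 4.0)
    s: float = 1.0  # radial decay scale (unused by Es directly; kept for f(x))
    a: float = 0.1  # sinusoid amplitude of the z modulation
    b: float = 1.0  # sinusoid frequency (rad/cm)
    c: float = 0.0  # sinusoid phase
    bs: tuple[float, float, float] = (4.0, 4.0, 6.0)  # directional decay rates (cm)
    sigma_max: float = 350.0  # uS/cm at the centre

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("decay scale s must be positive")
        if not (0 <= self.a < 1):
            raise ValueError("sinusoid amplitude a must lie in [0, 1)")
        if any(v <= 0 for v in self.bs):
            raise ValueError("bs decay rates must be positive")
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")


def radial_decay(x, s: float):
    """exp(-x/s); strictly decreasing in the distance x."""
    if s <= 0:
        raise ValueError("decay scale s must be positive")
    return np.exp(-np.asarray(x, dtype=float) / s)


def axial_scale(z, a: float, b: float, c: float):
    """1 + a*sin(b z + c), bounded in [1-a, 1+a]."""
    return 1.0 + a * np.sin(b * np.asarray(z, dtype=float) + c)


def maize_field(mesh: Mesh, spec: MaizePhantomSpec) -> ConductivityField:
    """Gradient conductivity field sigma_max * Es over element centroids."""
    cent = mesh.element_centroids / CM  # cm
    cx, cy, cz = spec.center
    lo, hi = cent.min(axis=0), cent.max(axis=0)
    if not (np.all(np.asarray(spec.center) >= lo - 1e-9) and np.all(np.asarray(spec.center) <= hi + 1e-9)):
        warnings.warn("phantom centre lies outside the mesh bounding box", stacklevel=2)
    dxy = np.hypot(cent[:, 0] - cx, cent[:, 1] - cy)
    dz = np.abs(cent[:, 2] - cz)
    sz = axial_scale(cent[:, 2], spec.a, spec.b, spec.c)
    es = np.exp(-dxy * sz / spec.bs[0] - dxy * sz / spec.bs[1] - dz / spec.bs[2])
    return ConductivityField(spec.sigma_max * es * US_PER_CM, mesh.mesh_hash)


def acrylic_field(mesh: Mesh, spec: AcrylicPhantomSpec) -> ConductivityField:
    """Piecewise-constant field: inclusion value inside any shape, else background."""
    cent = mesh.element_centroids / CM
    vals = np.full(mesh.n_elements, spec.sigma_background, dtype=float)
    for shape in spec.shapes:
        vals[shape.contains(cent)] = spec.sigma_inclusion
    return ConductivityField(vals * US_PER_CM, mesh.mesh_hash)


@dataclass
class PhantomSampler:
    """Seeded uniform sampler over phantom parameter ranges.

    Default centre ranges keep inclusion centroids within the central 60% of
    the cylinder both radially and axially; sizes default to 0.8-1.6 cm radii.
    """

    cylinder: CylinderSpec = field(default_factory=CylinderSpec)
    seed: int = 0
    center_radial_frac: float = 0.6
    center_axial_frac: tuple[float, float] = (0.2, 0.8)
    size_range: tuple[float, float] = (0.8, 1.6)  # cm
    kinds: tuple[str, ...] = KINDS
    n_shapes: tuple[int, int] = (1, 1)
    a_range: tuple[float, float] = (0.0, 0.2)
    b_range: tuple[float, float] = (0.5, 1.5)
    c_range: tuple[float, float] = (0.0, 6.283185307179586)
    bs_range: tuple[float, float] = (2.0, 6.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.size_range, self.a_range, self.b_range, self.c_range, self.bs_range):
            if hi < lo:
                raise ValueError("empty sampling range")
        self._rng = np.random.default_rng(self.seed)

    def _center(self) -> tuple[float, float, float]:
        rmax = self.center_radial_frac * self.cylinder.radius
        while True:
            x, y = self._rng.uniform(-rmax, rmax, size=2)
            if x * x + y * y <= rmax * rmax:
                break
        z = self._rng.uniform(*(f * self.cylinder.height for f in self.center_axial_frac))
        return (float(x), float(y), float(z))

    def sample_acrylic(self) -> AcrylicPhantomSpec:
        n = int(self._rng.integers(self.n_shapes[0], self.n_shapes[1] + 1))
        shapes = []
        for _ in range(n):
            kind = str(self._rng.choice(self.kinds))
            center = self._center()
            if kind == "cylinder":
                size = (float(self._rng.uniform(*self.size_range)),
                        float(self._rng.uniform(*self.size_range)) * 2)
            else:
                size = (float(self._rng.uniform(*self.size_range)),)
            shapes.append(Shape(kind, center, size))
        return AcrylicPhantomSpec(tuple(shapes))

    def sample_maize(self) -> MaizePhantomSpec:
        return MaizePhantomSpec(
            center=self._center(),
            s=1.0,
            a=float(self._rng.uniform(*self.a_range)),
            b=float(self._rng.uniform(*self.b_range)),
            c=float(self._rng.uniform(*self.c_range)),
            bs=tuple(float(self._rng.uniform(*self.bs_range)) for _ in range(3)),
        )

    def sample(self, kind: str):
        if kind == "acrylic":
            return self.sample_acrylic()
        if kind == "maize":
            return self.sample_maize()
        raise ValueError(f"unknown phantom family {kind!r}")
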