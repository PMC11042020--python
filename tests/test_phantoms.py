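"""Phantom generators: decay formulas, inclusion membership, seeded sampling."""

import numpy as np
import pytest

from eit3d.fem import US_PER_CM, ConductivityField
from eit3d.geometry import CM, CylinderSpec, build_cylinder_mesh
from eit3d.mesh import Mesh
from eit3d.phantoms import (
    AcrylicPhantomSpec,
    MaizePhantomSpec,
    PhantomSampler,
    Shape,
    acrylic_field,
    axial_scale,
    maize_field,
    radial_decay,
)


def test_radial_decay_values_and_monotonicity():
    assert radial_decay(0.0, 3.0) == 1.0
    assert radial_decay(2.5, 2.5) == pytest.approx(np.exp(-1), rel=1e-12)
    xs = np.linspace(0, 10, 50)
    f = radial_decay(xs, 1.7)
    assert np.all(np.diff(f) < 0)
    with pytest.raises(ValueError):
        radial_decay(1.0, 0.0)


def test_axial_scale_bounds_and_extrema():
    zs = np.linspace(-10, 10, 1001)
    s = axial_scale(zs, 0.3, 2.0, 0.5)
    assert np.all((s >= 0.7 - 1e-12) & (s <= 1.3 + 1e-12))
    assert axial_scale(0.0, 0.0, 5.0, 1.0) == 1.0
    assert axial_scale((np.pi / 2 - 0.5) / 2.0, 0.25, 2.0, 0.5) == pytest.approx(1.25)
    assert axial_scale((-np.pi / 2 - 0.5) / 2.0, 0.25, 2.0, 0.5) == pytest.approx(0.75)


def test_maize_field_matches_direct_reevaluation(mesh_default):
    spec = MaizePhantomSpec(center=(0.5, -0.3, 3.7), a=0.15, b=1.2, c=0.4,
                            bs=(3.0, 5.0, 4.0), sigma_max=350.0)
    fld = maize_field(mesh_default, spec)
    # independent per-element re-evaluation with plain Python arithmetic
    cent = mesh_default.element_centroids / CM
    for i in range(0, mesh_default.n_elements, 97):
        x, y, z = cent[i]
        dxy = ((x - 0.5) ** 2 + (y + 0.3) ** 2) ** 0.5
        dz = abs(z - 3.7)
        sz = 1 + 0.15 * np.sin(1.2 * z + 0.4)
        es = np.exp(-dxy * sz / 3.0 - dxy * sz / 5.0 - dz / 4.0)
        assert fld.values[i] == pytest.approx(350.0 * es * US_PER_CM, rel=1e-12)


def test_maize_field_center_and_bounds(mesh_default):
    cent = mesh_default.element_centroids / CM
    i = 7
    spec = MaizePhantomSpec(center=tuple(cent[i]), sigma_max=220.0)
    fld = maize_field(mesh_default, spec)
    assert fld.values[i] == pytest.approx(220.0 * US_PER_CM, rel=1e-12)
    es = fld.values / (220.0 * US_PER_CM)
    assert np.all((es > 0) & (es <= 1 + 1e-12))


def test_maize_field_translation_invariance(mesh_default):
    spec = MaizePhantomSpec(center=(0.2, 0.1, 4.0), a=0.1, b=0.0, c=0.0)
    f1 = maize_field(mesh_default, spec)
    shift = np.array([1.0, -2.0, 0.0]) * CM  # keep b=0 so z-phase is immaterial
    shifted = Mesh(nodes=mesh_default.nodes + shift, tets=mesh_default.tets,
                   boundary_faces=mesh_default.boundary_faces,
                   electrode_faces=mesh_default.electrode_faces)
    spec2 = MaizePhantomSpec(center=(1.2, -1.9, 4.0), a=0.1, b=0.0, c=0.0)
    f2 = maize_field(shifted, spec2)
    assert np.allclose(f1.values, f2.values, rtol=1e-12)


def test_maize_center_outside_mesh_warns(mesh_default):
    with pytest.warns(UserWarning, match="outside"):
        maize_field(mesh_default, MaizePhantomSpec(center=(20.0, 0.0, 4.0)))


def test_maize_spec_validation():
    with pytest.raises(ValueError):
        MaizePhantomSpec(a=1.5)
    with pytest.raises(ValueError):
        MaizePhantomSpec(bs=(1.0, -1.0, 1.0))
    with pytest.raises(ValueError):
        MaizePhantomSpec(s=0.0)


def test_acrylic_default_values(mesh_fine):
    spec = AcrylicPhantomSpec((Shape("sphere", (1.0, 0.0, 4.0), (1.5,)),))
    fld = acrylic_field(mesh_fine, spec)
    vals_uS = fld.to_uS_per_cm()
    assert np.any(np.isclose(vals_uS, 350.0))
    assert np.any(np.isclose(vals_uS, 0.0001))
    assert set(np.round(np.unique(vals_uS), 6)) <= {0.0001, 350.0}


def test_acrylic_shape_outside_domain_gives_uniform_background(mesh_default):
    spec = AcrylicPhantomSpec((Shape("sphere", (30.0, 0.0, 4.0), (1.0,)),))
    fld = acrylic_field(mesh_default, spec)
    assert np.allclose(fld.to_uS_per_cm(), 350.0)


def test_acrylic_multiple_shapes_inclusion_wins(mesh_fine):
    shapes = (
        Shape("sphere", (1.0, 0.0, 3.0), (1.4,)),
        Shape("cube", (1.0, 0.0, 3.0), (1.5,)),  # overlapping
        Shape("cylinder", (-1.5, 0.5, 5.0), (0.8, 1.5)),
    )
    fld = acrylic_field(mesh_fine, AcrylicPhantomSpec(shapes))
    assert np.count_nonzero(np.isclose(fld.to_uS_per_cm(), 0.0001)) > 0


def test_sphere_inclusion_volume_within_ten_percent(mesh_fine):
    mesh = mesh_fine
    r = 1.5
    sh = Shape("sphere", (1.0, 0.0, 4.0), (r,))
    inside = sh.contains(mesh.element_centroids / CM)
    vol_cm3 = mesh.element_volumes[inside].sum() / CM**3
    v_true = 4 / 3 * np.pi * r**3
    assert abs(vol_cm3 - v_true) / v_true < 0.10


def test_sampler_determinism_and_ranges():
    cyl = CylinderSpec()
    s1 = PhantomSampler(cylinder=cyl, seed=42)
    s2 = PhantomSampler(cylinder=cyl, seed=42)
    specs1 = [s1.sample("acrylic") for _ in range(20)]
    specs2 = [s2.sample("acrylic") for _ in range(20)]
    assert specs1 == specs2
    s3 = PhantomSampler(cylinder=cyl, seed=43)
    assert [s3.sample("acrylic") for _ in range(20)] != specs1

    s4 = PhantomSampler(cylinder=cyl, seed=7)
    rmax = 0.6 * cyl.radius
    for _ in range(1000):
        sp = s4.sample_acrylic()
        for sh in sp.shapes:
            x, y, z = sh.center
            assert x * x + y * y <= rmax * rmax + 1e-12
            assert 0.2 * cyl.height - 1e-12 <= z <= 0.8 * cyl.height + 1e-12


def test_sampler_maize_specs_valid():
    s = PhantomSampler(seed=3)
    for _ in range(100):
        sp = s.sample("maize")
        assert 0 <= sp.a < 1
        assert all(b > 0 for b in sp.bs)


def test_generated_fields_satisfy_invariants(mesh_default):
    s = PhantomSampler(seed=11)
    for _ in range(5):
        for kind in ("acrylic", "maize"):
            sp = s.sample(kind)
            fld = acrylic_field(mesh_default, sp) if kind == "acrylic" else maize_field(mesh_default, sp)
            assert isinstance(fld, ConductivityField)
            assert fld.values.size == mesh_default.n_elements
            assert np.all(fld.values > 0)
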