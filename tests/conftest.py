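import math

import numpy as np
import pytest

from fmvsd.devices import GraftSpec, StentSpec, Fenestration, auto_markers
from fmvsd.fem import MaterialSection


@pytest.fixture(scope="session")
def steel_section():
    return MaterialSection.circular(193000.0, 0.3, 0.125, shear_factor=None)


@pytest.fixture(scope="session")
def mini_graft():
    """Small 3-stent device for fast stage/pipeline tests."""
    stents = [
        StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0, axial_position=0.0),
        StentSpec(n_peaks=5, height=14.0, diameter_proximal=26.0, diameter_distal=24.0, axial_position=16.0),
        StentSpec(n_peaks=5, height=14.0, diameter_proximal=22.0, diameter_distal=20.0, axial_position=32.0),
    ]
    fens = [Fenestration(stent_index=0, angle=math.radians(-60.0), axial_offset=0.0, radius=3.0),
            Fenestration(stent_index=0, angle=math.radians(30.0), axial_offset=2.0, radius=3.0)]
    return GraftSpec(stents=stents, fenestrations=fens, markers=auto_markers(stents, fens))


@pytest.fixture(scope="session")
def mini_scene(mini_graft):
    """Rendered synthetic scene around the 3-stent device (straight tube)."""
    from fmvsd.synthetic import SceneSpec, build_scene

    spec = SceneSpec(
        device=mini_graft,
        seed=7,
        proximal_radius=12.0,
        distal_radius=11.0,
        mesh_sizes=(2.0, 0.5),
        image_size=(384, 384),
        pixel_spacing=0.8,
        name="mini",
    )
    return build_scene(spec)


def make_cantilever(n_elements, length=100.0, radius=0.5, E=193000.0, shear_factor=0.9):
    """Cantilever fixed at node 0, axis along x."""
    from fmvsd.fem import BeamAssembly

    sec = MaterialSection.circular(E, 0.3, 2 * radius, shear_factor=shear_factor)
    a = BeamAssembly()
    for k in range(n_elements + 1):
        a.add_node([k * length / n_elements, 0.0, 0.0])
    a.nodes[0].fixed_dofs[:] = True
    for k in range(n_elements):
        a.add_element(k, k + 1, sec)
    return a, sec


def make_ring(radius=14.0, n=90, wire=0.125, E=193000.0):
    """Plain circular wire ring in the x-y plane."""
    from fmvsd.fem import BeamAssembly

    sec = MaterialSection.circular(E, 0.3, wire, shear_factor=None)
    a = BeamAssembly()
    th = np.arange(n) * 2 * np.pi / n
    for t in th:
        a.add_node([radius * np.cos(t), radius * np.sin(t), 0.0])
    for k in range(n):
        a.add_element(k, (k + 1) % n, sec)
    return a, sec
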