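import numpy as np
import pytest

from retinaquant import synthgen as sg


@pytest.fixture(scope="session")
def plexus_scene():
    """One r=5 µm tube mid-corridor in a plexus grid on a spherical cap."""
    from retinaquant.studies import _vessel_scene

    spec, site_y = _vessel_scene(radius_um=5.0, seed=11)
    vol, truth = sg.make_plexus_volume(spec)
    return {"spec": spec, "vol": vol, "truth": truth, "site_y": site_y, "radius": 5.0}


@pytest.fixture(scope="session")
def tuft_scene():
    """A rendered medium tuft (12 nuclei, 3 stalks, 1 tunnel) scene."""
    surf = sg.SphericalCapSurface(1700.0, apex_zyx=(18.0, 60.0, 60.0))
    vessels = sg.plexus_vessel_grid(surf, (120.0, 120.0), pitch_um=22.0, radius_um=2.5)
    tuft = sg.TuftSpec(
        anchor_yx_um=(60.0, 60.0),
        n_nuclei=12,
        n_connections=3,
        n_tunnels=1,
        curved_nuclei_fraction=0.5,
        target_volume_um3=3.3e4,
        protrusion_height_um=45.0,
    )
    spec = sg.SceneSpec(
        seed=7,
        volume_shape=(88, 120, 120),
        spacing_um=(1.0, 1.0, 1.0),
        surface=surf,
        vessels=vessels,
        tufts=[tuft],
    )
    vol, truth = sg.make_tuft_volume(spec)
    return {"spec": spec, "vol": vol, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
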