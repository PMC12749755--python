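import numpy as np
import pytest

from aortaflow import synthetic


@pytest.fixture
def params():
    """Default noiseless acquisition on a small grid."""
    return synthetic.AcquisitionParams(grid_size=48, seed=0)


@pytest.fixture
def vessel(params):
    return synthetic.VesselSpec(
        center=(params.grid_size / 2, params.grid_size / 2), radius=15.0
    )


@pytest.fixture
def regurgitant_spec():
    return synthetic.WaveformSpec(
        forward_volume=100.0, rvol_true=45.0, reversal_shape="holodiastolic"
    )


@pytest.fixture
def regurgitant_phantom(params, vessel, regurgitant_spec):
    curve = synthetic.build_waveform(regurgitant_spec, params)
    return synthetic.render_phantom(curve, vessel, params, waveform_spec=regurgitant_spec)


def make_phantom(
    forward_volume=100.0,
    rvol=0.0,
    reversal="none",
    angulation=0.0,
    noise_sd=0.0,
    offset_coeffs=(0.0, 0.0, 0.0),
    seed=0,
    radius=15.0,
    profile="plug",
    grid_size=48,
    venc=180.0,
):
    params = synthetic.AcquisitionParams(
        grid_size=grid_size, noise_sd=noise_sd, offset_coeffs=offset_coeffs,
        seed=seed, venc=venc,
    )
    vessel = synthetic.VesselSpec(
        center=(grid_size / 2, grid_size / 2), radius=radius,
        angulation=angulation, profile=profile,
    )
    spec = synthetic.WaveformSpec(
        forward_volume=forward_volume, rvol_true=rvol, reversal_shape=reversal
    )
    curve = synthetic.build_waveform(spec, params)
    series = synthetic.render_phantom(curve, vessel, params, waveform_spec=spec)
    return series
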