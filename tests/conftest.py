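import numpy as np
import pytest

from mitralflow import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free default phantom: dataset, masks and ground truth."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse, short phantom for fast pipeline-level tests."""
    cfg = PhantomConfig(lv_radius_ed=20.0, lv_length=45.0, jet_radius=10.0, n_phases=20)
    return generate_phantom(cfg)


def uniform_field_dataset(v=(0.0, 0.0, 0.9), shape=(12, 14, 16), h=1.5, n_phases=3):
    """Dataset with a spatially uniform velocity everywhere, plus a full mask."""
    from mitralflow import Flow4DDataset, LVMaskStack

    nz, ny, nx = shape
    vel = np.zeros((n_phases, nz, ny, nx, 3))
    vel[..., 0], vel[..., 1], vel[..., 2] = v
    affine = np.diag([h, h, h, 1.0])
    ds = Flow4DDataset(
        velocity=vel,
        voxel_spacing=(h, h, h),
        affine=affine,
        phase_duration=30.0,
        rr_interval=30.0 * n_phases,
        venc=1.5,
    )
    mask = np.ones((n_phases, nz, ny, nx), dtype=bool)
    masks = LVMaskStack(mask=mask, voxel_spacing=(h, h, h), affine=affine)
    return ds, masks
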