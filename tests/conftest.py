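import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nmrcell as nc

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# study-condition susceptibilities (ppm): Shigemi glass vs 97% D2O / 3% H2O
CHI_GLASS = -9.075
CHI_SOLVENT = -9.011
HALF_CONTRAST = (CHI_GLASS - CHI_SOLVENT) / 2.0  # -0.032 ppm


@pytest.fixture(scope="session")
def shigemi_sim():
    """Shimmed field of the glass-bottom tube on a 64x64x256 grid at
    0.1 mm, interface on a voxel edge; shared by the forward-model,
    line-shape and extraction tests."""
    preset = nc.build_preset("shigemi", chi_glass=CHI_GLASS,
                             chi_solvent=CHI_SOLVENT, solvent_top=17.0)
    grid = nc.VoxelGrid.for_interface((64, 64, 256), 0.1,
                                      fraction_below=83 / 256)
    chi_map = nc.voxelize(preset.scene, grid, supersampling=3)
    ref_map = nc.voxelize(preset.shim_reference, grid, supersampling=3)
    field = nc.differential_field(chi_map, ref_map)
    solvent = np.abs(chi_map.chi - CHI_SOLVENT) <= 1e-9
    return {"preset": preset, "grid": grid, "chi_map": chi_map,
            "field": field, "solvent": solvent,
            "chi_glass": CHI_GLASS, "chi_solvent": CHI_SOLVENT}


def interface_slice_edge(sim, z0=0.0, z1=0.3):
    """Upfield edge (0.5th percentile) of solvent offsets in a thin
    layer above the interface — the reading convention of the
    slice-selection measurement."""
    zs = sim["grid"].axis_coords(2)
    Z = np.broadcast_to(zs[None, None, :], sim["solvent"].shape)
    sel = sim["solvent"] & (Z >= z0) & (Z <= z1)
    return float(np.percentile(sim["field"].offset_ppm[sel], 0.5))


def bulk_slice_value(sim, h=13.0, half=0.3):
    zs = sim["grid"].axis_coords(2)
    Z = np.broadcast_to(zs[None, None, :], sim["solvent"].shape)
    sel = sim["solvent"] & (Z >= h - half) & (Z <= h + half)
    return float(np.median(sim["field"].offset_ppm[sel]))


@pytest.fixture(scope="session")
def microcell_sims():
    """Voxelized microcell fields with and without the access channel
    (solvent ellipsoid in resin, 0.1 mm grid)."""
    chi_solvent, chi_resin = -9.011, -9.40
    grid = nc.VoxelGrid.centered((4.8, 4.8, 38.4), 0.1)
    out = {}
    for channel in (False, True):
        preset = nc.build_preset("microcell", chi_solvent=chi_solvent,
                                 chi_resin=chi_resin, channel=channel,
                                 background_chi=chi_resin)
        chi_map = nc.voxelize(preset.scene, grid, supersampling=3)
        out[channel] = {"chi_map": chi_map,
                        "field": nc.forward_field_fft(chi_map)}
    out["grid"] = grid
    out["chi_solvent"] = chi_solvent
    out["chi_resin"] = chi_resin
    return out


def microcell_interior_mask(grid, erode_mm=0.25, semi_axes=(1.65, 1.65, 11.5)):
    """Voxels safely inside the cavity (semi-axes shrunk by erode_mm)."""
    a, b, c = (s - erode_mm for s in semi_axes)
    X, Y, Z = np.meshgrid(*[grid.axis_coords(i) for i in range(3)],
                          indexing="ij")
    return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
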