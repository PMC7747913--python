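"""Shared fixtures: small phantoms, desk geometry, truth sampling."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.ndimage as ndi

import octmosaic as om


@pytest.fixture(scope="session")
def phantom():
    """Small tracking phantom: 10 degrees at 10 um/px (300 px)."""
    return om.make_phantom(0, extent_deg=10.0, vessel_density=0.10)


@pytest.fixture(scope="session")
def desk_geometry():
    return om.AcquisitionGeometry.desk(samples=(128, 64), depth_samples=128)


@pytest.fixture(scope="session")
def trained_state(phantom):
    rng = np.random.default_rng(5)
    frames = [om.render_slo_frame(phantom, noise_sd=0.01,
                                  seed=int(rng.integers(2 ** 31)))
              for _ in range(20)]
    return om.train_tracker(frames)


@pytest.fixture(scope="session")
def fundus_phantom():
    """Registration phantom at the OCT x pitch (8.2 um/px)."""
    return om.make_phantom(11, extent_deg=14.0, vessel_density=0.10,
                           pitch_um=8.2)


def sample_truth(phantom, geometry, field, region="central"):
    """Ground-truth depth surface (in z pixels) at the volume's lateral
    sample positions — the oracle segmentations are compared against."""
    nx, nb = geometry.samples
    px, py = geometry.pixel_pitch_um
    cx_um, cy_um = geometry.region_centers[region]
    phn = phantom.shape[0]
    c = (phn - 1) / 2.0
    x_um = (np.arange(nx) - (nx - 1) / 2.0) * px
    arr = np.empty((nb, nx))
    for b in range(nb):
        y_um = (b - (nb - 1) / 2.0) * py
        sy = np.full(nx, np.clip(c + (y_um + cy_um) / phantom.pitch_um,
                                 0, phn - 1))
        sx = np.clip(c + (x_um + cx_um) / phantom.pitch_um, 0, phn - 1)
        arr[b] = ndi.map_coordinates(field, [sy, sx], order=1)
    return arr / geometry.z_pitch_um


@pytest.fixture(scope="session")
def truth_surfaces():
    return sample_truth
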