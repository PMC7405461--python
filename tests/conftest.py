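"""Shared fixtures: phantoms, desk-scale training run, cylinder sets.

The desk-scale training fixture is expensive (~3 min on one CPU) and
session-scoped; every test that needs a trained network shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

import heartsr as h
from heartsr.harness import derive_seeds


@pytest.fixture(scope="session")
def default_phantom():
    """One seeded default phantom with masks and probes."""
    return h.generate_phantom(h.default_phantom_spec(seed=3))


@pytest.fixture(scope="session")
def phantom_pair(default_phantom):
    """Aligned (high, low) pair of the default phantom under the default
    50%/50%/6-8ths degradation."""
    vol, _, _ = default_phantom
    return h.degrade_pair(vol, h.DegradationSpec())


def desk_conditions():
    """The desk-scale study conditions: 8 training + 4 held-out phantoms at
    48^3, a 2-level / 8-channel residual U-Net, 30 epochs, master seed 0."""
    seeds = derive_seeds(0)
    template = h.default_phantom_spec()
    degradation = h.DegradationSpec()
    net_cfg = h.NetworkConfig(levels=2, base_channels=8, seed=seeds["init"])
    train_cfg = h.TrainConfig(epochs=30, seed=seeds["shuffle"])
    return seeds, template, degradation, net_cfg, train_cfg


@pytest.fixture(scope="session")
def desk_run():
    """Train the desk-scale network once; reused by the learning, sweep and
    calliper-bias tests."""
    seeds, template, degradation, net_cfg, train_cfg = desk_conditions()
    train_ds = h.make_dataset(template, 8, seeds["data"], degradation, role="train")
    test_ds = h.make_dataset(template, 4, seeds["test"], degradation, role="test")
    net, report = h.fit(train_ds, net_cfg, train_cfg)
    summary = h.validate(net, test_ds)
    return {
        "seeds": seeds,
        "template": template,
        "degradation": degradation,
        "net": net,
        "report": report,
        "summary": summary,
        "test_ds": test_ds,
    }


@pytest.fixture(scope="session")
def make_cylinder():
    """Factory fixture for single-cylinder phantoms."""
    return cylinder_phantom


def cylinder_phantom(diameter: float, *, spacing=(1.6, 1.6, 1.6), matrix=(48, 48, 48), seed=0):
    """Noiseless single-cylinder phantom at a generic (off-grid) position,
    with the standard blood pool/myocardium parked away from the vessel."""
    fov = np.array([m * s for m, s in zip(matrix, spacing)])
    c = fov / 2
    off = 0.8  # sub-voxel offset; axis-aligned grid symmetry is atypical
    vessel = h.VesselSpec(
        points=((c[0] + off, c[1] + off, 0.1 * fov[2]), (c[0] + off, c[1] + off, 0.9 * fov[2])),
        diameter=diameter,
        intensity=0.95,
    )
    spec = h.default_phantom_spec(
        matrix=matrix,
        spacing=spacing,
        seed=seed,
        vessels=(vessel,),
        noise_sd=0.0,
        bias_field_amplitude=0.0,
        blood_center=tuple(c + np.array([0.23 * fov[0], -0.29 * fov[1], 0.0])),
        blood_semi_axes=(0.08 * fov[0], 0.07 * fov[1], 0.07 * fov[2]),
        myocardium_thickness=0.04 * float(fov.min()),
    )
    return h.generate_phantom(spec)
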