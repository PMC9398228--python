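"""Shared builders for synthetic phantom scenes used across the suite."""

import dataclasses

import numpy as np
import pytest

from mrlqa.core import AcquisitionSpec
from mrlqa.phantoms import (
    GroundTruth,
    PhantomSpec,
    default_diffusion_vials,
    default_relaxometry_vials,
)


@pytest.fixture(scope="session")
def relaxometry_setup():
    """14-vial relaxometry phantom with the clinical VFA/MESE protocols."""
    centers, dia, t1s, t2s = default_relaxometry_vials()
    spec = PhantomSpec(
        kind="vial_array",
        object_signal=1000.0,
        geometry={"vial_centers_mm": centers.tolist(), "vial_diameter_mm": dia},
    )
    acq_vfa = AcquisitionSpec(
        tr_ms=20.0, te_ms_list=[2.3], flip_angles_deg=[4.0, 22.0],
        voxel_size_mm=(2.0, 2.0, 3.0), matrix=(160, 160, 1),
    )
    acq_mese = AcquisitionSpec(
        tr_ms=4000.0, te_ms_list=[22.0 + 11.0 * k for k in range(8)],
        voxel_size_mm=(2.0, 2.0, 3.0), matrix=(160, 160, 1),
    )
    truth = GroundTruth(t1_ms=t1s, t2_ms=t2s)
    return {
        "spec": spec, "acq_vfa": acq_vfa, "acq_mese": acq_mese,
        "truth": truth, "centers": centers, "t1s": t1s, "t2s": t2s,
    }


@pytest.fixture(scope="session")
def diffusion_setup():
    """13-vial diffusion phantom with the clinical 4-b-value protocol."""
    centers, dia, adcs, rings = default_diffusion_vials()
    spec = PhantomSpec(
        kind="vial_array",
        object_signal=1000.0,
        geometry={"vial_centers_mm": centers.tolist(), "vial_diameter_mm": dia},
    )
    acq = AcquisitionSpec(
        tr_ms=15000.0, te_ms_list=[149.0],
        b_values_s_per_mm2=[0.0, 500.0, 900.0, 2000.0],
        voxel_size_mm=(1.6, 1.6, 4.0), matrix=(128, 128, 1),
    )
    truth = GroundTruth(adc_mm2_per_s=adcs)
    return {"spec": spec, "acq": acq, "truth": truth,
            "centers": centers, "adcs": adcs, "rings": rings}


def with_noise(truth: GroundTruth, sd: float, seed: int) -> GroundTruth:
    return dataclasses.replace(truth, noise_sd=sd, seed=seed)


@pytest.fixture(scope="session")
def cylinder_setup():
    """40-cm uniform cylinder with the dual-echo / dual-TR protocols."""
    spec = PhantomSpec(kind="cylinder", object_signal=100.0)
    acq = AcquisitionSpec(
        tr_ms=30.0, te_ms_list=[5.4, 6.9], flip_angles_deg=[60.0],
        voxel_size_mm=(3.0, 3.0, 10.0), matrix=(150, 150, 1),
    )
    return {"spec": spec, "acq": acq}


@pytest.fixture(scope="session")
def fiducial_identity():
    """Rendered fiducial volume with zero distortion plus its known grid."""
    from mrlqa.phantoms import generate_fiducial_volume

    spec = PhantomSpec(kind="fiducial3d", object_signal=100.0)
    vol, known = generate_fiducial_volume(spec, GroundTruth())
    return {"spec": spec, "vol": vol, "known": known}
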