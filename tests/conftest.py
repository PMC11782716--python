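"""Shared fixtures: small spiral fixtures and session-scoped reconstructions.

The expensive fixtures (64x64 reconstructions) are computed once per session
and shared between the unit and acceptance tests.  All randomness is seeded.
"""

import numpy as np
import pytest

from smscine import (PhantomSpec, design_spiral, simulate_kspace, STCRConfig,
                     reconstruct, phantom_frame)
from smscine.stcr import adjoint_baseline

MATRIX = 64
SPACING = 3.4  # mm; desk-scale resolution so the 64x64 FOV covers a chest


def desk_spec(**overrides) -> PhantomSpec:
    base = dict(matrix_size=MATRIX, pixel_spacing=SPACING, n_slices=3,
                n_coils=4, apex_taper=0.3, body_semiaxes=(90.0, 100.0),
                noise_sigma=0.0)
    base.update(overrides)
    return PhantomSpec(**base)


def desk_trajectory(spec, n_arms, dwell=5e-6):
    return design_spiral(spec.fov, spec.pixel_spacing, 2.7, dwell,
                         n_arms_full=16, n_arms=n_arms)


@pytest.fixture(scope="session")
def static_sb():
    """Noiseless single-band acquisition of a (numerically) static phantom:
    150 golden-angle arms, Nyquist at 16 arms, 4 coils."""
    spec = desk_spec(contraction_fraction=1e-9)
    traj = desk_trajectory(spec, 150)
    raw = simulate_kspace(spec, traj, tr=6.6, sms_factor=1, slice_set=[1], seed=11)
    truth, ellipse = phantom_frame(spec, 0.0, 1)
    return {"spec": spec, "raw": raw, "truth": truth, "ellipse": ellipse}


@pytest.fixture(scope="session")
def static_sb_recon(static_sb):
    """STCR of the static fixture at Nyquist arms/frame with vanishing
    regularization: the data-consistency-only reconstruction."""
    cfg = STCRConfig(lambda_t_rel=1e-8, lambda_s_rel=1e-9,
                     arms_per_frame=16, max_iterations=60)
    return reconstruct(static_sb["raw"], cfg)


@pytest.fixture(scope="session")
def sms_dyn():
    """Noiseless SMS-3 acquisition of the beating 3-slice phantom,
    120 arms (20 real-time frames at 6 arms/frame)."""
    spec = desk_spec()
    traj = desk_trajectory(spec, 120)
    raw = simulate_kspace(spec, traj, tr=6.6, sms_factor=3,
                          slice_set=[0, 1, 2], seed=12)
    return {"spec": spec, "raw": raw}


@pytest.fixture(scope="session")
def sms_dyn_recon(sms_dyn):
    cfg = STCRConfig(arms_per_frame=6, max_iterations=60)
    series = reconstruct(sms_dyn["raw"], cfg)
    baseline = adjoint_baseline(sms_dyn["raw"], cfg)
    return {"series": series, "baseline": baseline}


@pytest.fixture(scope="session")
def disjoint_sms_recon():
    """SMS-3 data from three slices with disjoint supports, reconstructed;
    ground-truth supports attached for leakage measurements."""
    from smscine import make_coil_maps, EncodingOperator, caipi_phase_table
    from smscine.io import RawData

    n = 32
    maps = make_coil_maps(4, n, 3.0, seed=6)
    traj = design_spiral(n * 3.0, 3.0, 1.0, 4e-6, n_arms_full=8, n_arms=72)
    ax = (np.arange(n) - n / 2) * 3.0
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    truth = np.zeros((3, n, n), dtype=complex)
    for s, (cy, cx) in enumerate([(-24, -24), (0, 24), (24, -12)]):
        truth[s][(yy - cy) ** 2 + (xx - cx) ** 2 < 14**2] = 1.0
    op = EncodingOperator(traj, maps, sms_factor=3)
    raw = RawData(kspace=op.forward(truth), trajectory=traj,
                  caipi_phase=caipi_phase_table(3, traj.n_arms),
                  tr_ms=6.6, sms_factor=3,
                  slice_positions_mm=np.array([-8.0, 0.0, 8.0]),
                  fov_mm=n * 3.0, matrix_size=n, truth={"coil_maps": maps})
    series = reconstruct(raw, STCRConfig(arms_per_frame=6, max_iterations=40))
    return {"series": series, "support": [np.abs(t) > 0 for t in truth]}


@pytest.fixture(scope="session")
def contrast_ratio_run(tmp_path_factory):
    """Scaled-down paired SMS / single-band experiment with the inflow
    attenuation 0.5: one second of acquisition per mode at 64x64, 6 coils,
    25 lines per segment (runtime, not physics, dictates the scale)."""
    from smscine.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("ratio_run")
    cfg = {"phantom": {"matrix_size": MATRIX, "pixel_spacing": SPACING,
                       "n_coils": 6, "body_semiaxes": (90, 100)},
           "acquisition": {"duration_s": 1.0},
           "evaluation": {"n_lines_per_segment": 25},
           "seed": 7}
    return run_pipeline(cfg, out)
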