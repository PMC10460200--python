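import numpy as np
import pytest

from fdot.geometry import OptodeLayout, VoxelHeadModel
from fdot.optical import OpticalTable, Tissue, TissueOpticalProperties


def homogeneous_table(mu_a=0.01, mu_s=1.0, g=0.0, n=1.4):
    return OpticalTable({Tissue.SCALP_SKULL: TissueOpticalProperties(
        Tissue.SCALP_SKULL, mu_a, mu_s, g, n)})


@pytest.fixture(scope="session")
def slab():
    """Two-layer 40x40x20 mm slab at 1 mm voxels with one coaxial
    source-detector pair on the top face."""
    labels = np.ones((40, 40, 20), np.int16)
    labels[:, :, :10] = int(Tissue.WM)
    head = VoxelHeadModel(labels, 1.0)
    optics = OpticalTable({
        Tissue.SCALP_SKULL: TissueOpticalProperties(Tissue.SCALP_SKULL, 0.01, 1.0, 0.0, 1.4),
        Tissue.WM: TissueOpticalProperties(Tissue.WM, 0.02, 0.8, 0.0, 1.4),
    })
    layout = OptodeLayout(np.array([[12.0, 20.0, 20.0]]),
                          np.array([[28.0, 20.0, 20.0]]),
                          launch_target=np.array([12.0, 20.0, 0.0]))
    return head, optics, layout


@pytest.fixture(scope="session")
def slab_records(slab):
    """Detected-photon records of a fixed-seed 3e5-photon run."""
    from fdot import mc

    head, optics, layout = slab
    rec = mc.transport(head, optics, layout, 0, 300_000, seed=3)
    assert rec.n_detected > 50
    return rec


@pytest.fixture(scope="session")
def small_ball():
    """Structured ball mesh (R = 30 mm) with one source and one detector,
    homogeneous GM-like optics."""
    from fdot.da import tag_patches
    from fdot.mesh import ball_mesh

    R = 30.0
    mesh = ball_mesh(R, n_layers=10, subdiv=3, label=int(Tissue.GM))
    optics = OpticalTable({Tissue.GM: TissueOpticalProperties(
        Tissue.GM, 0.01, 10.0, 0.9, 1.4)})
    th = 0.9
    layout = OptodeLayout(np.array([[0.0, 0.0, R]]),
                          np.array([[R * np.sin(th), 0.0, R * np.cos(th)]]),
                          launch_target=np.zeros(3))
    model = tag_patches(mesh, layout)
    return model, optics


@pytest.fixture(scope="session")
def default_head():
    from fdot.phantom import HeadParams, generate_head

    return generate_head(0, HeadParams())


@pytest.fixture(scope="session")
def degenerate_study():
    """N = 2 zero-variation study: every anatomy identical to the
    reference, run with the deterministic solver."""
    from fdot.phantom import PopulationSpread
    from fdot.pipeline import StudyConfig, run_study

    cfg = StudyConfig(N=2, seed=3, solver="da",
                      spread=PopulationSpread(0.0, 0.0, 0.0, 0.0, 0.0, 0, 0.0),
                      mesh_spacing=3.0, csf_split=False)
    return run_study(cfg)
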