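import numpy as np
import pytest

import cristoscope.phantom as ph
import cristoscope.shape3d as s3
import cristoscope.subtomo as st
from cristoscope.labels import Compartment


@pytest.fixture(scope="session")
def bank() -> st.TemplateBank:
    return st.make_template_bank()


@pytest.fixture(scope="session")
def lamellar_phantom():
    """A mitochondrion with one 15 nm lamellar crista (noise-free, no wedge),
    the workhorse geometry for profile, sampling and volume checks."""
    crista = ph.CristaSpec(
        "lamellar",
        width_nm=15.0,
        length_nm=110.0,
        height_nm=90.0,
        orientation=(0.0, 0.0, 1.0),
        junctions=[ph.JunctionSpec(angle_deg=90.0, width_nm=20.0)],
    )
    spec = ph.PhantomSpec(
        box_shape=(96, 104, 112),
        semi_axes_nm=(100.0, 110.0, 120.0),
        cristae=[crista],
        noise_sigma=0.0,
        wedge_half_angle_deg=0.0,
        seed=11,
    )
    tomo, labels, ground = ph.generate_phantom(spec)
    return spec, tomo, labels, ground


@pytest.fixture(scope="session")
def exemplar_suite():
    """Rendered one-exemplar-per-class phantoms: name -> (spec, labels, crista)."""
    out = {}
    for name, crista in ph.exemplar_cristae().items():
        spec = ph.exemplar_phantom(crista, seed=5)
        _, labels, _ = ph.generate_phantom(spec)
        out[name] = (spec, labels, crista)
    return out


def crista_masks(labels: np.ndarray):
    solid = np.isin(labels, (Compartment.CRISTA_MEMBRANE, Compartment.CRISTA_LUMEN))
    lumen = labels == Compartment.CRISTA_LUMEN
    return solid, lumen
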