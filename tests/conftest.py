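import pytest

import gfsim


@pytest.fixture(scope="session")
def young_circuit():
    return gfsim.build_default_circuit()


@pytest.fixture(scope="session")
def old_circuit():
    return gfsim.build_old_circuit()


@pytest.fixture(scope="session")
def young_result(young_circuit):
    """Head-stimulation run of the young-fly default circuit (cached)."""
    return gfsim.run_head_stimulation(young_circuit)


@pytest.fixture(scope="session")
def old_result(old_circuit):
    return gfsim.run_head_stimulation(old_circuit)


def single_section_circuit(length=50.0, diam=10.0, nseg=1, active=True,
                           membrane=None, kinetics=None):
    """A one-cell, one-section circuit for compartment-level tests."""
    spec = gfsim.CircuitSpec()
    cell = gfsim.Cell("cell")
    cell.add_section(gfsim.SectionSpec("axon", length=length,
                                       diam_proximal=diam, nseg=nseg,
                                       active=active))
    spec.cells["cell"] = cell
    if membrane is not None:
        spec.membrane = membrane
    if kinetics is not None:
        spec.kinetics = kinetics
    return spec
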