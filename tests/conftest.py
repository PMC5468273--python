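import logging

import pytest

from aqpkit.osmotic import BathCondition, OocyteGeometry

# flagged-record warnings are part of the API surface but drown test output
logging.getLogger("aqpkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geom() -> OocyteGeometry:
    """Standard oocyte geometry (V0 = 9e-4 cm^3, S = 0.045 cm^2, Vw = 18)."""
    return OocyteGeometry()


@pytest.fixture(scope="session")
def hypo_bath() -> BathCondition:
    """The standard hypo-osmotic challenge bath (70 mOsm, no test solute)."""
    return BathCondition(osm_out=70.0)
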