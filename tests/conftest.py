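import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def disaccharide():
    """A built unsulfated GlcA(1->3)GalNAc disaccharide."""
    from cvls.chemistry import parse_name
    from cvls.geometry import build_3d

    return build_3d(parse_name("ZbB–VbCB"))


@pytest.fixture(scope="session")
def hexasaccharide():
    from cvls.chemistry import parse_name
    from cvls.geometry import build_3d

    return build_3d(parse_name("Zb2B–VbC46B–Zb2B–VbC4B–ZbB–VbC6B"))


@pytest.fixture(scope="session")
def toy_pocket():
    from cvls.fixtures import make_toy_pocket

    return make_toy_pocket(seed=1, n_basic=8, radius=8.0)


@pytest.fixture(scope="session")
def reference_tables():
    from cvls.fixtures import load_reference_tables

    return load_reference_tables()


@pytest.fixture(scope="session")
def cage(disaccharide):
    """Receptor cage whose docking optimum is the ligand's build pose."""
    from cvls.fixtures import make_hbond_cage

    receptor, planted = make_hbond_cage(disaccharide)
    return receptor, planted
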