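from datetime import date

import pytest

from toothsr import AssayCalibration, NuclideConstants, default_scenario


@pytest.fixture
def constants() -> NuclideConstants:
    return NuclideConstants()


@pytest.fixture
def calib() -> AssayCalibration:
    return AssayCalibration()


@pytest.fixture
def scenario():
    return default_scenario()


# Published stable-Sr concentrations (µg per g ash) of the two adult animals:
# pooled permanent molars and premolars.
ADULT_MOLARS = (187.0, 205.0, 204.0, 190.0, 155.0, 126.0)
ADULT_PREMOLARS = (211.0, 213.0, 197.0, 137.0, 134.0, 121.0)

# Stable-Sr values of the four young contaminated-area animals, grouped into
# deciduous molars / molars / premolars (non-missing cells only).
YOUNG_DM = (113.0, 106.0, 94.2, 193.0, 194.0, 206.0, 141.0, 128.0, 114.0, 133.0, 139.0)
YOUNG_M = (122.0, 136.0, 157.0, 206.0, 238.0, 248.0, 122.0, 125.0, 159.0, 147.0, 158.0, 214.0)
YOUNG_P = (169.0, 153.0, 189.0, 255.0, 239.0, 241.0, 184.0, 166.0, 173.0, 165.0)


@pytest.fixture
def adult_stable_sr():
    return ADULT_MOLARS, ADULT_PREMOLARS


@pytest.fixture
def young_stable_sr():
    return YOUNG_DM, YOUNG_M, YOUNG_P


@pytest.fixture
def accident() -> date:
    return date(2011, 3, 11)
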