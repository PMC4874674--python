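"""Shared fixtures: synthetic arrays built from the consensus fingers."""

import numpy as np
import pytest

from zfselect.synthetic_data import (
    UNIT_CONSENSUS_AA,
    LEAD_CONSENSUS_AA,
    UPSTREAM_FLANK,
    SPACER,
    DOWNSTREAM_FLANK,
    back_translate,
)

UNIT_NT = back_translate(UNIT_CONSENSUS_AA)
LEAD_NT = back_translate(LEAD_CONSENSUS_AA)


def make_amplicon(unit_nts, upstream=UPSTREAM_FLANK, lead=LEAD_NT,
                  spacer=SPACER, downstream=DOWNSTREAM_FLANK) -> str:
    """Assemble an amplicon from explicit 84-nt unit sequences."""
    return upstream + lead + spacer + "".join(unit_nts) + downstream


@pytest.fixture(scope="session")
def unit_nt() -> str:
    return UNIT_NT


@pytest.fixture(scope="session")
def lead_nt() -> str:
    return LEAD_NT


@pytest.fixture(scope="session")
def nine_unit_amplicon() -> str:
    return make_amplicon([UNIT_NT] * 9)


@pytest.fixture(scope="session")
def small_panel_sim():
    from zfselect.synthetic_data import ArraySimConfig, SpeciesConfig, simulate_population

    panel = (
        SpeciesConfig("cattle", 6, {"A": 0.4, "B": 0.4, "C": 0.2}),
        SpeciesConfig("goat", 6, {"D": 0.3, "E": 0.4, "F": 0.3}),
    )
    return simulate_population(ArraySimConfig(panel=panel, seed=5))
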