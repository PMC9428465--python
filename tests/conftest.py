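import math

import numpy as np
import pytest

from thermotrait.synthetic_data import (
    SimulationConfig,
    TrueTaxonParams,
    _th_for_topt,
)

PAPER_ASSAY_TEMPS = (0.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)


def make_taxon(taxon_id, topt_c, ea_ev, eh_over_ea=3.5, r_tc=0.3):
    """A taxon with an exact requested optimum, built by inverting Eq-style
    closed form for Th."""
    eh = ea_ev * eh_over_ea
    th = _th_for_topt(topt_c + 273.15, ea_ev, eh)
    return TrueTaxonParams(taxon_id=taxon_id, ea_ev=ea_ev, eh_ev=eh,
                           th_k=th, ln_r_tc=math.log(r_tc))


@pytest.fixture(scope="session")
def paper_like_taxa():
    """Eight taxa whose optima span 18.7-35.3 degC and activation energies
    span 0.23-1.06 eV, the trait ranges of the study system."""
    topts = np.linspace(18.7, 35.3, 8)
    eas = np.linspace(0.23, 1.06, 8)
    return [make_taxon(f"taxon_{i+1:02d}", t, e)
            for i, (t, e) in enumerate(zip(topts, eas))]


@pytest.fixture
def small_config():
    """A reduced design for fast end-to-end tests."""
    return SimulationConfig(
        n_taxa=3,
        assay_temps_c=(10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0),
        n_tech_reps=2,
        n_community_reps=8,
        total_colonies=100,
        seed=11,
    )
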