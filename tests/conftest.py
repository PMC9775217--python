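import numpy as np
import pytest

from phremc.titration import (
    EnergyTerms,
    GradientSpec,
    TitratableSite,
    Tautomer,
    assign_proton_baths,
    make_two_form_site,
)


@pytest.fixture
def single_site_pk6():
    """Isolated two-form site with intrinsic pK 6.0, assigned to the outer bath."""
    site, intrinsic = make_two_form_site("A", 6.0, start_z=5.0)
    return [site], EnergyTerms(intrinsic), assign_proton_baths([site], 0.0)


@pytest.fixture
def coupled_two_site():
    """Two coupled two-form sites (W = 2.5 pK between protonated forms)."""
    sites = [
        TitratableSite("A", (Tautomer("d", 0), Tautomer("p", 1)), start_z=5.0),
        TitratableSite("B", (Tautomer("d", 0), Tautomer("p", 1)), start_z=-5.0),
    ]
    terms = EnergyTerms(
        {("A", "d"): 0.0, ("A", "p"): -6.0, ("B", "d"): 0.0, ("B", "p"): -5.5},
        {("A", "p", "B", "p"): 2.5},
    )
    return sites, terms, assign_proton_baths(sites, 0.0)


@pytest.fixture
def flat_ph(request):
    return GradientSpec(6.0, 6.0)


def hh_fraction(pk: float, ph: float) -> float:
    """Henderson-Hasselbalch protonated fraction."""
    return 1.0 / (1.0 + 10.0 ** (ph - pk))
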