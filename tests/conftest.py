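import pytest

from alleleq import SiteSignature

ENDO = "GACGATCATGTACAGGACCGG"
EXO = "CACTATCATATATAGTACTGG"


@pytest.fixture(scope="session")
def signature() -> SiteSignature:
    """The worked-example endogenous/exogenous site pair."""
    return SiteSignature(endo_site=ENDO, exo_site=EXO)
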