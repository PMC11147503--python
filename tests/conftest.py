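import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ampedit as ae
from ampedit.donor_design import CodingContext, DesignRequest, design_ssodn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SRSF2_SPACER = "CGGCTGTGGTGTGAGTCCGG"


@pytest.fixture(scope="session")
def locus():
    """A synthetic 144-nt coding amplicon embedding the SRSF2 spacer + NGG.

    frame_offset 1 places the PAM's first G at a codon wobble position so a
    silent PAM disruption exists.
    """
    rng = np.random.default_rng(7)
    left = "".join(rng.choice(list("ACGT"), 60))
    right = "".join(rng.choice(list("ACGT"), 61))
    amp = ae.AmpliconReference("locus", left + SRSF2_SPACER + "TGG" + right)
    guide = ae.locate_guide(amp, SRSF2_SPACER, "NGG", require_pam=True, guide_id="g1")
    assert guide is not None and guide.strand == "+"
    ctx = CodingContext("locus", ((0, 144),), "+", 1)
    return amp, guide, ctx


@pytest.fixture(scope="session")
def designed_donor(locus):
    amp, guide, ctx = locus
    req = DesignRequest(guide=guide, mutate_pam=True, n_spacer_silent=2)
    return design_ssodn(req, amp, ctx)


@pytest.fixture(scope="session")
def printed_donors():
    return ae.load_printed_donors()


@pytest.fixture(scope="session")
def clean_errors():
    """Error-free reads with confident base qualities."""
    return ae.ErrorModel(quality_mean=40, quality_sd=0)
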