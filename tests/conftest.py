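import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fluxpheno as fp
from fluxpheno.types import DailyFluxSeries

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def make_flux(nee, site_id="T1", year=2001, tair=None, precip=None, **masks):
    """One site-year flux series on the full DOY axis from an NEE vector."""
    n = len(nee)
    return DailyFluxSeries(
        site_id=site_id, year=year, doy=np.arange(1, n + 1),
        nee=np.asarray(nee, dtype=float),
        tair=np.zeros(n) if tair is None else np.asarray(tair, dtype=float),
        precip=np.zeros(n) if precip is None else np.asarray(precip, dtype=float),
        **masks,
    )


@pytest.fixture
def noise_free_nee_params():
    return fp.NEEParams(r0=1.0, amplitude=4.0, t_up=120.0, s_up=7.0,
                        t_down=270.0, s_down=7.0, noise_sd=0.0)


@pytest.fixture
def noise_free_vi_params():
    return fp.VIParams(noise_sd=0.0, dropout_prob=0.0)


@pytest.fixture
def small_cohort():
    """A 12-site-year noise-free cohort with a simple SOS -> SCU link."""
    spec = fp.CohortSpec(
        n=12, seed=42,
        scu_link=fp.LinkSpec(10.0, 1.0, 0.0, (-20, 0), "temperature", 0.0),
        ecu_link=fp.LinkSpec(-20.0, 1.0, 0.0, (-20, 0), "temperature", 0.0),
        nee=fp.NEEParams(r0=2.0, amplitude=4.0, noise_sd=0.0),
        vi=fp.VIParams(noise_sd=0.0, dropout_prob=0.0),
    )
    return fp.generate_cohort(spec)
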