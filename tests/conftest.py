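import numpy as np
import pytest

import rootmix as rm


@pytest.fixture(scope="session")
def canonical_pair() -> rm.EndmemberPair:
    """Canonical C4-root vs C3-EOM endmember pair: -13.3 +/- 0.5 / -29.3 +/- 0.3."""
    return rm.pair_from_values(-13.3, 0.5, -29.3, 0.3, n_root=7, n_eom=12)


@pytest.fixture(scope="session")
def exact_pair() -> rm.EndmemberPair:
    """Same means with zero SDs, for exactness checks."""
    return rm.pair_from_values(-13.3, 0.0, -29.3, 0.0)


@pytest.fixture(scope="session")
def baseline_scenario() -> rm.Scenario:
    return rm.Scenario()


@pytest.fixture(scope="session")
def baseline_study(baseline_scenario):
    """One realized synthetic study (samples, reference, truth), seed 42."""
    return rm.generate_study(baseline_scenario, seed=42)


@pytest.fixture()
def small_samples_csv(tmp_path):
    """A minimal 3-record samples CSV covering both coring streams."""
    path = tmp_path / "samples.csv"
    path.write_text(
        "sample_id,plot_id,treatment,block,depth,position,method,"
        "size_class,eom_excluded,delta13c,dry_mass,c_concentration\n"
        "s1,P01,BIOORG1,1,D1,row,humax,pooled,true,-20.0,,\n"
        "s2,P01,BIOORG1,1,D1,inter_row,humax,pooled,true,-24.0,,\n"
        "s3,P01,BIOORG1,1,D1,row,puerckhauer,coarse,false,-15.0,1.2,0.45\n"
    )
    return path
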