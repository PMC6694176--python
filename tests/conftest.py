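import numpy as np
import pytest

import nestrisk as nr


@pytest.fixture(scope="session")
def profile() -> nr.ExposureProfile:
    """Default hoary-squash-bee exposure profile (full precision)."""
    return nr.build_exposure_profile()


@pytest.fixture(scope="session")
def endpoints() -> nr.EndpointSet:
    return nr.table1_endpoints()


@pytest.fixture(scope="session")
def concentrations():
    return nr.table1_concentrations()


@pytest.fixture()
def small_censored():
    """A small mixed censored dataset: 8 exact, 4 left, 3 interval."""
    rng = np.random.default_rng(42)
    exact = rng.lognormal(0.2, 0.8, 8)
    data = [nr.CensoredSample(kind="exact", value=float(v)) for v in exact]
    data += [nr.CensoredSample(kind="left", bound=0.4) for _ in range(4)]
    data += [nr.CensoredSample(kind="interval", lo=0.4, hi=1.1) for _ in range(3)]
    return data


def make_residue_rows(n_quant=1, n_nd=0, n_bloq=0, analyte="clothianidin",
                      matrix="soil", values=None, lod=0.05, loq=0.15):
    """Build a ResidueDataset with the requested censoring mix."""
    obs = []
    values = list(values or [])
    for i in range(n_quant):
        obs.append(
            nr.ResidueObservation(
                sample_id=f"q{i}", analyte=analyte, matrix=matrix,
                status="quantified",
                value=values[i] if i < len(values) else 1.0 + i,
                lod=lod, loq=loq,
            )
        )
    for i in range(n_nd):
        obs.append(
            nr.ResidueObservation(
                sample_id=f"n{i}", analyte=analyte, matrix=matrix,
                status="nondetect", lod=lod, loq=loq,
            )
        )
    for i in range(n_bloq):
        obs.append(
            nr.ResidueObservation(
                sample_id=f"b{i}", analyte=analyte, matrix=matrix,
                status="below_loq", lod=lod, loq=loq,
            )
        )
    return nr.ResidueDataset.from_observations(obs)
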