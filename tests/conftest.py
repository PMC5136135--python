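import pytest

import lenage as L


@pytest.fixture(scope="session")
def study_params() -> L.GrowthParams:
    """Best-fit seasonal growth parameters for the canonical scenario."""
    return L.GrowthParams(L_inf=448.0, K=0.47, t0=0.0, C=0.61, t_s=0.21, t_b=0.41)


@pytest.fixture(scope="session")
def canonical_hists():
    """One simulated realization of the canonical sampling series."""
    sc = L.canonical_scenario(seed=42)
    rec = L.simulate_records(sc)
    hists, n_out = L.records_to_histograms(rec, months=sc.months)
    return sc, rec, hists


@pytest.fixture(scope="session")
def quick_fit(canonical_hists):
    """A seasonal/variable-sigma fit of the canonical realization."""
    from lenage.fit import ModelSpec, fit_model

    _, _, hists = canonical_hists
    spec = ModelSpec(seasonal=True, variance_at_age="variable")
    return hists, fit_model(hists, spec, n_starts=1, seed=0)
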