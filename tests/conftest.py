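import pandas as pd
import pytest

from diglyq import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small 11-plex simulated experiment shared across pipeline tests."""
    cfg = SimulationConfig(seed=7, n_proteins=80, n_sites=150)
    psm, prot, ann, truth, seqs = simulate_experiment(cfg)
    return {
        "config": cfg,
        "psm": psm,
        "proteins": prot,
        "annotation": ann,
        "truth": truth,
        "sequences": seqs,
    }


@pytest.fixture()
def toy_psms():
    """Six PSMs, each violating exactly one quality criterion, plus one clean."""
    base = dict(
        peptide="AKGGK",
        proteins="P1",
        mods="2:glygly",
        charge=3,
        score=5.0,
        is_decoy=False,
        isolation_specificity=0.9,
        summed_sn=500.0,
        ms1_intensity=1e6,
        has_ms3=True,
        ascore=30.0,
        ch1=250.0,
        ch2=250.0,
    )
    rows = [
        dict(base),  # clean
        dict(base, isolation_specificity=0.69),
        dict(base, summed_sn=149.9),
        dict(base, has_ms3=False),
        dict(base, charge=2),
        dict(base, charge=7),
    ]
    return pd.DataFrame(rows)
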