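import numpy as np
import pandas as pd
import pytest

from tmtflow import SampleDesign, generate_ground_truth, simulate_peptide_table, \
    simulate_microarray, tmt_like


@pytest.fixture
def design6() -> SampleDesign:
    """Canonical 3 ADC vs 3 SCC six-channel design."""
    return SampleDesign(
        ["ADC1", "ADC2", "ADC3", "SCC1", "SCC2", "SCC3"],
        ["126", "127", "128", "129", "130", "131"],
        ["ADC", "ADC", "ADC", "SCC", "SCC", "SCC"],
    )


def make_filter_fixture(design: SampleDesign) -> pd.DataFrame:
    """Ten hand-built peptide rows: 2 high-PEP, 1 reverse, 1 contaminant,
    2 over-missing, 4 clean (including both filter boundaries)."""
    samples = list(design.sample_ids)

    def row(seq, pep=0.01, reverse=False, contaminant=False, n_missing=0):
        intens = [1000.0 * (i + 1) for i in range(len(samples))]
        for i in range(n_missing):
            intens[i] = np.nan
        rec = dict(sequence=seq, proteins=[f"PR{seq}"], pep=pep,
                   reverse=reverse, contaminant=contaminant, length=len(seq))
        rec.update(dict(zip(samples, intens)))
        return rec

    return pd.DataFrame([
        row("PEPHIGHA", pep=0.2),
        row("PEPHIGHB", pep=0.5),
        row("REVROW", reverse=True),
        row("CONROW", contaminant=True),
        row("MISSA", n_missing=4),
        row("MISSB", n_missing=5),
        row("CLEANA", pep=0.1),       # PEP exactly at the threshold: kept
        row("CLEANB", pep=0.05),
        row("CLEANC", n_missing=3),   # missing exactly at the threshold: kept
        row("CLEAND"),
    ])


@pytest.fixture
def filter_fixture(design6) -> pd.DataFrame:
    return make_filter_fixture(design6)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated experiment shared across tests (seed-fixed)."""
    params = tmt_like(n_proteins=60, seed=11)
    truth = generate_ground_truth(params)
    table = simulate_peptide_table(truth)
    exprs, mapping = simulate_microarray(truth)
    return truth, table, exprs, mapping
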