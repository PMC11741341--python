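import numpy as np
import pandas as pd
import pytest

from secretomics import ReporterMatrix, StudyDesign


def make_design(conditions=("A", "B"), n_replicates=3, reference=None):
    """Balanced design with sample-style channel names cond.rep."""
    chan_cond, chan_rep = {}, {}
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            ch = f"{cond}.{rep}"
            chan_cond[ch] = cond
            chan_rep[ch] = rep
    return StudyDesign(chan_cond, chan_rep, reference or conditions[0])


def make_matrix(values, channels, peptides=None, proteins=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"p{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"),
                      columns=channels)
    pep = pd.Series(peptides if peptides is not None else 5, index=df.index)
    return ReporterMatrix(df, pep)


@pytest.fixture
def two_group_design():
    return make_design(("A", "B"), n_replicates=3, reference="B")
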