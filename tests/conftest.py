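import numpy as np
import pandas as pd
import pytest

from survmr.containers import ClinicalTable, ExpressionMatrix, GenotypeMatrix


@pytest.fixture
def hand_survival_6():
    """Six subjects, distinct times 1..6, intercept + two covariates."""
    X = np.array(
        [
            [1.0, 0.0, 1.2],
            [1.0, 1.0, -0.4],
            [1.0, 0.0, 0.3],
            [1.0, 1.0, 2.0],
            [1.0, 1.0, -1.1],
            [1.0, 0.0, 0.7],
        ]
    )
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 1, 0, 1, 1, 1])
    return X, time, event


@pytest.fixture
def hand_survival_8():
    """Eight subjects, one binary covariate, no ties (Cox grid oracle)."""
    x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
    time = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0, 8.0, 6.0])
    event = np.array([1, 1, 1, 0, 1, 1, 1, 1])
    return x[:, None], time, event


def small_expression(counts: np.ndarray, gene_ids=None, sample_ids=None, scale="raw"):
    genes = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(counts.shape[1])]
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                          columns=pd.Index(samples, name="sample_id"))
    meta = pd.DataFrame(
        {"chrom": "1", "tss": 1_000_000 * (np.arange(len(genes)) + 1)},
        index=values.index,
    )
    return ExpressionMatrix(values, meta, scale=scale)


def genotypes_from_array(dos: np.ndarray, positions=None, chrom="1", sample_ids=None):
    n, m = dos.shape
    vids = [f"v{j}" for j in range(m)]
    samples = sample_ids or [f"s{i}" for i in range(n)]
    d = pd.DataFrame(dos, index=pd.Index(samples, name="sample_id"), columns=vids)
    freq = d.mean(axis=0) / 2
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions if positions is not None else 100 * (np.arange(m) + 1),
            "ref": "A",
            "alt": "C",
            "maf": np.minimum(freq, 1 - freq),
        },
        index=pd.Index(vids, name="variant_id"),
    )
    return GenotypeMatrix(d, meta)


def clinical_from_arrays(time, event, arm, index=None, **extra):
    idx = index if index is not None else pd.Index([f"s{i}" for i in range(len(time))], name="sample_id")
    tab = pd.DataFrame({"os_time": time, "os_event": event, "arm": arm}, index=idx)
    for k, v in extra.items():
        tab[k] = v
    return ClinicalTable(tab)
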