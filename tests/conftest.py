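"""Shared fixtures: tiny hand-written designs/tables and one synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phosq.io_sitetable import SiteRecord, StudyDesign
from phosq.normalize import QuantMatrix
from phosq.synthetic_data import SimConfig, generate


def make_design(
    n_batches: int = 2,
    clinical_per_batch: int = 2,
    refs_per_batch: int = 1,
) -> StudyDesign:
    """Minimal valid design: generic clinical tumor samples plus references."""
    rows = []
    s = 0
    for b in range(1, n_batches + 1):
        for c in range(clinical_per_batch):
            s += 1
            rows.append(
                {
                    "batch_id": f"B{b}",
                    "channel_id": f"ch{c + 1}",
                    "sample_id": f"S{s}",
                    "patient_id": f"P{s}",
                    "tissue": "T",
                    "her2": "positive",
                    "timepoint": "pre",
                    "is_reference": False,
                }
            )
        for r in range(refs_per_batch):
            rows.append(
                {
                    "batch_id": f"B{b}",
                    "channel_id": f"ref{r + 1}",
                    "sample_id": f"REF_B{b}_{r + 1}",
                    "patient_id": "none",
                    "tissue": "REF",
                    "her2": "none",
                    "timepoint": "none",
                    "is_reference": True,
                }
            )
    return StudyDesign(pd.DataFrame(rows))


def make_matrix(values: np.ndarray | list, stage: str = "raw_log2", n_batches: int = 1) -> QuantMatrix:
    """QuantMatrix from a plain array; samples spread over n_batches evenly."""
    arr = np.asarray(values, dtype=float)
    n_feat, n_samp = arr.shape
    samples = [f"S{j + 1}" for j in range(n_samp)]
    batches = pd.Series(
        [f"B{(j * n_batches) // n_samp + 1}" for j in range(n_samp)], index=samples
    )
    data = pd.DataFrame(arr, index=[f"G{i + 1}_S{i + 1}" for i in range(n_feat)], columns=samples)
    return QuantMatrix(data, stage, batches)


def make_record(**kw) -> SiteRecord:
    defaults = dict(
        site_id="s1",
        protein="P1",
        gene="GENE1",
        residue="S",
        position=10,
        localization_prob=0.9,
    )
    defaults.update(kw)
    return SiteRecord(**defaults)


@pytest.fixture(scope="session")
def tiny_design() -> StudyDesign:
    return make_design()


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """One default-condition synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("sim")
    return generate(SimConfig(seed=20260928 % 2**16), outdir)
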