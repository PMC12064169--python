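import json
from pathlib import Path

import numpy as np
import pytest

from ppiscorekit.fixtures import generate_cohort
from ppiscorekit.model_io import ModelResult

COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort(tmp_path_factory) -> tuple[Path, dict]:
    """One toy cohort shared across the session: (input_dir, manifest)."""
    root = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(root, seed=COHORT_SEED)
    return root, manifest


@pytest.fixture(scope="session")
def pipeline_results(cohort, tmp_path_factory):
    """The full pipeline run on the shared cohort."""
    from ppiscorekit.pipeline import run_pipeline

    input_dir, manifest = cohort
    out_dir = tmp_path_factory.mktemp("report")
    results = run_pipeline(input_dir, out_dir)
    return results, manifest, out_dir


def make_model(pae: np.ndarray, chain_lengths: list[int],
               job_id: str = "A_and_B", iptm: float = 0.8) -> ModelResult:
    """In-memory ModelResult with consecutive chain ranges over ``pae``."""
    ranges, cursor = {}, 0
    for i, n in enumerate(chain_lengths):
        ranges[chr(ord("A") + i)] = (cursor, cursor + n)
        cursor += n
    return ModelResult(job_id=job_id, model_index=1, iptm=iptm, iptm_ptm=iptm,
                       pae=pae, chain_ranges=ranges)
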