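import numpy as np
import pandas as pd
import pytest

from dualsens import ExpressionMatrix, StudyDesign, SynthConfig, TissueEffects


def make_expr(values, conditions, tissue="muscle", genes=None):
    """Build an ExpressionMatrix from a 2-D array and per-column conditions."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    counts: dict = {}
    sample_ids, reps = [], []
    for cond in conditions:
        counts[cond] = counts.get(cond, 0) + 1
        sample_ids.append(f"{tissue}_{cond}_r{counts[cond]}")
        reps.append(counts[cond])
    samples = pd.DataFrame(
        {"tissue": tissue, "condition": list(conditions), "replicate": reps},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids), samples)


@pytest.fixture
def null_effects():
    return TissueEffects(0.0, 0.0, 0.0, 0.0)


@pytest.fixture
def small_study():
    """A small two-tissue study with planted effects and probe-level data."""
    cfg = SynthConfig(n_genes=120, seed=42)
    design = StudyDesign(tissues=("muscle", "prostate"))
    return design, cfg
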