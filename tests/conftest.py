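import pandas as pd
import pytest

import synadapt as sa


@pytest.fixture(scope="session")
def prior():
    return sa.PriorConfig()


@pytest.fixture(scope="session")
def small_exp1_records():
    """A small but complete interleaved-design dataset (8 subjects)."""
    design = sa.build_design_exp1(n_subjects=8, seed=42)
    return sa.generate_dataset(design, seed=42)


@pytest.fixture(scope="session")
def small_exp1_table(small_exp1_records):
    table, _ = sa.run_pipeline(small_exp1_records)
    return table


@pytest.fixture(scope="session")
def small_exp2_records():
    """Two-group blocked-design dataset (10 subjects per group)."""
    frames = []
    for i, group in enumerate(("RC_First", "Filler_First")):
        design = sa.build_design_exp2(group, n_subjects=10, seed=42)
        rec = sa.generate_dataset(design, seed=42 + i)
        rec["subject_id"] += i * 10
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)
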