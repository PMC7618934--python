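import warnings

import numpy as np
import pytest
from hypothesis import settings

import shortform as sf

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# liblinear emits ConvergenceWarning-free fits at our tolerances, but the
# deprecation chatter from older/newer sklearn APIs is irrelevant noise here
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (n=490, seed 7), scored."""
    return sf.generate_cohort(sf.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Parameter-recovery scenario: 12 informative items, n=2000, seed 3."""
    return sf.generate_cohort(
        sf.GeneratorConfig(seed=3, n_informative_items=12, n_participants=2000)
    )


@pytest.fixture(scope="session")
def recovery_selection(recovery_cohort):
    return sf.stability_select(recovery_cohort, plan=sf.FoldPlan(seed=3))


def make_toy_instrument(n_items: int = 4) -> sf.Instrument:
    """A small instrument with the default stand-in cutoffs."""
    scales = [
        "unusual_thought_content",
        "non_bizarre_ideas",
        "perceptual_abnormalities",
        "disorganized_speech",
    ]
    items = [
        sf.ItemDefinition(item_id=f"it_{k:02d}", scale=scales[k % 4])
        for k in range(n_items)
    ]
    return sf.Instrument(items=items)


def make_record(instrument, pid="p1", positive_items=(), psychosis_items=(), **demo):
    """A record endorsing the given items (severity 4, frequency 4),
    psychosis-level (severity 6) on ``psychosis_items``, zero elsewhere."""
    sev = {i: 0 for i in instrument.item_ids}
    freq = {i: 0 for i in instrument.item_ids}
    for i in positive_items:
        sev[i], freq[i] = 4, 4
    for i in psychosis_items:
        sev[i], freq[i] = 6, 4
    return sf.ResponseRecord(participant_id=pid, severity=sev, frequency=freq, **demo)


def make_cohort(instrument, specs):
    """Cohort from (pid, positive_items, psychosis_items, demo-dict) tuples."""
    records = []
    for spec in specs:
        pid, pos, psych, demo = (list(spec) + [{}])[:4] if len(spec) < 4 else spec
        records.append(make_record(instrument, pid, pos, psych, **(demo or {})))
    ds = sf.CohortDataset(instrument=instrument, records=records)
    return sf.dichotomize_cohort(ds)
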