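"""Shared fixtures: small, fast synthetic configurations.

All fixtures use short time axes and few channels so the full suite stays
quick; the statistical structure (factorial design, SDT behavior, planted
patterns, correlated noise) matches the default generator.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cvdecode import GeneratorParams, simulate_subject
from cvdecode.containers import accuracy_from, response_from

SHORT_TIME = np.arange(-0.6, 1.601, 0.05)  # 45 samples at 20 Hz
RAMP = np.clip(SHORT_TIME / 0.3, 0.0, 1.0)


def cheap_params(**kw) -> GeneratorParams:
    """Generator config with a short epoch and few channels."""
    defaults = dict(
        n_trials_per_task=160,
        n_channels=6,
        time=SHORT_TIME,
        patterns={"stimulus": 0.8, "choice": 0.8, "response": 0.8},
        temporal_profiles={
            "stimulus": RAMP,
            "choice": RAMP,
            "choice_pre": RAMP,
            "choice_post": RAMP,
            "response": RAMP,
            "task": RAMP,
            "mapping": RAMP,
            "confidence": RAMP,
        },
        seed=0,
    )
    defaults.update(kw)
    return GeneratorParams(**defaults)


def balanced_table(variables=("task", "stimulus", "choice", "mapping"), reps=5,
                   run="run1") -> pd.DataFrame:
    """Fully crossed table over independent variables, each combo × reps,
    with the deterministic columns derived consistently."""
    levels = {
        "task": ("pre", "post"),
        "stimulus": ("signal", "noise"),
        "choice": ("yes", "no"),
        "mapping": ("yes=left", "yes=right"),
        "confidence": ("high", "low"),
    }
    combos = list(itertools.product(*[levels[v] for v in variables]))
    rows = []
    for combo in combos:
        d = dict(zip(variables, combo))
        d.setdefault("stimulus", "signal")
        d.setdefault("choice", "yes")
        d.setdefault("mapping", "yes=left")
        d["response"] = response_from(d["choice"], d["mapping"])
        d["accuracy"] = accuracy_from(d["stimulus"], d["choice"])
        d["run"] = run
        rows.extend([dict(d)] * reps)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def subject():
    """One cheap simulated subject with planted patterns."""
    return simulate_subject(cheap_params(seed=7))


@pytest.fixture(scope="session")
def null_subject():
    """Behavior intact but no planted neural patterns."""
    return simulate_subject(cheap_params(patterns={}, seed=11))
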