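"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from mouseeg import staging, synthgen

FS = 1000.0


@pytest.fixture(scope="session")
def sleep_session():
    """A 600-s mixed-stage session with default parameters and ground truth."""
    hyp = synthgen.generate_hypnogram(600.0, target_nrem_fraction=0.55, seed=7)
    rec, truth = synthgen.synthesize_session(hyp, seed=7)
    return hyp, rec, truth


@pytest.fixture(scope="session")
def nrem_only_session():
    """600 s of pure NREM with spindles at 11 Hz only, rate 5/min."""
    hyp = staging.Hypnogram(np.full(60, "NREM"), 10.0)
    params = synthgen.SpindleGenParams(rates={11.0: 5.0})
    rec, truth = synthgen.synthesize_session(hyp, spindle_params=params, seed=21)
    return hyp, rec, truth


@pytest.fixture(scope="session")
def aperiodic_only_params():
    """Stage parameters with no oscillatory peaks (pure 1/f background)."""
    return {
        "WAKE": synthgen.StageParams(2.0, 2.0, (), 40.0),
        "NREM": synthgen.StageParams(2.0, 2.0, (), 10.0),
        "REM": synthgen.StageParams(2.0, 2.0, (), 5.0),
    }


def match_events(truth, detected, onset_tol_s=0.25):
    """Greedy one-to-one matching of detected to ground-truth events."""
    used = set()
    matched = 0
    for tv in truth:
        for j, dv in enumerate(detected):
            if j in used:
                continue
            if (
                abs(dv.onset_s - tv.onset_s) <= onset_tol_s
                or dv.onset_s <= tv.onset_s <= dv.offset_s
            ):
                matched += 1
                used.add(j)
                break
    return matched
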