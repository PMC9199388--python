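"""Shared fixtures: the seed-0 sequence fixture with its design run, and
batches of synthetic micrograph replicates with their pipeline results."""

from __future__ import annotations

import numpy as np
import pytest

import endofish as ef


@pytest.fixture(scope="session")
def seq_fixture():
    """Seed-0 planted-probe sequence set with ground truth."""
    spec = ef.SeqFixtureSpec(seed=0)
    records, truth = ef.generate_sequences(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def design_run(seq_fixture):
    """Design pipeline output on the seed-0 fixture under default config."""
    _, records, _ = seq_fixture
    return ef.design_probes(records, ef.DesignConfig())


@pytest.fixture(scope="session")
def noisefree_image():
    """Noise-free micrograph fixture: counts must be exact."""
    spec = ef.ImageFixtureSpec(seed=0, noise_sigma=0.0)
    stack, truth = ef.generate_image(spec)
    result = ef.quantify_stacks([stack])[0]
    return spec, stack, truth, result


@pytest.fixture(scope="session")
def snr5_replicates():
    """Ten replicates at the default spot SNR of 5, with pipeline results."""
    out = []
    for seed in range(10):
        spec = ef.ImageFixtureSpec(seed=seed)
        stack, truth = ef.generate_image(spec)
        result = ef.quantify_stacks([stack])[0]
        out.append((spec, truth, result))
    return out


def match_detections(
    detected: np.ndarray, centers: np.ndarray, radius: float
) -> int:
    """Greedy one-to-one matching of detections to true centers."""
    used = set()
    tp = 0
    for (y, x) in centers:
        if len(detected) == 0:
            break
        d = np.hypot(detected[:, 0] - y, detected[:, 1] - x)
        order = np.argsort(d)
        for j in order:
            if d[j] > radius:
                break
            if j not in used:
                used.add(j)
                tp += 1
                break
    return tp
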