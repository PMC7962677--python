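import numpy as np
import pytest

from microsaccades.detect import DetectionParams, detect_dataset
from microsaccades.simulate import SimulationConfig, simulate_study
from microsaccades.stats import counts_frame


@pytest.fixture(scope="session")
def toy_config():
    """Small but otherwise default-regime study: 4 participants x 2 x 8 trials."""
    return SimulationConfig(n_participants=4, n_trials_per_session=8, seed=7)


@pytest.fixture(scope="session")
def toy_study(toy_config):
    return simulate_study(toy_config)


@pytest.fixture(scope="session")
def toy_detections(toy_study):
    dataset, _ = toy_study
    return detect_dataset(dataset.trials, DetectionParams())


@pytest.fixture(scope="session")
def toy_counts(toy_detections):
    return counts_frame(toy_detections)


def match_events(truth_onsets, detected_onsets, tol=0.020):
    """Greedy onset-proximity matching; returns (tp, fp, fn)."""
    used = set()
    tp = fn = 0
    for t in truth_onsets:
        candidates = [i for i, d in enumerate(detected_onsets)
                      if i not in used and abs(d - t) <= tol]
        if candidates:
            used.add(min(candidates, key=lambda i: abs(detected_onsets[i] - t)))
            tp += 1
        else:
            fn += 1
    fp = len(detected_onsets) - len(used)
    return tp, fp, fn


def f1_against_ground_truth(dataset, ground_truth, detections, tol=0.020):
    tp = fp = fn = 0
    for det in detections:
        truth = [e.onset_time for e in ground_truth.events[det.trial.key()]]
        found = [b.onset_index / det.trial.sampling_rate
                 for b in det.binocular_events]
        a, b, c = match_events(truth, found, tol)
        tp += a; fp += b; fn += c
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
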