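"""Shared fixtures.

The expensive session fixture (`study_protocol`) trains full-size networks
once and is shared by every acceptance test; everything else is small and
fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import hmaxmli as h
from hmaxmli import stimuli
from hmaxmli.experiments import _sweep_curve


@pytest.fixture(scope="session")
def gabor_bank():
    return h.make_gabor_bank(h.HmaxConfig())


@pytest.fixture(scope="session")
def small_c1_sets(gabor_bank):
    """C1 encodings of a handful of training images (shared, read-only)."""
    images = stimuli.generate_dataset("XF", 3, 7)
    return images, [h.compute_c1(im.pixels, gabor_bank) for im in images]


# ---------------------------------------------------------------------------
# the full-protocol fixture behind the acceptance tests

N_RUNS = 5                # networks trained (illusion-direction statistics)
N_SWEEP_RUNS = 3          # of those, runs also measured psychometrically
N_TEST_PER_CATEGORY = 50
IMAGES_PER_DIFF = 40
SWEEP_DIFFS = tuple(range(-60, 61, 10))
PROTOCOL_SEED = 20130215


@pytest.fixture(scope="session")
def study_protocol():
    """Train N_RUNS default-size networks and measure every condition.

    Returns a dict with per-run LR/ML accuracies (overall and per category)
    for all runs, per-run PSEs and pooled curves for the control and each
    Müller-Lyer fin angle on the first N_SWEEP_RUNS runs, and the trained
    networks themselves for post-hoc analyses.
    """
    config = h.RunConfig(n_test_per_category=N_TEST_PER_CATEGORY,
                         images_per_diff=IMAGES_PER_DIFF,
                         sweep_diffs=SWEEP_DIFFS,
                         master_seed=PROTOCOL_SEED)
    conditions = (("control", "LR", None), ("ML20", "ML", 20.0),
                  ("ML40", "ML", 40.0), ("ML60", "ML", 60.0))
    acc = {s: {"overall": [], "LONG": [], "SHORT": []} for s in ("LR", "ML")}
    pse = {name: [] for name, _, _ in conditions}
    curves = {name: [] for name, _, _ in conditions}
    networks = []
    ss = np.random.SeedSequence(PROTOCOL_SEED)
    for run, rseed in enumerate(ss.spawn(N_RUNS)):
        train_seed, test_seed, sweep_seed = rseed.spawn(3)
        network = h.train_network(config, train_seed)
        networks.append(network)
        for style, tseed in zip(("LR", "ML"), test_seed.spawn(2)):
            frame = network.classify(stimuli.generate_dataset(
                style, config.n_test_per_category, np.random.default_rng(tseed)))
            correct = frame["label"] == frame["predicted"]
            acc[style]["overall"].append(100.0 * correct.mean())
            for cat in ("LONG", "SHORT"):
                acc[style][cat].append(
                    100.0 * correct[frame["label"] == cat].mean())
        if run >= N_SWEEP_RUNS:
            continue
        for (name, style, angle), cseed in zip(conditions,
                                               sweep_seed.spawn(len(conditions))):
            sweep = stimuli.SweepSpec(style=style, fin_angle=angle,
                                      diffs=SWEEP_DIFFS,
                                      images_per_diff=IMAGES_PER_DIFF,
                                      seed=cseed)
            curve = _sweep_curve(network, sweep)
            curves[name].append(curve)
            try:
                pse[name].append(
                    h.estimate_pse(h.fit_sigmoid(curve)))
            except h.FitError:
                pse[name].append(np.nan)
    pooled = {}
    for name in curves:
        pooled[name] = h.PsychometricCurve(
            diffs=np.asarray(SWEEP_DIFFS, dtype=float),
            n_long=np.sum([c.n_long for c in curves[name]], axis=0),
            n_total=np.sum([c.n_total for c in curves[name]], axis=0))
    return {"config": config, "accuracy": acc, "per_run_pse": pse,
            "curves": curves, "pooled_curves": pooled, "networks": networks,
            "n_runs": N_RUNS, "n_sweep_runs": N_SWEEP_RUNS}
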