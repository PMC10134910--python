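"""Shared fixtures.

The semi-supervised benchmark runs (full model, GAN-only variant and the
supervised-only baseline, each trained on the same single labeled subject)
are expensive, so they are trained once per session and shared by the tests
that grade segmentation accuracy, reconstruction quality and the style-swap
disentanglement probe.
"""

import pytest

from cardisent.experiments import lowlabel_study, train_variant

BENCH_SEED = 1


@pytest.fixture(scope="session")
def lowlabel_benchmark():
    study, splits = lowlabel_study(seed=BENCH_SEED)
    results = {
        variant: train_variant(study, splits, seed=BENCH_SEED, variant=variant)
        for variant in ("full", "model1", "supervised")
    }
    return {"study": study, "splits": splits, "results": results}
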