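"""Shared fixtures; the expensive trained model is built once per session."""

import pytest


@pytest.fixture(scope="session")
def desk_training_run():
    """Full desk-scale segmentation study: tiny network, 6 phantoms,
    200 balanced-batch steps, one held-out phantom.  Several minutes of
    CPU; shared by every test that needs a trained segmenter."""
    from vesselforge.experiments import train_desk_segmenter
    model, history, dice = train_desk_segmenter(seed=0)
    return {"model": model, "history": history, "holdout_dice": dice}


@pytest.fixture(scope="session")
def tiny_trained_model(desk_training_run):
    return desk_training_run["model"]
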