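"""Shared fixtures: small seeded synthetic corpora and feature matrices."""

from __future__ import annotations

import numpy as np
import pytest

from falladl.features import extract_set
from falladl.segmentation import SegmentationConfig, segment_streams
from falladl.synthdata import easy_config, harmonized_streams, synth_corpus


@pytest.fixture(scope="session")
def easy_streams():
    """Small easy-preset corpus, harmonized to canonical 50 Hz streams."""
    cfg = easy_config(seed=7, n_subjects=1, session_s=60.0)
    return harmonized_streams(cfg)


@pytest.fixture(scope="session")
def easy_fm(easy_streams):
    """Raw (unscaled) feature matrix of the small easy corpus."""
    ws = segment_streams(easy_streams, SegmentationConfig())
    return extract_set(ws)


@pytest.fixture(scope="session")
def easy_corpus_native():
    """Raw native-frame recordings + manifests of the small easy corpus."""
    cfg = easy_config(seed=7, n_subjects=1, session_s=60.0)
    return synth_corpus(cfg)


@pytest.fixture(scope="session")
def separable_fm():
    """Raw feature matrix of the full separable study corpus."""
    cfg = easy_config(seed=1, n_subjects=3, session_s=115.0)
    ws = segment_streams(harmonized_streams(cfg), SegmentationConfig())
    return extract_set(ws)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
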