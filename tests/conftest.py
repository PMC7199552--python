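"""Shared fixtures: the seeded phantom battery and cached pipeline runs.

Full-pipeline runs take ~10 s each on one core, so each phantom is run
through :func:`tumorscan.detect` at most once per session and the reports
are shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tumorscan import PipelineConfig, default_suite, detect

SUITE_SEED = 7


@pytest.fixture(scope="session")
def suite():
    """The 8-phantom battery, keyed by name."""
    return {p.metadata["name"]: p for p in default_suite(SUITE_SEED)}


@pytest.fixture(scope="session")
def reports(suite):
    """Default-config detection reports for the phantoms tests assert on."""
    return {
        name: detect(suite[name].image)
        for name in ("large", "mixed8", "decoys_only", "tiny")
    }


@pytest.fixture(scope="session")
def tiny_report_noscale(suite):
    """The tiny-tumor phantom processed with patch upscaling disabled."""
    return detect(suite["tiny"].image, PipelineConfig(scale=1))


@pytest.fixture(scope="session")
def tiny_report_repeat(suite):
    """Second run on the tiny phantom, for bit-determinism checks."""
    return detect(suite["tiny"].image)


def truth_components(truth: np.ndarray):
    """Labeled 8-connected components of a ground-truth mask."""
    from scipy import ndimage

    labels, n = ndimage.label(truth, structure=np.ones((3, 3), bool))
    return labels, n
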