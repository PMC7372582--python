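"""Shared fixtures: small synthetic screens generated at test time."""

from __future__ import annotations

import warnings

import pytest

from phenoscreen.preprocess import profile_cell_line
from phenoscreen.synth import generate_screen, small_config


@pytest.fixture(scope="session")
def tiny_screen():
    """A 4-line screen small enough for sub-second per-stage runs."""
    cfg = small_config(cells_per_image_mean=120.0, n_features=50, seed=3)
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def tiny_wells(tiny_screen):
    """Well profiles per line for the tiny screen (full preprocessing)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for line in tiny_screen.cell_lines:
            cells = tiny_screen.cell_features(line)
            wells, report = profile_cell_line(cells, tiny_screen.platemap_for(line))
            out[line] = (wells, report)
    return out
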