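from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from anatogram import (
    ExpressionMatrix,
    FixtureSpec,
    GeneLookup,
    GeneRecord,
    TissueGroup,
    TissueSummary,
    ViewDefinition,
    build_demo_catalog,
    generate_anatomy,
)


@pytest.fixture(scope="session")
def demo_catalog(tmp_path_factory):
    """The shipped demo compendium, built once per session."""
    d = tmp_path_factory.mktemp("demo_catalog")
    catalog = build_demo_catalog(d, seed=0)
    return d, catalog


@pytest.fixture(scope="session")
def demo_microarray(demo_catalog):
    _, catalog = demo_catalog
    return catalog.load_matrix("HG-U133A"), catalog.load_lookup()


@pytest.fixture
def small_matrix():
    """2 measurements x 4 samples with one missing cell."""
    df = pd.DataFrame(
        {
            "s1": [10.0, 1.0],
            "s2": [14.0, 2.0],
            "s3": [7.0, math.nan],
            "s4": [3.0, 4.0],
        },
        index=["p1", "p2"],
    )
    return ExpressionMatrix(df, "HG-U133A")


@pytest.fixture
def small_lookup():
    return GeneLookup(
        [
            GeneRecord("3630", "INS", ("p1", "p2"), "insulin"),
            GeneRecord("6496", "SIX3", ("p3",), "homeobox"),
        ]
    )


@pytest.fixture
def small_view():
    """Two-tissue view over the small_matrix samples (no image on disk)."""
    return ViewDefinition(
        name="toy",
        base_image_path="missing.png",
        platform_tag="HG-U133A",
        groups=(
            TissueGroup("alpha", (255, 0, 0), ("s1", "s2"), record_id="GSE7307",
                        centroid_hint=(5, 5)),
            TissueGroup("beta", (0, 255, 0), ("s3", "s4"), centroid_hint=(15, 5)),
        ),
    )


@pytest.fixture
def drawn_view(tmp_path):
    """A three-region anatomy actually drawn to disk."""
    spec = FixtureSpec(n_regions=3, image_size=(90, 60), seed=7)
    img, view = generate_anatomy(spec, tmp_path, name="drawn", platform_tag="HG-U133A")
    return spec, img, view


def make_summaries(means, missing=None, sds=None):
    missing = missing or [False] * len(means)
    sds = sds or [0.0] * len(means)
    return [
        TissueSummary(
            f"t{i}",
            math.nan if miss else m,
            math.nan if miss else sd,
            0 if miss else 3,
            missing=miss,
        )
        for i, (m, miss, sd) in enumerate(zip(means, missing, sds))
    ]
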