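"""Shared fixtures: small synthetic cohorts and a reusable embedding.

Everything is generated programmatically with fixed seeds; session scope
keeps the t-SNE runs (the only expensive step) to a minimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hspcmap.fcs_io import load_config
from hspcmap.pregating import pregate_patient
from hspcmap.similarity_classify import DensityGrid, GridSpec
from hspcmap.synthetic_cohort import (
    CohortSpec,
    default_mixture,
    generate_cohort,
)
from hspcmap.transform_embed import (
    EmbedParams,
    merge_cohort,
    scale_expression,
    tsne_embed,
)


def cd34_only_mixture(group: str) -> dict[str, float]:
    """Group mixture restricted to the CD34+ compartment (no background)."""
    mix = {
        k: v
        for k, v in default_mixture(group).items()
        if k not in ("LYMPHOCYTE", "MONOCYTE", "GRANULOCYTE")
    }
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


@pytest.fixture(scope="session")
def default_config():
    return load_config(None)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six patients with full background/doublet/dead structure."""
    spec = CohortSpec(
        n_cr=3, n_ad=3, cells_per_patient=(800, 1500), seed=1
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def embedded_cohort(tiny_cohort, default_config):
    """Pregated, merged and embedded tiny cohort (~900 cells)."""
    _, cohort = tiny_cohort
    cfg = default_config
    gated = []
    for table in cohort.tables:
        g, _ = pregate_patient(
            table,
            scatter_gate=cfg.scatter_gate,
            cd45_gate=cfg.cd45_gate,
            goi_gate=cfg.goi_gate,
            viability_threshold=cfg.viability_threshold,
            cd34_threshold=cfg.cd34_threshold,
            cap=150,
            seed=0,
        )
        gated.append(scale_expression(g, cfg.cofactor))
    merged = merge_cohort(gated)
    return tsne_embed(merged, EmbedParams(perplexity=30, n_iter=300, seed=0))


@pytest.fixture(scope="session")
def embedding_grid(embedded_cohort):
    return DensityGrid.from_embedding(embedded_cohort, GridSpec())
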