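import numpy as np
import pandas as pd
import pytest

from tlskit import (
    MarkerSet,
    SimulationConfig,
    mcp_score,
    simulate_cna_survival,
    simulate_expression,
)

MARKERS = MarkerSet(
    "B_lineage", ("CD79A", "CD79B", "CD19", "MS4A1", "BANK1",
                  "CR2", "FCRL2", "IGKC", "PAX5", "CD22")
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sample cohort with a protective TLS effect, shared across tests."""
    cfg = SimulationConfig(
        n_samples=120, n_genes=150, tls_fraction=0.25, marker_effect=2.0,
        planted_locus_genes=["LOCUS01"], deletion_prob_low=0.8,
        deletion_prob_high=0.1, seed=42,
    )
    expr, labels = simulate_expression(cfg, list(MARKERS.genes))
    scores = mcp_score(expr, MARKERS)
    cna, clinical, truth = simulate_cna_survival(cfg, scores)
    return {
        "config": cfg, "expr": expr, "labels": labels, "scores": scores,
        "cna": cna, "clinical": clinical, "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
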