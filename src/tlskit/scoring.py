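"""Marker-based immune population scoring and TLS dichotomization.

The TLS signature is the B-lineage population score: the arithmetic mean of
the log2 expression of the B-lineage marker genes present in the matrix
(the MCPcounter-style population statistic).  Samples are split into
TLS-high / TLS-low at a configurable score quantile (default: top quartile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from math import ceil

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSet",
    "mcp_score",
    "score_all_populations",
    "dichotomize_scores",
    "load_default_marker_db",
    "read_gmt",
]

TLS_POPULATION = "B_lineage"


@dataclass(frozen=True)
class MarkerSet:
    """A named immune population and its marker gene list."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"marker set {self.name!r} has duplicate genes")


def read_gmt(path) -> list[MarkerSet]:
    """Read marker sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append(MarkerSet(name=fields[0], genes=tuple(g for g in fields[2:] if g)))
    return sets


def load_default_marker_db() -> list[MarkerSet]:
    """The bundled six-population marker database (B lineage = TLS)."""
    ref = resources.files("tlskit") / "markers" / "default_populations.gmt"
    with resources.as_file(ref) as path:
        return read_gmt(path)


def mcp_score(expr: pd.DataFrame, markers: MarkerSet) -> pd.Series:
    """Population score: mean log2 expression of the present marker genes.

    Markers absent from the matrix are ignored (and listed in the error if
    none at all are present).  The score is invariant to gene/row order and
    to any non-marker rows.
    """
    present = [g for g in markers.genes if g in expr.index]
    if not present:
        raise ValueError(
            f"no marker genes of population {markers.name!r} present in the "
            f"expression matrix; missing: {list(markers.genes)}"
        )
    missing = [g for g in markers.genes if g not in expr.index]
    if missing:
        warnings.warn(f"{markers.name}: {len(missing)} marker gene(s) absent: {missing}")
    scores = expr.loc[present].mean(axis=0)
    scores.name = markers.name
    return scores


def score_all_populations(expr: pd.DataFrame, marker_db: list[MarkerSet]) -> pd.DataFrame:
    """Score every population; one column per population (samples as rows).

    Populations with no marker genes in the matrix are dropped with a
    warning rather than failing the whole table.
    """
    cols = {}
    for ms in marker_db:
        try:
            cols[ms.name] = mcp_score(expr, ms)
        except ValueError:
            warnings.warn(f"population {ms.name!r} dropped: no marker genes present")
    return pd.DataFrame(cols)


def dichotomize_scores(scores: pd.Series, high_quantile: float = 0.75) -> pd.Series:
    """Label the top (1 - high_quantile) fraction of samples as TLS-high.

    Exactly ceil((1 - high_quantile) * n) samples are labeled high; ties in
    the score are broken by stable sample-id order so the assignment is
    deterministic and permutation-invariant.  227 distinct scores at the
    default 0.75 give the 57 high / 170 low split.
    """
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if not 0 < high_quantile < 1:
        raise ValueError("high_quantile must be in (0,1)")
    if scores.nunique() == 1:
        warnings.warn("all scores identical; labeling every sample TLS-low")
        return pd.Series(0, index=scores.index, name="tls_label")
    n_high = ceil((1 - high_quantile) * n)
    order = scores.to_frame("s").assign(sid=scores.index.astype(str))
    order = order.sort_values(["s", "sid"], ascending=[False, True], kind="stable")
    high_ids = set(order.index[:n_high])
    labels = pd.Series(
        [1 if s in high_ids else 0 for s in scores.index],
        index=scores.index,
        name="tls_label",
    )
    return labels
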