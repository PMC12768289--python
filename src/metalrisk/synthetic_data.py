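"""Synthetic concentration surveys with known statistical structure.

Trace-element data are positive and right-skewed, elements sharing a source
co-vary, and outfalls fall into groups with distinct release profiles.  The
generator emulates exactly that: log-normal marginals coupled through a
Gaussian copula with block-structured correlation, plus optional multiplicative
site-cluster offsets.  The ground truth (target correlation matrix, cluster
labels) is returned next to the table so recovery tests never re-derive it.

The two bundled study tables (9 outfalls × 12 elements; water in µg/L,
sediment in mg/kg) are exposed here as well via :func:`bundled_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import ConcentrationTable, read_concentration_table

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "bundled_table"]

_FIXTURES = {"water": "water_table1.csv", "sediment": "sediment_table2.csv"}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic survey.

    ``correlation_blocks`` is a list of ``(element subset, rho)`` pairs giving
    the common within-block correlation of the log-concentrations; blocks must
    be disjoint and the implied matrix positive definite.  ``site_clusters``
    optionally lists ``(site index subset, element → multiplicative offset)``
    pairs creating separable site groups.
    """

    n_sites: int
    elements: list[str]
    log_mean: dict[str, float]
    log_sd: dict[str, float]
    correlation_blocks: list[tuple[list[str], float]] = field(default_factory=list)
    site_clusters: list[tuple[list[int], dict[str, float]]] = field(default_factory=list)
    seed: int = 0
    medium: str = "water"

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        missing = [e for e in self.elements if e not in self.log_mean or e not in self.log_sd]
        if missing:
            raise ValueError(f"log_mean/log_sd missing for {missing}")
        if any(self.log_sd[e] <= 0 for e in self.elements):
            raise ValueError("log_sd must be > 0")
        seen: set[str] = set()
        for block, rho in self.correlation_blocks:
            if not 0 <= rho < 1:
                raise ValueError("block correlation must be in [0, 1)")
            if seen & set(block):
                raise ValueError("correlation blocks must be disjoint")
            seen |= set(block)
        for sites, offsets in self.site_clusters:
            if any(v <= 0 for v in offsets.values()):
                raise ValueError("cluster offsets must be > 0")
            if any(not 0 <= i < self.n_sites for i in sites):
                raise ValueError("cluster site index out of range")

    def correlation_matrix(self) -> np.ndarray:
        p = len(self.elements)
        corr = np.eye(p)
        idx = {e: i for i, e in enumerate(self.elements)}
        for block, rho in self.correlation_blocks:
            ii = [idx[e] for e in block]
            for a in ii:
                for b in ii:
                    if a != b:
                        corr[a, b] = rho
        return corr


@dataclass
class GroundTruth:
    correlation: pd.DataFrame  # target log-space correlation
    cluster_labels: pd.Series  # site → cluster id (0 = background)
    log_mean: dict[str, float]
    log_sd: dict[str, float]


def generate(config: SyntheticConfig) -> tuple[ConcentrationTable, GroundTruth]:
    """Sample one survey; deterministic for a fixed config + seed."""
    config.validate()
    corr = config.correlation_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied correlation matrix is not positive definite") from exc

    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n_sites, len(config.elements))) @ chol.T
    mu = np.array([config.log_mean[e] for e in config.elements])
    sd = np.array([config.log_sd[e] for e in config.elements])
    values = np.exp(mu + sd * z)

    labels = np.zeros(config.n_sites, dtype=int)
    for cluster_id, (sites, offsets) in enumerate(config.site_clusters, start=1):
        labels[sites] = cluster_id
        for e, factor in offsets.items():
            values[sites, config.elements.index(e)] *= factor

    site_ids = [f"S{i + 1}" for i in range(config.n_sites)]
    frame = pd.DataFrame(values, index=pd.Index(site_ids, name="site"),
                         columns=config.elements)
    table = ConcentrationTable(medium=config.medium, values=frame)
    truth = GroundTruth(
        correlation=pd.DataFrame(corr, index=config.elements, columns=config.elements),
        cluster_labels=pd.Series(labels, index=site_ids, name="cluster"),
        log_mean=dict(config.log_mean),
        log_sd=dict(config.log_sd),
    )
    return table, truth


def bundled_table(which: str) -> ConcentrationTable:
    """One of the two bundled study tables (``"water"`` or ``"sediment"``)."""
    if which not in _FIXTURES:
        raise ValueError(f"unknown fixture {which!r}; choose from {sorted(_FIXTURES)}")
    ref = resources.files("metalrisk.data").joinpath(_FIXTURES[which])
    with resources.as_file(ref) as path:
        return read_concentration_table(Path(path), medium=which)
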