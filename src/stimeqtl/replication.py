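"""Replication-rate estimation via Storey's pi0 / pi1.

pi0(lambda) = #{p > lambda} / (n (1 - lambda)) over a lambda grid; a cubic
smoother through the grid evaluated at the largest lambda gives the pi0
estimate (clipped to [0, 1]); pi1 = 1 - pi0 quantifies the fraction of
true alternatives, used as the replication rate of one dataset's
significant eQTLs in another.

Caveat carried into the output metadata: this approach does not take the
direction or magnitude of eQTL effects into account — only the p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("stimeqtl")

CAVEAT = ("pi1 is based on p-values only and does not take the direction "
          "or magnitude of eQTL effects into account")


@dataclass
class ReplicationEstimate:
    n_pairs: int
    lambda_grid: np.ndarray
    pi0: float
    n_unmatched: int = 0
    note: str = field(default=CAVEAT)

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


def pi0_estimate(p, lambda_grid: np.ndarray | None = None) -> ReplicationEstimate:
    """Smoother-based Storey pi0 from a p-value vector.

    Default grid 0.05..0.95 step 0.05; a cubic polynomial fit of
    pi0(lambda) is evaluated at the maximum lambda and clipped to [0, 1].
    Fails below 10 p-values (the smoother is unstable there).
    """
    p = np.asarray(p, dtype=float)
    if p.size < 10:
        raise ValueError("pi0 estimation needs at least 10 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    grid = np.arange(0.05, 0.96, 0.05) if lambda_grid is None \
        else np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
    coeffs = np.polyfit(grid, pi0_lam, deg=3)
    pi0 = float(np.clip(np.polyval(coeffs, grid.max()), 0.0, 1.0))
    return ReplicationEstimate(n_pairs=p.size, lambda_grid=grid, pi0=pi0)


def replication_rate(discovery_pairs: pd.DataFrame,
                     replication: pd.DataFrame) -> ReplicationEstimate:
    """pi1 of one dataset's significant pairs evaluated in another.

    Both frames need gene and snp columns; ``replication`` needs p.
    Unmatched discovery pairs are counted and excluded (eQTLs untested in
    the replication dataset do not enter the estimate).
    """
    rep = replication.set_index(["gene", "snp"])["p"]
    keys = pd.MultiIndex.from_frame(discovery_pairs[["gene", "snp"]])
    matched = keys[keys.isin(rep.index)]
    n_unmatched = len(keys) - len(matched)
    if len(matched) == 0:
        raise ValueError("no discovery pair found in the replication dataset")
    if n_unmatched:
        logger.info("%d discovery pairs untested in replication; excluded",
                    n_unmatched)
    est = pi0_estimate(rep.loc[matched].to_numpy())
    est.n_unmatched = n_unmatched
    return est
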