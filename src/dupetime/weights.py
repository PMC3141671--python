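"""Topology probabilities from per-topology (site) log-likelihoods.

Two estimators are provided: normalized likelihood weights (an approximate
posterior over topologies under equal priors) and RELL bootstrap
proportions (site log-likelihoods resampled with replacement, winners
tallied). A Kishino–Hasegawa-style one-standard-error confidence set is
computed from per-site log-likelihood differences against the best
topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TopologyWeights:
    """Normalized topology probabilities plus per-topology diagnostics."""

    lnl: np.ndarray                  # per-topology total log-likelihood
    weights: np.ndarray              # normalized, sums to one
    method: str                      # "likelihood_weight" or "rell_bp"
    delta_lnl: np.ndarray = field(default=None)  # lnL_max - lnL_t
    kh_se: np.ndarray | None = None  # KH standard error of delta vs best
    in_sigma_set: np.ndarray | None = None
    replicates: int | None = None
    seed: int | None = None
    placement_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.lnl = np.asarray(self.lnl, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.delta_lnl is None:
            self.delta_lnl = self.lnl.max() - self.lnl
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to one")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "placement_id": self.placement_ids
                if self.placement_ids is not None
                else np.arange(len(self.lnl)),
                "lnL": self.lnl,
                "delta_lnL": self.delta_lnl,
                "weight": self.weights,
            }
        )
        if self.kh_se is not None:
            df["KH_SE"] = self.kh_se
        if self.in_sigma_set is not None:
            df["in_1sigma_set"] = self.in_sigma_set
        return df


def likelihood_weights(lnl, placement_ids=None) -> TopologyWeights:
    """Softmax of total log-likelihoods (log-sum-exp stabilized).

    w_t = exp(lnL_t - m) / sum_s exp(lnL_s - m) with m = max lnL; invariant
    under adding a constant to every lnL.
    """
    lnl = np.asarray(lnl, dtype=float)
    if lnl.size == 0:
        raise ValueError("empty log-likelihood vector")
    if not np.all(np.isfinite(lnl)):
        raise ValueError("non-finite log-likelihoods")
    shifted = lnl - lnl.max()
    w = np.exp(shifted)
    w /= w.sum()
    return TopologyWeights(
        lnl=lnl, weights=w, method="likelihood_weight", placement_ids=placement_ids
    )


def rell_weights(
    site_lnl, replicates: int = 10_000, seed: int | None = None, placement_ids=None
) -> TopologyWeights:
    """RELL bootstrap proportions over topologies.

    ``site_lnl`` is (sites x topologies). Sites are resampled with
    replacement; per-topology totals are recomputed by summation only (no
    re-optimization) and the best topology of each replicate scores one
    (ties split equally).
    """
    site_lnl = np.asarray(site_lnl, dtype=float)
    if site_lnl.ndim != 2 or site_lnl.shape[0] < 1 or site_lnl.shape[1] < 2:
        raise ValueError("need a (sites >= 1) x (topologies >= 2) matrix")
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if seed is None:
        raise ValueError("a seed is mandatory for RELL resampling")
    n_sites, n_topo = site_lnl.shape
    rng = np.random.default_rng(seed)
    wins = np.zeros(n_topo)
    chunk = max(1, min(2000, replicates))
    done = 0
    p = np.full(n_sites, 1.0 / n_sites)
    while done < replicates:
        b = min(chunk, replicates - done)
        counts = rng.multinomial(n_sites, p, size=b)      # (b, sites)
        totals = counts @ site_lnl                         # (b, topologies)
        best = totals.max(axis=1, keepdims=True)
        is_best = np.isclose(totals, best, rtol=0.0, atol=1e-10)
        wins += (is_best / is_best.sum(axis=1, keepdims=True)).sum(axis=0)
        done += b
    w = wins / replicates
    return TopologyWeights(
        lnl=site_lnl.sum(axis=0),
        weights=w,
        method="rell_bp",
        replicates=replicates,
        seed=seed,
        placement_ids=placement_ids,
    )


def kh_standard_errors(site_lnl) -> tuple[np.ndarray, np.ndarray]:
    """(delta_lnl, KH SE) of each topology against the maximum-likelihood one.

    SE(t) = sd over sites of (site_lnL_best - site_lnL_t) scaled by
    sqrt(n_sites), i.e. the standard error of the summed difference.
    """
    site_lnl = np.asarray(site_lnl, dtype=float)
    totals = site_lnl.sum(axis=0)
    best = int(np.argmax(totals))
    diffs = site_lnl[:, [best]] - site_lnl  # (sites, topologies)
    n = site_lnl.shape[0]
    sd = diffs.std(axis=0, ddof=1) if n > 1 else np.zeros(site_lnl.shape[1])
    return totals[best] - totals, sd * np.sqrt(n)


def kh_sigma_set(site_lnl) -> np.ndarray:
    """Boolean mask of topologies within one KH standard error of the best.

    The maximum-likelihood topology is always a member (delta = SE = 0).
    """
    delta, se = kh_standard_errors(site_lnl)
    return delta <= se + 1e-12


def attach_kh(weights: TopologyWeights, site_lnl) -> TopologyWeights:
    """Fill the KH-SE and one-sigma-set fields from a site matrix."""
    delta, se = kh_standard_errors(site_lnl)
    weights.kh_se = se
    weights.in_sigma_set = delta <= se + 1e-12
    weights.delta_lnl = delta
    return weights
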