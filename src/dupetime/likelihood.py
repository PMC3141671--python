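"""Fixed-topology likelihood of protein alignments under empirical models.

Implements Felsenstein's pruning algorithm for the JTT and LG amino-acid
replacement matrices with discrete-gamma rate variation (+G), a proportion
of invariant sites (+I) and optional empirical frequencies (+F), plus
coordinate-wise (Brent) maximum-likelihood branch-length optimization on a
fixed topology. This is the engine used to score each candidate placement
of a query gene on the constrained backbone.

Rate matrices are assembled as Q_ij = s_ij * pi_j from the published
exchangeabilities (Jones et al. 1992 for JTT; Le & Gascuel 2008 for LG;
values shipped as PAML-format text under ``data/``) and rescaled so one
unit of branch length equals one expected substitution per site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .seqdata import ProteinAlignment, RootedTree

#: canonical residue order of the PAML matrix files
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_MATRIX_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0


def load_empirical_matrix(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (exchangeabilities 20x20 symmetric, stationary frequencies).

    ``name`` is ``"JTT"`` or ``"LG"``. Files are PAML-format lower
    triangles followed by the 20 frequencies, in ARNDCQEGHILKMFPSTWYV
    order.
    """
    key = name.upper()
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    if key not in {"JTT", "LG"}:
        raise ValueError(f"unknown matrix {name!r}; choose JTT or LG")
    text = (resources.files("dupetime") / "data" / f"{key.lower()}.dat").read_text()
    numbers = [float(x) for x in text.split()]
    if len(numbers) != 190 + 20:
        raise ValueError(f"malformed matrix file for {key}")
    S = np.zeros((20, 20))
    pos = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = numbers[pos]
            pos += 1
    pi = np.array(numbers[190:])
    pi = pi / pi.sum()
    _MATRIX_CACHE[key] = (S, pi)
    return S, pi


def discretize_gamma(alpha: float, k: int, method: str = "mean") -> np.ndarray:
    """Discrete-gamma category rates (equal probability 1/k per category).

    ``method="mean"`` uses the mean of each inter-quantile slice of
    Gamma(alpha, alpha) (mean-one parameterization), so the category rates
    average exactly one; ``"median"`` uses slice medians renormalized to
    mean one.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    if method == "mean":
        bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
        # E[X; X in slice] for X~Gamma(alpha, rate alpha) via the shape+1 CDF
        upper = gammainc(alpha + 1.0, alpha * bounds[1:])
        upper[-1] = 1.0
        lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
        rates = k * (upper - lower)
    elif method == "median":
        q = (np.arange(k) + 0.5) / k
        rates = gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha)
        rates = rates / rates.mean()
    else:
        raise ValueError("method must be 'mean' or 'median'")
    return rates


@dataclass(frozen=True)
class SubstitutionModel:
    """Empirical amino-acid model: JTT or LG, optionally +I, +G, +F.

    alpha=None means no gamma rate variation; p_inv=None means no invariant
    class. With both present, variable-category rates are rescaled by
    1/(1-p_inv) so the expected overall rate stays one.
    """

    matrix_name: str = "JTT"
    alpha: float | None = None
    n_categories: int = 4
    p_inv: float | None = None
    frequencies: np.ndarray | None = None  # None = model frequencies
    gamma_method: str = "mean"

    def with_empirical_frequencies(self, aln: ProteinAlignment) -> "SubstitutionModel":
        """The '+F' variant: frequencies observed in the alignment."""
        counts = np.zeros(20)
        for row in aln.rows:
            for ch in row:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        if counts.sum() == 0:
            raise ValueError("alignment has no canonical residues")
        return replace(self, frequencies=counts / counts.sum())

    @property
    def pi(self) -> np.ndarray:
        if self.frequencies is not None:
            return np.asarray(self.frequencies, dtype=float)
        return load_empirical_matrix(self.matrix_name)[1]

    def rate_matrix(self) -> np.ndarray:
        """Q normalized to one expected substitution per unit branch length."""
        S, _ = load_empirical_matrix(self.matrix_name)
        pi = self.pi
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def category_rates(self) -> tuple[np.ndarray, float]:
        """(variable-category rates, p_inv); rates already 1/(1-p_inv) scaled."""
        p_inv = float(self.p_inv) if self.p_inv is not None else 0.0
        if not 0.0 <= p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.alpha is None:
            rates = np.ones(1)
        else:
            rates = discretize_gamma(self.alpha, self.n_categories, self.gamma_method)
        return rates / (1.0 - p_inv), p_inv

    def spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via pi^{1/2} symmetrization.

        Returns (left, eigenvalues, right) with P(t) = left @ diag(e^{lam t}) @ right.
        """
        pi = self.pi
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        # reversibility makes D^{1/2} Q D^{-1/2} symmetric (up to rounding)
        B = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        left = V / sq[:, None]
        right = V.T * sq[None, :]
        return left, lam, right

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        left, lam, right = self.spectral()
        P = (left * np.exp(lam * t)[None, :]) @ right
        return np.clip(P, 0.0, None)


@dataclass
class SiteLogLikelihoods:
    """Per-site log-likelihoods of one alignment on one topology."""

    per_site: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_site.sum())


class TreeLikelihood:
    """Pruning-algorithm likelihood of one alignment on one rooted topology.

    Site patterns are compressed; partial likelihoods carry per-pattern log
    scaling factors so long trees do not underflow. Under the reversible
    models used here the likelihood is invariant to root position.
    """

    def __init__(self, tree: RootedTree, aln: ProteinAlignment, model: SubstitutionModel):
        missing = set(tree.leaf_names()) - set(aln.names)
        if missing:
            raise ValueError(f"taxa missing from alignment: {sorted(missing)}")
        self.tree = tree
        self.model = model
        self.nodes = list(tree.postorder())
        self.index = {n.name: i for i, n in enumerate(self.nodes)}
        # encode columns: rows ordered as tree leaves; -1 = gap/X (missing)
        leaf_names = tree.leaf_names()
        mat = np.array(
            [[AA_INDEX.get(ch, -1) for ch in aln.row(name)] for name in leaf_names],
            dtype=np.int16,
        )
        patterns, self.pattern_index, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_leaves, n_patterns)
        self.weights = counts.astype(float)
        self.leaf_row = {name: i for i, name in enumerate(leaf_names)}
        self.n_sites = aln.length
        self.left, self.lam, self.right = model.spectral()
        self.rates, self.p_inv = model.category_rates()
        self.pi = model.pi
        self._inv_lik = self._invariant_likelihood() if self.p_inv > 0 else None

    # -- transition matrices ----------------------------------------------

    def _P(self, t: float) -> np.ndarray:
        """(k, 20, 20) transition matrices at branch length t, one per rate."""
        e = np.exp(self.lam[None, :] * (self.rates[:, None] * max(t, 0.0)))
        P = np.einsum("ij,kj,jl->kil", self.left, e, self.right)
        return np.clip(P, 0.0, None)

    def _invariant_likelihood(self) -> np.ndarray:
        """Per-pattern likelihood under the zero-rate (invariant) class."""
        lik = np.ones(self.patterns.shape[1])
        for p in range(self.patterns.shape[1]):
            col = self.patterns[:, p]
            present = col[col >= 0]
            if present.size == 0:
                lik[p] = 1.0
            elif np.all(present == present[0]):
                lik[p] = self.pi[present[0]]
            else:
                lik[p] = 0.0
        return lik

    # -- downward (post-order) partials -----------------------------------

    def _leaf_partial(self, name: str) -> np.ndarray:
        col = self.patterns[self.leaf_row[name]]
        k, npat = len(self.rates), self.patterns.shape[1]
        part = np.zeros((k, npat, 20))
        obs = col >= 0
        part[:, ~obs, :] = 1.0
        part[:, np.where(obs)[0], col[obs]] = 1.0
        return part

    def _down_pass(self):
        """Conditional likelihoods of each subtree; returns (partials, logscales).

        Side effect: caches each child's branch contribution
        ``down[j] @ P(t_j)^T`` in ``self._contrib`` for reuse by the above
        pass and the per-edge optimizer.
        """
        npat = self.patterns.shape[1]
        down: list[np.ndarray | None] = [None] * len(self.nodes)
        logscale = [np.zeros(npat) for _ in self.nodes]
        self._contrib: list[np.ndarray | None] = [None] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            if not node.is_leaf:
                part = np.ones((len(self.rates), npat, 20))
                for child in node.children:
                    j = self.index[child.name]
                    part = part * self._contrib[j]
                    logscale[i] += logscale[j]
                m = part.max(axis=(0, 2))
                m[m == 0.0] = 1.0
                down[i] = part / m[None, :, None]
                logscale[i] += np.log(m)
            else:
                down[i] = self._leaf_partial(node.name)
            if node is not self.tree.root:
                P = self._P(self._length(node))
                self._contrib[i] = down[i] @ P.transpose(0, 2, 1)
        return down, logscale

    @staticmethod
    def _length(node) -> float:
        if node.length is None:
            raise ValueError(f"branch above {node.name!r} has no length")
        return float(node.length)

    # -- full likelihood ---------------------------------------------------

    def site_log_likelihoods(self) -> SiteLogLikelihoods:
        down, logscale = self._down_pass()
        r = self.index[self.tree.root.name]
        mix = (down[r] @ self.pi).mean(axis=0)  # average over rate categories
        per_pattern = self._combine(mix, logscale[r])
        return SiteLogLikelihoods(per_pattern[self.pattern_index])

    def _combine(self, mix: np.ndarray, logscale: np.ndarray) -> np.ndarray:
        """Fold the invariant class into the variable-rate mixture (log scale)."""
        if self.p_inv > 0:
            var = np.log(np.clip((1.0 - self.p_inv) * mix, 1e-300, None)) + logscale
            inv = np.log(np.clip(self.p_inv * self._inv_lik, 1e-300, None))
            return np.logaddexp(var, inv)
        return np.log(np.clip(mix, 1e-300, None)) + logscale

    def log_likelihood(self) -> float:
        down, logscale = self._down_pass()
        r = self.index[self.tree.root.name]
        mix = (down[r] @ self.pi).mean(axis=0)
        per_pattern = self._combine(mix, logscale[r])
        return float(per_pattern @ self.weights)

    # -- branch-length optimization ----------------------------------------

    def _edge_objective(self, B, Dv):
        """Spectral factorization of one branch's likelihood profile.

        With P(t) = L diag(e^{lam r_c t}) R, the category mixture
        sum_ab B_a P_ab(t) D_b reduces to sum_j (B L)_j (D R^T)_j e^{lam_j r_c t},
        so each Brent trial costs O(k * patterns * 20).
        """
        U = (B @ self.left) * (Dv @ self.right.T)  # (k, npat, 20)
        def mix_at(t: float) -> np.ndarray:
            e = np.exp(self.lam[None, :] * (self.rates[:, None] * max(t, 0.0)))
            return np.einsum("kpj,kj->p", U, e) / len(self.rates)
        return mix_at

    def _edge_loglik(self, mix_at, t, scale):
        per_pattern = self._combine(np.clip(mix_at(t), 0.0, None), scale)
        return float(per_pattern @ self.weights)

    def optimize_branch_lengths(
        self,
        tol: float = 1e-6,
        max_rounds: int = 50,
        xtol: float = 1e-6,
        branches: set[str] | None = None,
    ) -> float:
        """Cyclic Brent optimization of branch lengths in place.

        ``branches`` restricts optimization to the named branches (child-node
        names), e.g. the three branches touched by a graft; default is all.

        Each sweep recomputes subtree partials post-order, then walks the
        tree pre-order maintaining exact above-edge partials as lengths
        change, so every one-dimensional step is true coordinate ascent and
        the likelihood is non-decreasing across sweeps. Returns the final
        log-likelihood; warns (keeping the last iterate) if the round limit
        is reached without convergence.
        """
        npat = self.patterns.shape[1]
        k = len(self.rates)
        prev = self.log_likelihood()
        for _ in range(max_rounds):
            down, dscale = self._down_pass()
            r = self.index[self.tree.root.name]
            A: list[np.ndarray | None] = [None] * len(self.nodes)
            ascale = [np.zeros(npat) for _ in self.nodes]
            A[r] = np.broadcast_to(self.pi, (k, npat, 20)).copy()
            for node in self.tree.preorder():
                i = self.index[node.name]
                for child in node.children:
                    j = self.index[child.name]
                    # above-edge partial from exactly current quantities:
                    # siblings processed earlier in this loop have updated
                    # contributions; branches below are untouched this sweep
                    B = A[i].copy()
                    bscale = ascale[i].copy()
                    for sib in node.children:
                        if sib is child:
                            continue
                        s = self.index[sib.name]
                        B = B * self._contrib[s]
                        bscale += dscale[s]
                    if branches is None or child.name in branches:
                        scale = bscale + dscale[j]
                        mix_at = self._edge_objective(B, down[j])
                        current = self._edge_loglik(mix_at, self._length(child), scale)
                        res = minimize_scalar(
                            lambda t: -self._edge_loglik(mix_at, t, scale),
                            bounds=(MIN_BRANCH, MAX_BRANCH),
                            method="bounded",
                            options={"xatol": xtol},
                        )
                        if -res.fun > current:
                            child.length = float(res.x)
                            P = self._P(child.length)
                            self._contrib[j] = down[j] @ P.transpose(0, 2, 1)
                    if not child.is_leaf:
                        part = B @ self._P(self._length(child))
                        m = part.max(axis=(0, 2))
                        m[m == 0.0] = 1.0
                        A[j] = part / m[None, :, None]
                        ascale[j] = bscale + np.log(m)
            total = self.log_likelihood()
            if total < prev - 1e-6:
                warnings.warn("branch sweep decreased the likelihood; stopping")
                break
            if abs(total - prev) < tol:
                prev = total
                break
            prev = total
        else:
            warnings.warn("branch-length optimization hit the round limit")
        return prev


def pruning_loglik(
    aln: ProteinAlignment, tree: RootedTree, model: SubstitutionModel
) -> SiteLogLikelihoods:
    """Per-site log-likelihoods of ``aln`` on ``tree`` under ``model``."""
    return TreeLikelihood(tree, aln, model).site_log_likelihoods()


def optimize_branch_lengths(
    aln: ProteinAlignment,
    tree: RootedTree,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 50,
    xtol: float = 1e-6,
    branches: set[str] | None = None,
) -> tuple[RootedTree, float]:
    """ML branch lengths on a fixed topology (tree is copied, not mutated)."""
    work = tree.copy()
    for node in work.postorder():
        if node is not work.root and node.length is None:
            node.length = 0.1
    engine = TreeLikelihood(work, aln, model)
    lnl = engine.optimize_branch_lengths(
        tol=tol, max_rounds=max_rounds, xtol=xtol, branches=branches
    )
    return work, lnl


def estimate_alpha(
    aln: ProteinAlignment,
    tree: RootedTree,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.05, 50.0),
    branch_rounds: int = 2,
) -> float:
    """One-dimensional ML estimate of the gamma shape on a fixed topology.

    Branch lengths are re-optimized (coarsely) for each trial alpha; used
    once on a reference topology, after which the shape is held fixed
    across candidate placements.
    """

    def neg(log_a: float) -> float:
        m = replace(model, alpha=float(np.exp(log_a)))
        _, lnl = optimize_branch_lengths(aln, tree, m, max_rounds=branch_rounds, xtol=1e-4)
        return -lnl

    res = minimize_scalar(
        neg,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-2},
    )
    return float(np.exp(res.x))


def estimate_p_inv(
    aln: ProteinAlignment,
    tree: RootedTree,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.0, 0.7),
    branch_rounds: int = 2,
) -> float:
    """One-dimensional ML estimate of the invariant-site proportion."""

    def neg(p: float) -> float:
        m = replace(model, p_inv=float(p))
        _, lnl = optimize_branch_lengths(aln, tree, m, max_rounds=branch_rounds, xtol=1e-4)
        return -lnl

    res = minimize_scalar(
        neg, bounds=bounds, method="bounded", options={"xatol": 1e-2}
    )
    return float(res.x)
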