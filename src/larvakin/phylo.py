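"""Bayesian multivariate Brownian-motion trait evolution on a fixed tree.

Species-level traits (log-transformed kinematic statistics) are modelled
as a multivariate Brownian diffusion along a rooted binary phylogeny
with relative-time branch lengths.  The model factorises the tip
distribution as a matrix normal: the n x n row covariance C is the
phylogenetic covariance with *branch-specific* rates r_b (a relaxed
clock: C[i,j] sums r_b * t_b over the branches shared by the root-to-tip
paths of i and j), and the k x k column covariance is

    Sigma = sigma^2 * diag(sqrt(v)) * R * diag(sqrt(v)),

with a global scale sigma^2, relative per-trait rates v_k constrained to
mean 1, and a trait correlation matrix R.  Branch rates carry an
uncorrelated exponential (UCED) or mean-one gamma (UCG) relaxed-clock
prior; R carries a uniform (LKJ eta=1) prior sampled through a
partial-correlation (vine) parameterisation that keeps every proposal a
valid correlation matrix.  Inference is blockwise Metropolis-Hastings;
posteriors are summarised by means and 95% highest-posterior-density
(HPD) intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

LOG_2PI = math.log(2.0 * math.pi)


class TreeError(ValueError):
    """Invalid phylogeny for this model (polytomy, missing lengths...)."""


class NotPositiveDefiniteError(ValueError):
    def __init__(self, name: str, smallest_eig: float):
        super().__init__(
            f"matrix {name} is not positive definite "
            f"(smallest eigenvalue {smallest_eig:.3e})"
        )
        self.name = name
        self.smallest_eig = smallest_eig


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted binary tree with positive branch lengths (relative time).

    ``branch_lengths[b]`` and the boolean incidence matrix
    ``tip_branch[i, b]`` (True when branch b lies on the root-to-tip path
    of tip i) are derived once from the dendropy tree; the root (seed)
    edge is excluded, so a binary tree with n tips has 2n - 2 branches.
    """

    tree: dendropy.Tree
    tip_labels: list[str]
    branch_lengths: np.ndarray
    tip_branch: np.ndarray  # (n_tips, n_branches) bool
    _edges: list = field(default_factory=list, repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            children = node.child_nodes()
            if children and len(children) != 2:
                raise TreeError(
                    f"polytomy (or unary node) at node "
                    f"{node.taxon.label if node.taxon else node.bipartition or '<internal>'}: "
                    f"{len(children)} children; a rooted binary tree is required"
                )
            if not children and (node.taxon is None or not node.taxon.label):
                raise TreeError("unlabeled tip in tree")
        edges = []
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue  # seed edge does not separate any tips
            if edge.length is None:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "<internal>"
                raise TreeError(f"missing branch length above node {name}")
            if not edge.length > 0:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "<internal>"
                raise TreeError(f"non-positive branch length above node {name}")
            edges.append(edge)
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        tip_index = {label: i for i, label in enumerate(tips)}
        lengths = np.array([e.length for e in edges], dtype=float)
        incidence = np.zeros((len(tips), len(edges)), dtype=bool)
        for b, edge in enumerate(edges):
            for leaf in edge.head_node.leaf_iter():
                incidence[tip_index[leaf.taxon.label], b] = True
        return cls(
            tree=tree,
            tip_labels=tips,
            branch_lengths=lengths,
            tip_branch=incidence,
            _edges=edges,
        )

    def to_newick(self, branch_annotations: np.ndarray | None = None) -> str:
        """Newick string; optional per-branch ``[&rate=...]`` annotations."""
        ann = {}
        if branch_annotations is not None:
            if len(branch_annotations) != self.n_branches:
                raise ValueError("one annotation per branch required")
            ann = {id(e): branch_annotations[b] for b, e in enumerate(self._edges)}

        def rec(node):
            children = node.child_nodes()
            if not children:
                label = node.taxon.label
            else:
                label = f"({','.join(rec(c) for c in children)})"
            edge = node.edge
            if edge.head_node is self.tree.seed_node or edge.length is None:
                return label
            suffix = f":{edge.length:.10g}"
            if id(edge) in ann:
                suffix += f"[&rate={ann[id(edge)]:.4g}]"
            return label + suffix

        return rec(self.tree.seed_node) + ";"


def read_newick(source) -> Phylogeny:
    """Read a rooted binary Newick tree from a path or string."""
    text = str(source)
    if "(" in text:  # newick data, not a filesystem path
        tree = dendropy.Tree.get(data=text, schema="newick")
    else:
        tree = dendropy.Tree.get(path=text, schema="newick")
    tree.is_rooted = True
    return Phylogeny.from_dendropy(tree)


def phylo_covariance(tree: Phylogeny, branch_rates: np.ndarray) -> np.ndarray:
    """Tip covariance C[i,j] = sum of r_b * t_b over shared branches."""
    branch_rates = np.asarray(branch_rates, dtype=float)
    if branch_rates.shape != (tree.n_branches,):
        raise ValueError(
            f"expected {tree.n_branches} branch rates, got {branch_rates.shape}"
        )
    B = tree.tip_branch.astype(float)
    return (B * (branch_rates * tree.branch_lengths)) @ B.T


# ---------------------------------------------------------------------------
# traits and transform
# ---------------------------------------------------------------------------

def log_transform_traits(
    traits: pd.DataFrame, offset: dict | float | None = None
) -> tuple[pd.DataFrame, dict]:
    """Z = ln(value + delta) per trait.

    Brownian changes are additive, so raw positive traits are
    log-transformed.  ``offset`` (delta) handles zeros: by default each
    trait containing a zero gets delta = half its smallest positive
    value; traits without zeros get delta = 0.
    """
    deltas = {}
    Z = {}
    for col in traits.columns:
        x = traits[col].to_numpy(float)
        if np.any(x < 0):
            raise ValueError(f"trait {col!r} has negative values")
        if offset is None:
            if np.any(x == 0):
                positive = x[x > 0]
                if positive.size == 0:
                    raise ValueError(f"trait {col!r} is identically zero")
                delta = float(positive.min() / 2)
            else:
                delta = 0.0
        elif isinstance(offset, dict):
            delta = float(offset.get(col, 0.0))
        else:
            delta = float(offset)
        deltas[col] = delta
        Z[col] = np.log(x + delta)
    out = pd.DataFrame(Z, index=traits.index)
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("log-transform produced non-finite values; check offsets")
    return out, deltas


def align_traits_to_tree(Z: pd.DataFrame, tree: Phylogeny) -> np.ndarray:
    missing = set(tree.tip_labels) - set(Z.index)
    extra = set(Z.index) - set(tree.tip_labels)
    if missing or extra:
        raise ValueError(
            f"trait rows and tree tips disagree (missing {sorted(missing)}, "
            f"extra {sorted(extra)})"
        )
    return Z.loc[tree.tip_labels].to_numpy(float)


# ---------------------------------------------------------------------------
# model parameters, likelihood, priors
# ---------------------------------------------------------------------------

@dataclass
class BMParameters:
    """Parameters of the relaxed-clock multivariate Brownian model."""

    branch_rates: np.ndarray  # (n_branches,), > 0
    relative_trait_rates: np.ndarray  # (k,), > 0, mean 1 (variance scale)
    global_scale: float  # sigma^2 > 0
    correlation: np.ndarray  # (k, k) correlation matrix
    root_state: np.ndarray  # (k,)

    def trait_covariance(self) -> np.ndarray:
        s = np.sqrt(self.relative_trait_rates)
        return self.global_scale * (s[:, None] * self.correlation * s[None, :])


def _chol_or_raise(mat: np.ndarray, name: str):
    try:
        return cho_factor(mat, lower=True)
    except np.linalg.LinAlgError:
        eig = float(np.linalg.eigvalsh(mat).min())
        raise NotPositiveDefiniteError(name, eig) from None


def log_likelihood(Z: np.ndarray, tree: Phylogeny, params: BMParameters) -> float:
    """Matrix-normal log density of tip traits Z (n x k).

    log p = -(nk/2) ln 2pi - (k/2) ln|C| - (n/2) ln|Sigma|
            - tr(Sigma^-1 (Z - 1 mu^T)^T C^-1 (Z - 1 mu^T)) / 2
    """
    Z = np.asarray(Z, dtype=float)
    n, k = Z.shape
    C = phylo_covariance(tree, params.branch_rates)
    Sigma = params.trait_covariance()
    Cfac = _chol_or_raise(C, "C (phylogenetic covariance)")
    Sfac = _chol_or_raise(Sigma, "Sigma (trait covariance)")
    logdet_C = 2.0 * np.sum(np.log(np.diag(Cfac[0])))
    logdet_S = 2.0 * np.sum(np.log(np.diag(Sfac[0])))
    A = Z - params.root_state[None, :]
    M = A.T @ cho_solve(Cfac, A)
    quad = float(np.trace(cho_solve(Sfac, M)))
    return float(
        -0.5 * n * k * LOG_2PI - 0.5 * k * logdet_C - 0.5 * n * logdet_S - 0.5 * quad
    )


@dataclass
class PriorConfig:
    """Prior specification for the Brownian MCMC.

    ``family`` selects the relaxed clock: "uced" draws each branch rate
    i.i.d. Exponential(rate_lambda); "ucg" draws Gamma(gamma_alpha,
    gamma_alpha) with mean 1.  The global scale is Lognormal(0, 1),
    relative trait rates are uniform on the mean-1 simplex (Dirichlet(1)
    scaled by k), the correlation matrix is LKJ(eta=1) (uniform), and the
    root state is Normal(root_mean, root_sd) per trait (defaults: the
    per-trait data mean and 10 x data s.d.).
    """

    family: str = "uced"
    rate_lambda: float = 10.0
    gamma_alpha: float = 2.0
    root_mean: np.ndarray | None = None
    root_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in ("uced", "ucg"):
            raise ValueError("prior family must be 'uced' or 'ucg'")
        if self.family == "uced" and not self.rate_lambda > 0:
            raise ValueError("rate_lambda must be positive")
        if self.family == "ucg" and not self.gamma_alpha > 0:
            raise ValueError("gamma_alpha must be positive")

    def with_data_defaults(self, Z: np.ndarray) -> "PriorConfig":
        root_mean = self.root_mean
        root_sd = self.root_sd
        if root_mean is None:
            root_mean = Z.mean(axis=0)
        if root_sd is None:
            sd = Z.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            root_sd = 10.0 * sd
        return replace(self, root_mean=np.asarray(root_mean, float),
                       root_sd=np.asarray(root_sd, float))

    def log_branch_rate_prior(self, rates: np.ndarray) -> float:
        if np.any(rates <= 0):
            return -np.inf
        if self.family == "uced":
            lam = self.rate_lambda
            return float(rates.size * math.log(lam) - lam * rates.sum())
        a = self.gamma_alpha
        return float(
            rates.size * (a * math.log(a) - gammaln(a))
            + (a - 1) * np.log(rates).sum()
            - a * rates.sum()
        )


def log_prior(params: BMParameters, config: PriorConfig) -> float:
    """Joint log prior density of the model parameters.

    The LKJ(1) correlation prior is flat over correlation matrices, so R
    contributes 0 (its dimension-dependent normaliser is omitted, as only
    prior differences matter for inference).
    """
    k = params.relative_trait_rates.size
    lp = config.log_branch_rate_prior(np.asarray(params.branch_rates, float))
    v = np.asarray(params.relative_trait_rates, float)
    if np.any(v <= 0) or abs(v.mean() - 1.0) > 1e-6:
        return -np.inf
    # v / k ~ Dirichlet(1, ..., 1): constant density on the mean-1 simplex
    lp += float(gammaln(k) - (k - 1) * math.log(k))
    s2 = params.global_scale
    if not s2 > 0:
        return -np.inf
    ls = math.log(s2)
    lp += -ls - 0.5 * ls * ls - 0.5 * LOG_2PI  # Lognormal(0, 1)
    mu = np.asarray(params.root_state, float)
    rm = np.asarray(config.root_mean, float)
    rs = np.asarray(config.root_sd, float)
    lp += float(
        np.sum(-0.5 * LOG_2PI - np.log(rs) - 0.5 * ((mu - rm) / rs) ** 2)
    )
    return float(lp)


# ---------------------------------------------------------------------------
# vine (partial-correlation) parameterisation of R
# ---------------------------------------------------------------------------

def _vine_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k - 1) for j in range(i + 1, k)]


def gamma_to_correlation(gamma: np.ndarray, k: int) -> np.ndarray:
    """Map unconstrained vine coordinates to a correlation matrix.

    ``gamma`` holds one real number per pair (i < j); tanh maps each to a
    partial correlation, and the C-vine recursion assembles a valid
    (positive-definite) correlation matrix for any input.
    """
    pairs = _vine_pairs(k)
    if gamma.shape != (len(pairs),):
        raise ValueError(f"expected {len(pairs)} vine coordinates")
    P = np.zeros((k, k))
    for g, (i, j) in zip(np.tanh(gamma), pairs):
        P[i, j] = g
    R = np.eye(k)
    for i in range(k - 1):
        for j in range(i + 1, k):
            rho = P[i, j]
            for l in range(i - 1, -1, -1):
                rho = rho * math.sqrt((1 - P[l, j] ** 2) * (1 - P[l, i] ** 2)) \
                    + P[l, i] * P[l, j]
            R[i, j] = R[j, i] = rho
    return R


def log_vine_density(gamma: np.ndarray, k: int, eta: float = 1.0) -> float:
    """Log density in gamma-space whose pushforward over R is LKJ(eta).

    Partial correlations of layer l = j - i are independent
    Beta(b, b) on (-1, 1) with b = eta + (k - 1 - l) / 2; the tanh
    Jacobian d p / d gamma = 1 - p^2 is included.
    """
    pairs = _vine_pairs(k)
    p = np.tanh(gamma)
    lp = 0.0
    for pc, (i, j) in zip(p, pairs):
        b = eta + (k - 1 - (j - i)) / 2.0
        log_beta_norm = gammaln(2 * b) - 2 * gammaln(b) - (2 * b - 1) * math.log(2.0)
        lp += log_beta_norm + (b - 1) * math.log1p(-pc * pc)
        lp += math.log1p(-pc * pc)  # Jacobian of tanh
    return float(lp)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Sampler settings.  ``iterations`` counts full block sweeps."""

    iterations: int = 4000
    burnin_frac: float = 0.25
    thin: int = 5
    chains: int = 2
    seed: int = 0
    likelihood: bool = True  # False -> prior-only run
    adapt: bool = True
    ess_floor: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.burnin_frac < 1):
            raise ValueError("burnin_frac must be in [0, 1)")
        if self.iterations <= int(self.iterations * self.burnin_frac):
            raise ValueError("iterations must exceed burn-in")


@dataclass
class BMPosterior:
    """Posterior samples (all chains concatenated) and diagnostics."""

    branch_rates: np.ndarray  # (m, n_branches)
    relative_trait_rates: np.ndarray  # (m, k)
    global_scale: np.ndarray  # (m,)
    correlation: np.ndarray  # (m, k, k)
    root_state: np.ndarray  # (m, k)
    log_posterior: np.ndarray  # (m,)
    chain: np.ndarray  # (m,) chain index
    trait_names: list[str]
    acceptance: dict
    ess: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.global_scale)


class _ModelState:
    """Mutable sampler state with cached likelihood factorisations."""

    __slots__ = (
        "rates", "v", "sigma2", "gamma", "mu", "R",
        "Cfac", "logdet_C", "A", "M", "Sinv", "logdet_S",
        "tree", "Z", "n", "k", "weighted_B",
    )

    def __init__(self, tree, Z, rates, v, sigma2, gamma, mu):
        self.tree = tree
        self.Z = Z
        self.n, self.k = Z.shape
        self.rates = rates
        self.v = v
        self.sigma2 = sigma2
        self.gamma = gamma
        self.mu = mu
        self.refresh_C()
        self.refresh_mu()
        self.refresh_Sigma()

    def refresh_C(self) -> bool:
        B = self.tree.tip_branch
        w = self.rates * self.tree.branch_lengths
        C = (B * w) @ B.T
        try:
            self.Cfac = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return False
        self.logdet_C = 2.0 * np.sum(np.log(np.diag(self.Cfac[0])))
        return True

    def refresh_mu(self) -> None:
        self.A = self.Z - self.mu[None, :]
        self.M = self.A.T @ cho_solve(self.Cfac, self.A)

    def refresh_Sigma(self) -> bool:
        self.R = gamma_to_correlation(self.gamma, self.k)
        s = np.sqrt(self.v)
        Sigma = self.sigma2 * (s[:, None] * self.R * s[None, :])
        try:
            fac = cho_factor(Sigma, lower=True)
        except np.linalg.LinAlgError:
            return False
        self.logdet_S = 2.0 * np.sum(np.log(np.diag(fac[0])))
        self.Sinv = cho_solve(fac, np.eye(self.k))
        return True

    def loglik(self) -> float:
        quad = float(np.sum(self.Sinv * self.M))
        return (
            -0.5 * self.n * self.k * LOG_2PI
            - 0.5 * self.k * self.logdet_C
            - 0.5 * self.n * self.logdet_S
            - 0.5 * quad
        )

    def params(self) -> BMParameters:
        return BMParameters(
            branch_rates=self.rates.copy(),
            relative_trait_rates=self.v.copy(),
            global_scale=float(self.sigma2),
            correlation=self.R.copy(),
            root_state=self.mu.copy(),
        )


def _run_single_chain(Z, tree, prior, config, rng, chain_id):
    n, k = Z.shape
    nb = tree.n_branches
    pairs = _vine_pairs(k)
    npairs = len(pairs)

    state = _ModelState(
        tree=tree,
        Z=Z,
        rates=np.ones(nb),
        v=np.ones(k),
        sigma2=float(np.mean(np.var(Z, axis=0, ddof=1)))
        / float(np.mean(np.diag(phylo_covariance(tree, np.ones(nb)))))
        if config.likelihood
        else 1.0,
        gamma=np.zeros(npairs),
        mu=Z.mean(axis=0),
    )
    use_lik = config.likelihood

    def loglik():
        return state.loglik() if use_lik else 0.0

    def log_prior_parts():
        lp = prior.log_branch_rate_prior(state.rates)
        ls = math.log(state.sigma2)
        lp += -ls - 0.5 * ls * ls
        lp += log_vine_density(state.gamma, k)
        lp += float(
            np.sum(-0.5 * ((state.mu - prior.root_mean) / prior.root_sd) ** 2
                   - np.log(prior.root_sd))
        )
        return lp

    cur_ll = loglik()
    if not np.isfinite(cur_ll + log_prior_parts()):
        raise RuntimeError(
            "non-finite posterior at initialization; jitter the starting "
            "values or rescale the traits"
        )

    scales = {"rate": 2.0, "sigma2": 1.2, "v": 0.25, "gamma": 0.8, "mu": 0.5}
    accept = {key: 0 for key in scales}
    tries = {key: 0 for key in scales}
    window_accept = {key: 0 for key in scales}
    window_tries = {key: 0 for key in scales}

    burnin = int(config.iterations * config.burnin_frac)
    keep_every = max(1, config.thin)
    samples = {
        "rates": [], "v": [], "sigma2": [], "R": [], "mu": [], "lp": [],
    }

    for it in range(config.iterations):
        # --- branch rates: multiplicative random walk, one branch at a time
        for b in range(nb):
            tries["rate"] += 1
            window_tries["rate"] += 1
            old = state.rates[b]
            factor = math.exp(scales["rate"] * (rng.random() - 0.5))
            new = old * factor
            d_prior = (
                prior.log_branch_rate_prior(np.array([new]))
                - prior.log_branch_rate_prior(np.array([old]))
            )
            if use_lik:
                old_fac, old_ld, old_M = state.Cfac, state.logdet_C, state.M
                old_ll = cur_ll
                state.rates[b] = new
                if not state.refresh_C():
                    state.rates[b] = old
                    state.Cfac, state.logdet_C, state.M = old_fac, old_ld, old_M
                    continue
                state.M = state.A.T @ cho_solve(state.Cfac, state.A)
                new_ll = state.loglik()
                logr = new_ll - old_ll + d_prior + math.log(factor)
                if math.log(rng.random()) < logr:
                    cur_ll = new_ll
                    accept["rate"] += 1
                    window_accept["rate"] += 1
                else:
                    state.rates[b] = old
                    state.Cfac, state.logdet_C, state.M = old_fac, old_ld, old_M
            else:
                logr = d_prior + math.log(factor)
                if math.log(rng.random()) < logr:
                    state.rates[b] = new
                    accept["rate"] += 1
                    window_accept["rate"] += 1

        # --- global scale: multiplicative move with closed-form update
        tries["sigma2"] += 1
        window_tries["sigma2"] += 1
        factor = math.exp(scales["sigma2"] * (rng.random() - 0.5))
        new_s2 = state.sigma2 * factor
        ls_old, ls_new = math.log(state.sigma2), math.log(new_s2)
        d_prior = (-ls_new - 0.5 * ls_new**2) - (-ls_old - 0.5 * ls_old**2)
        if use_lik:
            quad = float(np.sum(state.Sinv * state.M))
            d_ll = -0.5 * n * k * math.log(factor) - 0.5 * quad * (
                1.0 / factor - 1.0
            )
        else:
            d_ll = 0.0
        if math.log(rng.random()) < d_ll + d_prior + math.log(factor):
            state.sigma2 = new_s2
            if use_lik:
                state.logdet_S += k * math.log(factor)
                state.Sinv = state.Sinv / factor
                cur_ll += d_ll
            accept["sigma2"] += 1
            window_accept["sigma2"] += 1

        # --- relative trait rates: mass-preserving pair move on the simplex
        if k >= 2:
            tries["v"] += 1
            window_tries["v"] += 1
            i, j = rng.choice(k, size=2, replace=False)
            delta = scales["v"] * rng.standard_normal()
            vi, vj = state.v[i] + delta, state.v[j] - delta
            if vi > 1e-8 and vj > 1e-8:
                old_v = state.v.copy()
                state.v[i], state.v[j] = vi, vj
                if use_lik:
                    old_S = (state.logdet_S, state.Sinv)
                    old_ll = cur_ll
                    if state.refresh_Sigma():
                        new_ll = state.loglik()
                        if math.log(rng.random()) < new_ll - old_ll:
                            cur_ll = new_ll
                            accept["v"] += 1
                            window_accept["v"] += 1
                        else:
                            state.v = old_v
                            state.logdet_S, state.Sinv = old_S
                    else:
                        state.v = old_v
                        state.logdet_S, state.Sinv = old_S
                else:
                    accept["v"] += 1
                    window_accept["v"] += 1

        # --- correlation: random walk on vine coordinates
        for m in range(npairs):
            tries["gamma"] += 1
            window_tries["gamma"] += 1
            old_g = state.gamma[m]
            state.gamma[m] = old_g + scales["gamma"] * rng.standard_normal()
            d_prior = log_vine_density(state.gamma, k) - log_vine_density(
                np.concatenate([state.gamma[:m], [old_g], state.gamma[m + 1:]]), k
            )
            if use_lik:
                old_S = (state.logdet_S, state.Sinv, state.R)
                old_ll = cur_ll
                if state.refresh_Sigma():
                    new_ll = state.loglik()
                    if math.log(rng.random()) < new_ll - old_ll + d_prior:
                        cur_ll = new_ll
                        accept["gamma"] += 1
                        window_accept["gamma"] += 1
                    else:
                        state.gamma[m] = old_g
                        state.logdet_S, state.Sinv, state.R = old_S
                else:
                    state.gamma[m] = old_g
                    state.logdet_S, state.Sinv, state.R = old_S
            else:
                if math.log(rng.random()) < d_prior:
                    accept["gamma"] += 1
                    window_accept["gamma"] += 1
                else:
                    state.gamma[m] = old_g

        # --- root state: Gaussian slide per trait
        for j in range(k):
            tries["mu"] += 1
            window_tries["mu"] += 1
            old_mu = state.mu[j]
            step = scales["mu"] * prior.root_sd[j] / 10.0
            state.mu[j] = old_mu + step * rng.standard_normal()
            d_prior = (
                -0.5 * ((state.mu[j] - prior.root_mean[j]) / prior.root_sd[j]) ** 2
                + 0.5 * ((old_mu - prior.root_mean[j]) / prior.root_sd[j]) ** 2
            )
            if use_lik:
                old_A, old_M = state.A, state.M
                old_ll = cur_ll
                state.refresh_mu()
                new_ll = state.loglik()
                if math.log(rng.random()) < new_ll - old_ll + d_prior:
                    cur_ll = new_ll
                    accept["mu"] += 1
                    window_accept["mu"] += 1
                else:
                    state.mu[j] = old_mu
                    state.A, state.M = old_A, old_M
            else:
                if math.log(rng.random()) < d_prior:
                    accept["mu"] += 1
                    window_accept["mu"] += 1
                else:
                    state.mu[j] = old_mu

        # --- adapt proposal scales toward ~30% acceptance during burn-in
        if config.adapt and it < burnin and (it + 1) % 100 == 0:
            for key in scales:
                if window_tries[key] == 0:
                    continue
                rate = window_accept[key] / window_tries[key]
                scales[key] *= math.exp(0.5 * (rate - 0.30))
                scales[key] = min(max(scales[key], 1e-3), 20.0)
                window_accept[key] = 0
                window_tries[key] = 0

        if it >= burnin and (it - burnin) % keep_every == 0:
            state.R = gamma_to_correlation(state.gamma, k)
            samples["rates"].append(state.rates.copy())
            samples["v"].append(state.v.copy())
            samples["sigma2"].append(state.sigma2)
            samples["R"].append(state.R.copy())
            samples["mu"].append(state.mu.copy())
            samples["lp"].append(cur_ll + log_prior_parts())

    acc = {
        key: (accept[key] / tries[key] if tries[key] else float("nan"))
        for key in scales
    }
    return samples, acc


def run_mcmc(
    Z: np.ndarray | pd.DataFrame,
    tree: Phylogeny,
    config: MCMCConfig,
    prior: PriorConfig | None = None,
) -> BMPosterior:
    """Blockwise Metropolis-Hastings sampler for the Brownian model.

    Blocks per sweep: multiplicative scaling of each branch rate and of
    the global scale, a mass-preserving pair move on the mean-1 relative
    trait rates, random walks on the vine coordinates of R, and Gaussian
    slides on the root state.  Proposal scales adapt toward ~30%
    acceptance during burn-in only.  ``config.likelihood = False`` gives
    a prior-only run (used to validate the sampler against the analytic
    prior moments).
    """
    if isinstance(Z, pd.DataFrame):
        trait_names = list(Z.columns)
        Z = align_traits_to_tree(Z, tree)
    else:
        Z = np.asarray(Z, dtype=float)
        trait_names = [f"trait_{j}" for j in range(Z.shape[1])]
    if Z.shape[0] != tree.n_tips:
        raise ValueError("one trait row per tree tip required")
    prior = (prior or PriorConfig()).with_data_defaults(Z)

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_samples = {"rates": [], "v": [], "sigma2": [], "R": [], "mu": [], "lp": []}
    chain_ids = []
    acceptances = []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        samples, acc = _run_single_chain(Z, tree, prior, config, rng, c)
        m = len(samples["sigma2"])
        chain_ids.extend([c] * m)
        for key in all_samples:
            all_samples[key].extend(samples[key])
        acceptances.append(acc)

    posterior = BMPosterior(
        branch_rates=np.array(all_samples["rates"]),
        relative_trait_rates=np.array(all_samples["v"]),
        global_scale=np.array(all_samples["sigma2"]),
        correlation=np.array(all_samples["R"]),
        root_state=np.array(all_samples["mu"]),
        log_posterior=np.array(all_samples["lp"]),
        chain=np.array(chain_ids),
        trait_names=trait_names,
        acceptance={
            key: float(np.mean([a[key] for a in acceptances]))
            for key in acceptances[0]
        },
        ess={},
    )
    posterior.ess = _effective_sample_sizes(posterior, config)
    floor = config.ess_floor
    low = [name for name, e in posterior.ess.items() if e < floor]
    if low:
        posterior.warnings.append(
            f"ESS below {floor:.0f} for: {', '.join(low)}; consider longer chains"
        )
    return posterior


def _effective_sample_sizes(posterior: BMPosterior, config: MCMCConfig) -> dict:
    import arviz as az

    def per_chain(x):
        chains = [x[posterior.chain == c] for c in np.unique(posterior.chain)]
        m = min(len(c) for c in chains)
        return np.stack([c[:m] for c in chains])

    out = {}
    out["global_scale"] = float(az.ess(per_chain(posterior.global_scale)))
    k = posterior.relative_trait_rates.shape[1]
    for j in range(k):
        name = posterior.trait_names[j]
        out[f"rate[{name}]"] = float(
            az.ess(per_chain(posterior.relative_trait_rates[:, j]))
        )
    for i in range(k - 1):
        for j in range(i + 1, k):
            out[f"corr[{posterior.trait_names[i]},{posterior.trait_names[j]}]"] = float(
                az.ess(per_chain(posterior.correlation[:, i, j]))
            )
    return out


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("hpd_interval needs at least 20 samples")
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    best = int(np.argmin(widths))
    return float(x[best]), float(x[best + m - 1])


@dataclass
class PosteriorSummary:
    annotated_newick: str
    branch_rate_mean: np.ndarray
    trait_rates: pd.DataFrame  # mean, hpd_lo, hpd_hi per trait
    correlation_mean: pd.DataFrame
    correlation_hpd_lo: pd.DataFrame
    correlation_hpd_hi: pd.DataFrame


def summarize_posterior(
    posterior: BMPosterior, tree: Phylogeny, mass: float = 0.95
) -> PosteriorSummary:
    """Posterior means and HPD intervals in exportable form.

    Produces a Newick string annotated with each branch's posterior-mean
    rate, a per-trait table of relative evolutionary rates, and the k x k
    mean / HPD tables of the trait correlations.
    """
    if posterior.n_samples == 0:
        raise ValueError("empty posterior")
    names = posterior.trait_names
    k = len(names)
    branch_mean = posterior.branch_rates.mean(axis=0)
    rows = []
    for j in range(k):
        lo, hi = hpd_interval(posterior.relative_trait_rates[:, j], mass)
        rows.append(
            {
                "trait": names[j],
                "mean": float(posterior.relative_trait_rates[:, j].mean()),
                "hpd_lo": lo,
                "hpd_hi": hi,
            }
        )
    corr_mean = np.eye(k)
    corr_lo = np.eye(k)
    corr_hi = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            draws = posterior.correlation[:, i, j]
            corr_mean[i, j] = corr_mean[j, i] = draws.mean()
            lo, hi = hpd_interval(draws, mass)
            corr_lo[i, j] = corr_lo[j, i] = lo
            corr_hi[i, j] = corr_hi[j, i] = hi
    return PosteriorSummary(
        annotated_newick=tree.to_newick(branch_annotations=branch_mean),
        branch_rate_mean=branch_mean,
        trait_rates=pd.DataFrame(rows).set_index("trait"),
        correlation_mean=pd.DataFrame(corr_mean, index=names, columns=names),
        correlation_hpd_lo=pd.DataFrame(corr_lo, index=names, columns=names),
        correlation_hpd_hi=pd.DataFrame(corr_hi, index=names, columns=names),
    )
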