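"""Phylogenetic comparative methods for continuous traits.

Implements the Brownian-motion (BM) machinery used throughout the
analysis: the species covariance matrix implied by shared branch
lengths, Pagel's λ transform and maximum-likelihood λ estimation with a
likelihood-ratio test against λ = 0, phylogenetic generalised least
squares (PGLS) regression, and ML ancestral states for continuous-trait
mapping.  Trees are :class:`dendropy.Tree` objects, treated as rooted at
their seed node; polytomies are handled natively (equivalent to zero-
length resolution, which leaves the likelihood unchanged).

Model: a trait x evolves by BM with rate σ², so tip values are
multivariate normal, x ~ N(μ·1, σ²·C) with C[i,j] the root-to-MRCA path
length of tips i and j.  Pagel's λ rescales the off-diagonal of C:
λ = 1 is pure BM, λ = 0 removes all phylogenetic covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from camtraits.errors import InsufficientDataError, OrphanTaxonError

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# tree utilities

def _prepare_tree(tree: dendropy.Tree) -> None:
    """Normalise edge lengths (None → 0) and reject negative branches."""
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise ValueError("negative branch length in tree")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bm_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance structure of a rooted tree.

    Returns ``(labels, C)`` with ``C[i, j]`` the root-to-MRCA distance of
    tips i and j and ``C[i, i]`` the root-to-tip distance, in the tree's
    branch-length units.
    """
    _prepare_tree(tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            leafsets[id(node)] = [i]
            C[i, i] = node.root_distance
        else:
            child_sets = [leafsets.pop(id(ch)) for ch in node.child_nodes()]
            d = node.root_distance
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        C[i, child_sets[b]] = d
                        C[np.asarray(child_sets[b]), i] = d
            leafsets[id(node)] = [i for s in child_sets for i in s]
    return labels, C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's λ transform: off-diagonal entries scaled by λ, diagonal kept."""
    if lam < 0:
        raise ValueError("λ must be non-negative")
    V = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(V, np.diag(C))
    return V


def lambda_upper_bound(C: np.ndarray, cap: float = 1.0) -> float:
    """Largest λ keeping every off-diagonal below both tip variances.

    min over pairs of min(C_ii, C_jj)/C_ij, capped (default at the
    ultrametric bound 1.0).  Star trees (all off-diagonals zero) return
    the cap.
    """
    n = C.shape[0]
    d = np.diag(C)
    bound = cap
    for i in range(n):
        for j in range(i + 1, n):
            if C[i, j] > 0:
                bound = min(bound, min(d[i], d[j]) / C[i, j])
    return bound


# ---------------------------------------------------------------------------
# likelihoods

def bm_loglik(
    x: np.ndarray,
    V: np.ndarray,
    mu: float,
    sigma2: float,
    se: np.ndarray | None = None,
) -> float:
    """Log density of x under N(μ·1, σ²·V [+ diag(SE²)]), dense evaluation."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if sigma2 <= 0:
        raise ValueError("σ² must be positive")
    V_tot = sigma2 * np.asarray(V, dtype=float)
    if se is not None:
        V_tot = V_tot + np.diag(np.asarray(se, dtype=float) ** 2)
    try:
        cf = cho_factor(V_tot, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("covariance not positive definite") from exc
    r = x - mu
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    return -0.5 * (n * _LOG_2PI + logdet + quad)


def _lambda_depths(tree: dendropy.Tree, lam: float) -> dict[int, float]:
    """Per-edge λ-transformed branch lengths keyed by child-node id.

    Internal branches scale by λ; each terminal branch is stretched so
    the tip's root-to-tip distance is preserved (diagonal unchanged).
    """
    _prepare_tree(tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    lengths: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        bl = node.edge.length or 0.0
        if node.is_leaf():
            depth = node.root_distance
            lengths[id(node)] = depth - lam * (depth - bl)
        else:
            lengths[id(node)] = lam * bl
    return lengths


def bm_loglik_pruning(
    tree: dendropy.Tree,
    x_by_label: dict[str, float],
    mu: float,
    sigma2: float,
    lam: float = 1.0,
) -> float:
    """BM log-likelihood by Felsenstein's pruning algorithm.

    An independent code path from :func:`bm_loglik`: no covariance
    matrix is formed.  Children of a node are combined pairwise, each
    combination contributing the density of the difference of the two
    partial estimates; the root contributes the density of the final
    estimate around μ.
    """
    lengths = _lambda_depths(tree, lam)
    loglik = 0.0
    state: dict[int, tuple[float, float]] = {}  # node id -> (value, extra var)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = (x_by_label[node.taxon.label], lengths[id(node)])
            continue
        children = node.child_nodes()
        v1, var1 = state.pop(id(children[0]))
        for ch in children[1:]:
            v2, var2 = state.pop(id(ch))
            pooled = var1 + var2
            loglik += -0.5 * (
                _LOG_2PI + np.log(sigma2 * pooled) + (v1 - v2) ** 2 / (sigma2 * pooled)
            )
            v1 = (var2 * v1 + var1 * v2) / pooled
            var1 = var1 * var2 / pooled
        state[id(node)] = (v1, var1 + lengths[id(node)])
    root_val, root_var = state[id(tree.seed_node)]
    loglik += -0.5 * (
        _LOG_2PI + np.log(sigma2 * root_var) + (root_val - mu) ** 2 / (sigma2 * root_var)
    )
    return float(loglik)


# ---------------------------------------------------------------------------
# Pagel's lambda

@dataclass(frozen=True)
class LambdaFit:
    lam: float
    sigma2: float
    mu: float
    loglik: float
    loglik_lambda0: float
    lrt: float
    pvalue: float
    lambda_max: float
    identifiable: bool
    n: int
    used_se: bool


def _gls_profile(x: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """Closed-form GLS μ̂, σ̂² and the resulting log-likelihood."""
    n = x.size
    cf = cho_factor(V, lower=True)
    ones = np.ones(n)
    Vi1 = cho_solve(cf, ones)
    mu = float(ones @ cho_solve(cf, x) / (ones @ Vi1))
    r = x - mu
    sigma2 = float(r @ cho_solve(cf, r) / n)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    loglik = -0.5 * (n * (_LOG_2PI + np.log(sigma2) + 1.0) + logdet)
    return mu, sigma2, loglik


def _se_profile(x: np.ndarray, V: np.ndarray, se: np.ndarray) -> tuple[float, float, float]:
    """Profile over σ² numerically when observation SEs enter the covariance."""
    n = x.size

    def negloglik(log_s2: float) -> float:
        s2 = np.exp(log_s2)
        V_tot = s2 * V + np.diag(se**2)
        cf = cho_factor(V_tot, lower=True)
        ones = np.ones(n)
        mu = float(ones @ cho_solve(cf, x) / (ones @ cho_solve(cf, ones)))
        r = x - mu
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return 0.5 * (n * _LOG_2PI + logdet + float(r @ cho_solve(cf, r)))

    s2_start = max(float(np.var(x)) / max(float(np.mean(np.diag(V))), 1e-12), 1e-12)
    res = optimize.minimize_scalar(
        negloglik,
        bounds=(np.log(s2_start) - 12, np.log(s2_start) + 12),
        method="bounded",
        options={"xatol": 1e-10},
    )
    s2 = float(np.exp(res.x))
    V_tot = s2 * V + np.diag(se**2)
    cf = cho_factor(V_tot, lower=True)
    ones = np.ones(n)
    mu = float(ones @ cho_solve(cf, x) / (ones @ cho_solve(cf, ones)))
    return mu, s2, -float(res.fun)


def fit_lambda(
    x,
    tree: dendropy.Tree,
    use_se: bool = False,
    se=None,
    lambda_cap: float = 1.0,
    n_grid: int = 11,
    boundary_mixture: bool = False,
) -> LambdaFit:
    """Maximum-likelihood Pagel's λ with a χ²(1) likelihood-ratio test vs λ = 0.

    For each λ the root state μ and BM rate σ² are maximised in closed
    form by GLS (numerically when per-species SEs are supplied); λ itself
    by bounded scalar search seeded from a coarse grid, guarding against
    local optima.  On a star tree the likelihood is flat in λ; the fit is
    reported at the lower bound with ``identifiable=False``.

    ``boundary_mixture`` switches the LRT reference distribution from
    plain χ²(1) to the 50:50 point-mass/χ²(1) mixture appropriate for a
    null on the parameter boundary; both remain conservative in practice
    because λ̂ sticks to the boundary in well over half of null samples.
    """
    labels, C = bm_covariance(tree)
    x = np.asarray(x, dtype=float)
    if x.size != len(labels):
        raise ValueError("trait length does not match number of tips")
    if x.size < 4:
        raise InsufficientDataError("λ estimation needs ≥ 4 species")
    if np.var(x) == 0:
        raise ValueError("zero trait variance")
    se_arr = None
    if use_se:
        if se is None:
            raise ValueError("use_se=True requires per-species standard errors")
        se_arr = np.asarray(se, dtype=float)
    lam_max = lambda_upper_bound(C, cap=lambda_cap)
    identifiable = bool(np.max(C - np.diag(np.diag(C))) > 1e-12 * np.max(np.diag(C)))

    def profile(lam: float) -> tuple[float, float, float]:
        V = lambda_transform(C, lam)
        if se_arr is not None:
            return _se_profile(x, V, se_arr)
        return _gls_profile(x, V)

    mu0, s20, ll0 = profile(0.0)
    if not identifiable:
        return LambdaFit(
            lam=0.0, sigma2=s20, mu=mu0, loglik=ll0, loglik_lambda0=ll0,
            lrt=0.0, pvalue=1.0, lambda_max=lam_max, identifiable=False,
            n=x.size, used_se=use_se,
        )

    grid = np.linspace(0.0, lam_max, n_grid)
    grid_ll = np.array([profile(lam)[2] for lam in grid])
    best = int(np.argmax(grid_ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda lam: -profile(lam)[2],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    cand = [(grid[best], grid_ll[best]), (float(res.x), -float(res.fun))]
    lam_hat, ll_hat = max(cand, key=lambda t: t[1])
    mu_hat, s2_hat, ll_hat = profile(lam_hat)
    ll_hat = max(ll_hat, ll0)  # numerical guard: λ = 0 is nested
    lrt = max(2.0 * (ll_hat - ll0), 0.0)
    if lrt > 0:
        pvalue = float(stats.chi2.sf(lrt, df=1))
        if boundary_mixture:
            pvalue *= 0.5
    else:
        pvalue = 1.0
    return LambdaFit(
        lam=float(lam_hat), sigma2=float(s2_hat), mu=float(mu_hat),
        loglik=float(ll_hat), loglik_lambda0=float(ll0), lrt=float(lrt),
        pvalue=pvalue, lambda_max=float(lam_max), identifiable=True,
        n=x.size, used_se=use_se,
    )


# ---------------------------------------------------------------------------
# PGLS

@dataclass(frozen=True)
class PGLSFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    loglik: float
    structure: str  # "bm" | "lambda" | "identity"
    lambda_used: float | None
    n: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.t, "p": self.p},
            index=list(self.names),
        )


def _gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    cf = cho_factor(V, lower=True)
    XtVi = cho_solve(cf, X).T
    XtViX = XtVi @ X
    beta = np.linalg.solve(XtViX, XtVi @ y)
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = y.size
    sigma2_ml = rss / n
    loglik = -0.5 * (n * (_LOG_2PI + np.log(sigma2_ml) + 1.0) + logdet)
    cov_unscaled = np.linalg.inv(XtViX)
    return beta, rss, loglik, cov_unscaled


def pgls(
    y,
    X,
    tree: dendropy.Tree,
    structure: str = "lambda",
    names: tuple[str, ...] | None = None,
    add_intercept: bool = True,
    lambda_cap: float = 1.0,
) -> PGLSFit:
    """Phylogenetic generalised least squares regression.

    ``structure`` selects the residual covariance: ``"bm"`` (V = C),
    ``"lambda"`` (V = C(λ) with λ estimated by ML jointly with the
    coefficients) or ``"identity"`` (ordinary least squares, for
    reference).  Rows of ``y`` and ``X`` must align with the tree's tip
    order.  Standard errors are classical GLS with the unbiased residual
    variance; t tests use n − p degrees of freedom.
    """
    labels, C = bm_covariance(tree)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if y.size != len(labels) or X.shape[0] != y.size:
        raise ValueError("y/X rows must align with tree tips")
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
        if names is not None:
            names = ("intercept",) + tuple(names)
    if names is None:
        names = tuple(
            ["intercept"] * add_intercept + [f"x{i}" for i in range(X.shape[1] - add_intercept)]
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    lam_used: float | None = None
    if structure == "identity":
        V = np.eye(y.size)
    elif structure == "bm":
        V = C.copy()
        lam_used = 1.0
    elif structure == "lambda":
        lam_max = lambda_upper_bound(C, cap=lambda_cap)

        def negloglik(lam: float) -> float:
            return -_gls_fit(y, X, lambda_transform(C, lam))[2]

        grid = np.linspace(0.0, lam_max, 11)
        ll = np.array([-negloglik(lam) for lam in grid])
        best = int(np.argmax(ll))
        res = optimize.minimize_scalar(
            negloglik,
            bounds=(grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_used = float(res.x) if -res.fun >= ll[best] else float(grid[best])
        V = lambda_transform(C, lam_used)
    else:
        raise ValueError(f"unknown structure {structure!r}")

    beta, rss, loglik, cov_unscaled = _gls_fit(y, X, V)
    n, p = y.size, X.shape[1]
    if n <= p:
        raise InsufficientDataError("PGLS needs n > number of coefficients")
    sigma2 = rss / (n - p)
    se_beta = np.sqrt(sigma2 * np.diag(cov_unscaled))
    tvals = beta / se_beta
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    return PGLSFit(
        names=tuple(names), coef=beta, se=se_beta, t=tvals, p=pvals,
        sigma2=float(sigma2), loglik=float(loglik), structure=structure,
        lambda_used=lam_used, n=n,
    )


# ---------------------------------------------------------------------------
# ancestral states

@dataclass(frozen=True)
class AncestralStates:
    node_labels: tuple[str, ...]
    states: np.ndarray
    variances: np.ndarray
    root_state: float
    sigma2: float
    table: pd.DataFrame


def ancestral_states(x, tree: dendropy.Tree) -> AncestralStates:
    """Maximum-likelihood ancestral states under Brownian motion.

    For each internal node the conditional expectation given the tip
    data is computed by GLS:  â = μ̂ + c V⁻¹ (x − μ̂1) with c the vector
    of shared path lengths between the node and every tip.  The reported
    variance includes the uncertainty of the GLS root estimate μ̂.  The
    root state equals μ̂ by construction.
    """
    labels, C = bm_covariance(tree)
    x = np.asarray(x, dtype=float)
    if x.size != len(labels):
        raise ValueError("trait length does not match number of tips")
    if np.var(x) == 0:
        mu = float(x[0])
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        nlab = tuple(_node_label(nd, i) for i, nd in enumerate(internals))
        states = np.full(len(internals), mu)
        variances = np.zeros(len(internals))
        table = pd.DataFrame({"node": nlab, "state": states, "variance": variances})
        return AncestralStates(nlab, states, variances, mu, 0.0, table)

    mu, sigma2, _ = _gls_profile(x, C)
    cf = cho_factor(C, lower=True)
    ones = np.ones(x.size)
    Vi1 = cho_solve(cf, ones)
    denom_mu = float(ones @ Vi1)
    resid = x - mu
    Vir = cho_solve(cf, resid)

    # leaf index sets and depths per node
    leaves = list(tree.leaf_node_iter())
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    leafset: dict[int, frozenset[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[id(node)] = frozenset([index[id(node)]])
        else:
            leafset[id(node)] = frozenset().union(
                *(leafset[id(ch)] for ch in node.child_nodes())
            )

    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    node_labels, states, variances = [], [], []
    for i, node in enumerate(internals):
        c = np.empty(x.size)
        # tips below the node share its full depth; for the rest walk up
        # to the first ancestor containing the tip
        for j in range(x.size):
            if j in leafset[id(node)]:
                c[j] = node.root_distance
            else:
                anc = node.parent_node
                while j not in leafset[id(anc)]:
                    anc = anc.parent_node
                c[j] = anc.root_distance
        state = mu + float(c @ Vir)
        Vic = cho_solve(cf, c)
        var = sigma2 * (
            node.root_distance
            - float(c @ Vic)
            + (1.0 - float(ones @ Vic)) ** 2 / denom_mu
        )
        node_labels.append(_node_label(node, i))
        states.append(state)
        variances.append(max(var, 0.0))
    states_arr = np.asarray(states)
    variances_arr = np.asarray(variances)
    table = pd.DataFrame(
        {"node": node_labels, "state": states_arr, "variance": variances_arr}
    )
    return AncestralStates(
        tuple(node_labels), states_arr, variances_arr, mu, float(sigma2), table
    )


def _node_label(node: dendropy.Node, i: int) -> str:
    if node.label:
        return str(node.label)
    return "root" if node.parent_node is None else f"node{i}"


# ---------------------------------------------------------------------------
# pruning / lumping

def prune_and_lump(
    tree: dendropy.Tree,
    trait_table: pd.DataFrame,
    lump_map: dict[str, str] | None = None,
    taxon_col: str = "taxon",
    value_col: str = "value",
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Align replicate-level trait data with a tree, pooling lumped taxa.

    ``lump_map`` maps data-taxon names onto tree-tip labels (for taxa
    absent from the tree, e.g. subspecies pooled into one tip).  Tips
    without data are pruned; data taxa with neither a matching tip nor a
    lump rule raise :class:`OrphanTaxonError` listing every orphan.
    Replicate values are pooled per tip before the species mean, SD, SE
    and n are computed.  The returned table rows follow the pruned
    tree's tip order.
    """
    lump_map = lump_map or {}
    tree = tree.clone(depth=1)
    tip_labels = set(leaf_labels(tree))
    data = trait_table[[taxon_col, value_col]].dropna().copy()
    data["tip"] = data[taxon_col].map(lambda t: lump_map.get(t, t))
    orphans = sorted(set(data["tip"]) - tip_labels)
    if orphans:
        raise OrphanTaxonError(
            f"data taxa with no tree tip and no lump rule: {orphans}"
        )
    keep = sorted(set(data["tip"]))
    if len(keep) < len(tip_labels):
        tree.retain_taxa_with_labels(keep)
    agg = data.groupby("tip")[value_col].agg(["mean", "std", "count"])
    agg["se"] = agg["std"] / np.sqrt(agg["count"])
    order = leaf_labels(tree)
    out = agg.reindex(order).reset_index(names=taxon_col)
    out = out.rename(columns={"count": "n"})
    return tree, out[[taxon_col, "mean", "std", "se", "n"]]
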