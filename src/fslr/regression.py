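"""Logistic logic-regression layer.

The model is ``g(E[P]) = beta0 + sum_i beta_i * L_i(h)`` where the L_i are
logic trees evaluated on a binary genotype, g is the logistic (sigmoid)
link, and P is the binary case-control phenotype.  Coefficients are fitted
as MAP estimates under a zero-mean normal prior with variance ``v``
(ridge-penalized logistic regression solved by Newton/IRLS).

Also here: the model score (number of correctly predicted individuals), the
size-penalizing model prior in factorized form, the acceptance probability
for worse-scoring proposals, and stepwise elimination of insignificant SNP
leaves by partial F statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .logic_tree import LogicTree, del_snp, to_infix


@dataclass(frozen=True)
class Dataset:
    """Binary genotype matrix (M x N) and binary phenotype vector (M)."""

    genotypes: np.ndarray
    phenotypes: np.ndarray
    snp_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        p = np.asarray(self.phenotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if p.shape != (g.shape[0],):
            raise ValueError(
                f"phenotype length {p.shape} does not match M={g.shape[0]}"
            )
        if g.size and (g.min() < 0 or g.max() > 1):
            raise ValueError("genotype entries must be 0/1")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("phenotype entries must be 0/1")
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "phenotypes", p)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class RegressionModel:
    """k logic trees with logistic coefficients (beta0 + per-tree betas)."""

    trees: tuple[LogicTree, ...]
    beta0: float = 0.0
    betas: tuple[float, ...] = ()
    ridge_stabilized: bool = False  # set when the fit needed extra damping

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise ValueError("model requires at least one tree")
        if self.betas and len(self.betas) != len(self.trees):
            raise ValueError("betas length must equal number of trees")

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def model_size(self) -> int:
        """Total number of SNP leaves s over all trees."""
        return sum(t.size for t in self.trees)

    @property
    def fitted(self) -> bool:
        return len(self.betas) == len(self.trees)

    def snps(self) -> list[int]:
        out: list[int] = []
        for t in self.trees:
            out.extend(t.snps())
        return out

    def distinct_snps(self) -> set[int]:
        return set(self.snps())

    def design(self, genotypes: np.ndarray) -> np.ndarray:
        """M x (k+1) design: intercept column then one column per tree."""
        genotypes = np.asarray(genotypes)
        cols = [np.ones(genotypes.shape[:-1], dtype=np.float64)]
        cols.extend(t.evaluate(genotypes).astype(np.float64) for t in self.trees)
        return np.stack(cols, axis=-1)

    def linear_predictor(self, genotypes: np.ndarray) -> np.ndarray:
        eta = np.full(np.asarray(genotypes).shape[:-1], self.beta0, dtype=float)
        for b, t in zip(self.betas, self.trees):
            eta = eta + b * t.evaluate(genotypes)
        return eta

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        """Case probability g(beta0 + sum beta_i L_i) in (0, 1)."""
        if not self.fitted:
            raise ValueError("model is not fitted")
        return _sigmoid(self.linear_predictor(genotypes))

    def classify(self, genotypes: np.ndarray) -> np.ndarray:
        """Predicted phenotype: probability >= 0.5 -> case (1)."""
        return (self.predict(genotypes) >= 0.5).astype(np.int8)

    def describe(self) -> str:
        return " + ".join(to_infix(t) for t in self.trees)


def single_tree_model(tree: LogicTree) -> RegressionModel:
    return RegressionModel(trees=(tree,))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    # clipping at |eta|=35 saturates beyond double precision of the result
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_tree(tree: LogicTree, data: Dataset) -> int:
    """Explanations of a bare Boolean expression: #{i : L(h_i) == P_i}."""
    if data.n_individuals == 0:
        raise ValueError("empty dataset")
    return int(np.sum(tree.evaluate(data.genotypes) == data.phenotypes))


def score(model: RegressionModel, data: Dataset) -> int:
    """Number of individuals whose predicted phenotype equals the observed.

    The prediction threshold is 0.5 (the sigmoid midpoint); for a bare
    single-tree model use :func:`score_tree`.
    """
    if data.n_individuals == 0:
        raise ValueError("empty dataset")
    return int(np.sum(model.classify(data.genotypes) == data.phenotypes))


# ---------------------------------------------------------------------------
# Coefficient estimation (MAP ridge-logistic via Newton/IRLS)
# ---------------------------------------------------------------------------

def _irls(
    X: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 50, tol: float = 1e-9
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS for the ridge-penalized logistic log-likelihood."""
    p = X.shape[1]
    beta = np.zeros(p)
    eye = lam * np.eye(p)
    stabilized = False
    for _ in range(max_iter):
        mu = _sigmoid(X @ beta)
        grad = X.T @ (y - mu) - lam * beta
        H = (X.T * (mu * (1.0 - mu))) @ X + eye
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            stabilized = True
            step = np.linalg.solve(H + 1e-6 * np.eye(p), grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if not np.all(np.isfinite(beta)):  # pathological separation fallback
        stabilized = True
        beta = np.zeros(p)
    return beta, stabilized


def fit_betas(
    model: RegressionModel,
    data: Dataset,
    v: float = 10.0,
    rows: np.ndarray | None = None,
) -> RegressionModel:
    """MAP logistic coefficients under a N(0, v) prior on every coefficient.

    ``rows`` restricts the fit to a subset (e.g. a bootstrap sample).
    Deterministic given data and v.  A singular or separated design is
    stabilized by extra ridge damping and flagged on the returned model.
    """
    g = data.genotypes if rows is None else data.genotypes[rows]
    y = (data.phenotypes if rows is None else data.phenotypes[rows]).astype(float)
    X = model.design(g)
    beta, stabilized = _irls(X, y, 1.0 / v)
    return replace(
        model,
        beta0=float(beta[0]),
        betas=tuple(float(b) for b in beta[1:]),
        ridge_stabilized=stabilized,
    )


def fit_assess_arrays(
    model: RegressionModel,
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    v: float = 10.0,
) -> tuple[RegressionModel, int, "AcceptanceParams"]:
    """Fit on (genotypes, phenotypes) and return (fitted model, score,
    acceptance parameters) sharing a single design evaluation — the swarm's
    hot path."""
    y = phenotypes.astype(float)
    X = model.design(genotypes)
    beta, stabilized = _irls(X, y, 1.0 / v)
    fitted = replace(
        model,
        beta0=float(beta[0]),
        betas=tuple(float(b) for b in beta[1:]),
        ridge_stabilized=stabilized,
    )
    pred = (X @ beta) >= 0.0  # sigmoid(eta) >= 0.5  <=>  eta >= 0
    sc = int(np.sum(pred == (y == 1.0)))
    params = _acceptance_params_from_design(X, y, model.k, v)
    return fitted, sc, params


def fit_and_assess(
    model: RegressionModel, data: Dataset, v: float = 10.0
) -> tuple[RegressionModel, int, "AcceptanceParams"]:
    return fit_assess_arrays(model, data.genotypes, data.phenotypes, v)


def canonicalize_signs(model: RegressionModel) -> RegressionModel:
    """Rewrite every tree with a negative coefficient as its De Morgan
    complement with a positive coefficient (absorbing the shift into the
    intercept), so reported trees read as positive-risk expressions.  The
    predictor is unchanged: beta * L = beta + (-beta) * (1 - L)."""
    from .logic_tree import complement

    if not model.fitted:
        return model
    trees = list(model.trees)
    betas = list(model.betas)
    beta0 = model.beta0
    for i, b in enumerate(betas):
        if b < 0:
            trees[i] = complement(trees[i])
            beta0 += b
            betas[i] = -b
    return replace(
        model, trees=tuple(trees), beta0=beta0, betas=tuple(betas)
    )


def model_forest(model: RegressionModel, max_conjunctions: int = 10_000) -> "Forest":
    """AND-only conjunctions of the Boolean classifier the fitted model
    computes.

    A fitted model classifies by thresholding beta0 + sum beta_i L_i, which
    is a Boolean function of the k tree outputs.  That function is expanded
    as a disjunction over its true minterms; each minterm is the conjunction
    of the corresponding trees (or their De Morgan complements), whose
    OR-split forests are multiplied out.  Contradictory conjunctions
    (containing a literal and its negation) are dropped.  This is the
    epistatic-unit view of a model: a pair of SNPs interacts iff it
    co-occurs inside one conjunction.
    """
    from itertools import product as _product

    from .logic_tree import Forest, complement, split_to_forest

    if not model.fitted:
        raise ValueError("model_forest requires a fitted model")
    conjs: list[frozenset] = []
    seen: set[frozenset] = set()
    for bits in _product((0, 1), repeat=model.k):
        eta = model.beta0 + sum(
            b for b, t in zip(model.betas, bits) if t
        )
        if eta < 0:
            continue
        factors = [
            split_to_forest(tree if t else complement(tree)).conjunctions
            for tree, t in zip(model.trees, bits)
        ]
        partial: list[frozenset] = [frozenset()]
        for factor in factors:
            partial = [p | c for p in partial for c in factor]
            if len(partial) > max_conjunctions:
                raise RuntimeError("model forest too large to expand")
        for conj in partial:
            snps_pos = {l.snp_index for l in conj if not l.negated}
            snps_neg = {l.snp_index for l in conj if l.negated}
            if snps_pos & snps_neg:
                continue  # contradictory, evaluates to 0
            if conj not in seen:
                seen.add(conj)
                conjs.append(conj)
    return Forest(tuple(conjs))


# ---------------------------------------------------------------------------
# Model prior (size-penalized, factorized)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Size-penalizing model prior.

    ``alpha`` in (0,1) penalizes large models via alpha^s; the geometric
    size prior is normalized (the theta constant) over the sizes attainable
    with ``n_l`` trees of at most ``s_max`` leaves; the number of trees is
    uniform on {1..n_max}.
    """

    alpha: float = 0.5
    s_max: int = 8
    n_max: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.s_max < 1 or self.n_max < 1:
            raise ValueError("s_max and n_max must be >= 1")

    def log_theta(self, n_l: int) -> float:
        """Log of the normalizer making the size prior sum to 1 over
        s in [n_l, n_l * s_max]."""
        sizes = np.arange(n_l, n_l * self.s_max + 1)
        log_terms = sizes * math.log(self.alpha) + math.log(1 - self.alpha)
        m = log_terms.max()
        return -(m + math.log(np.exp(log_terms - m).sum()))


def _n_compositions(s: int, n_l: int, s_max: int) -> int:
    """Compositions of s into n_l ordered parts, each in [1, s_max]."""
    if n_l == 0:
        return 1 if s == 0 else 0
    table = np.zeros(s + 1, dtype=object)
    table[0] = 1
    for _ in range(n_l):
        new = np.zeros(s + 1, dtype=object)
        for total in range(1, s + 1):
            new[total] = sum(table[total - part] for part in range(1, min(s_max, total) + 1))
        table = new
    return int(table[s])


def model_log_prior(
    model: RegressionModel, prior: PriorConfig, n_snps: int
) -> float:
    """Log prior of a model under the factorized form.

    log p(n_l) + log p(s | n_l) + log p(s_vec | s, n_l)
    + sum_i log p(q_i | s_i), with p(s | n_l) = theta * alpha^s * (1-alpha),
    the size vector uniform over compositions, and p(q_i | s_i) uniform over
    the C(N, s_i) indicator vectors.  Returns -inf for impossible models
    (s > n_l * s_max, any tree larger than s_max, or n_l > n_max).
    """
    n_l = model.k
    s = model.model_size
    if (
        n_l > prior.n_max
        or s > n_l * prior.s_max
        or any(t.size > prior.s_max for t in model.trees)
    ):
        return -math.inf
    lp = -math.log(prior.n_max)  # p(n_l)
    lp += prior.log_theta(n_l) + s * math.log(prior.alpha) + math.log(1 - prior.alpha)
    lp -= math.log(_n_compositions(s, n_l, prior.s_max))
    for t in model.trees:
        lp -= math.log(math.comb(n_snps, t.size))
    return lp


# ---------------------------------------------------------------------------
# Acceptance probability for worse-scoring proposals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcceptanceParams:
    """Sufficient quantities of a model for the acceptance ratio.

    Conjugate Gaussian treatment of the response on the tree-output design:
    V_hat = (Omega' Omega + I/v)^-1, beta_hat = V_hat Omega' y, and the
    error term a = y'y - beta_hat' V_hat^-1 beta_hat measuring residual
    misfit (smaller is better).
    """

    k: int
    log_det_v_hat: float
    error_term: float
    log_v: float


def _acceptance_params_from_design(
    omega: np.ndarray, y: np.ndarray, k: int, v: float
) -> AcceptanceParams:
    p = omega.shape[1]
    precision = omega.T @ omega + np.eye(p) / v
    sign, logdet_prec = np.linalg.slogdet(precision)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance not positive definite")
    beta_hat = np.linalg.solve(precision, omega.T @ y)
    a = float(y @ y - beta_hat @ precision @ beta_hat)
    if not math.isfinite(a):
        raise FloatingPointError("error term is not finite")
    return AcceptanceParams(
        k=k,
        log_det_v_hat=-logdet_prec,
        error_term=a,
        log_v=math.log(v),
    )


def acceptance_params(
    model: RegressionModel, data: Dataset, v: float = 10.0,
    rows: np.ndarray | None = None,
) -> AcceptanceParams:
    g = data.genotypes if rows is None else data.genotypes[rows]
    y = (data.phenotypes if rows is None else data.phenotypes[rows]).astype(float)
    return _acceptance_params_from_design(model.design(g), y, model.k, v)


def acceptance_probability(
    current: AcceptanceParams, proposed: AcceptanceParams
) -> float:
    """Q = min{1, v^{k/2} |V*|^{1/2} / (v^{k*/2} |V|^{1/2}) * exp(a - a*)}.

    Identical models give Q = 1; a better-fitting proposal (smaller error
    term a*) increases Q.  Computed in log space.
    """
    log_q = (
        0.5 * (current.k * current.log_v - proposed.k * proposed.log_v)
        + 0.5 * (proposed.log_det_v_hat - current.log_det_v_hat)
        + (current.error_term - proposed.error_term)
    )
    if log_q >= 0.0:
        return 1.0
    return math.exp(log_q)


# ---------------------------------------------------------------------------
# Stepwise elimination by partial F statistics
# ---------------------------------------------------------------------------

def _linear_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _leaf_positions(model: RegressionModel) -> list[tuple[int, tuple[int, ...]]]:
    out = []
    for ti, tree in enumerate(model.trees):
        for path in tree.leaf_paths():
            out.append((ti, path))
    return out


def _drop_leaf(
    model: RegressionModel, tree_idx: int, path: tuple[int, ...]
) -> RegressionModel | None:
    """Model without one leaf; None when the last leaf would be dropped."""
    tree = model.trees[tree_idx]
    if tree.size == 1:
        trees = model.trees[:tree_idx] + model.trees[tree_idx + 1 :]
    else:
        trees = (
            model.trees[:tree_idx]
            + (del_snp(tree, path),)
            + model.trees[tree_idx + 1 :]
        )
    return RegressionModel(trees=trees) if trees else None


def leaf_f_statistics(
    model: RegressionModel, data: Dataset
) -> list[tuple[int, tuple[int, ...], float]]:
    """Partial F statistic of each SNP leaf.

    F compares the linear regression of the phenotype on the model's tree
    outputs with and without the leaf: F = (RSS_red - RSS_full) /
    (RSS_full / (M - p)).  A leaf whose removal leaves the fit unchanged
    (e.g. a duplicated SNP) has F = 0.
    """
    y = data.phenotypes.astype(float)
    X_full = model.design(data.genotypes)
    rss_full = _linear_rss(X_full, y)
    m, p = X_full.shape
    denom = rss_full / max(m - p, 1)
    stats = []
    for tree_idx, path in _leaf_positions(model):
        reduced = _drop_leaf(model, tree_idx, path)
        if reduced is None:
            X_red = np.ones((m, 1))
        else:
            X_red = reduced.design(data.genotypes)
        delta = max(_linear_rss(X_red, y) - rss_full, 0.0)
        if denom < 1e-12:
            f = 0.0 if delta < 1e-9 else math.inf
        else:
            f = delta / denom
        stats.append((tree_idx, path, f))
    return stats


def stepwise_eliminate(
    model: RegressionModel,
    data: Dataset,
    f_out: float = 4.0,
    v: float = 10.0,
) -> RegressionModel:
    """Greedy backward elimination of SNP leaves with F <= ``f_out``.

    Leaves are removed one at a time (lowest F first, recomputing after each
    removal) so that of two duplicated leaves only one is dropped for free.
    Never returns an empty model: the last surviving leaf is kept even if
    its F is below the threshold.  The pruned model is refitted.
    """
    if model.model_size < 1:
        raise ValueError("model must contain at least one SNP leaf")
    current = RegressionModel(trees=model.trees)
    while current.model_size >= 2:
        stats = leaf_f_statistics(current, data)
        tree_idx, path, f_min = min(stats, key=lambda t: (t[2], t[0], t[1]))
        if f_min > f_out:
            break
        current = _drop_leaf(current, tree_idx, path)
    return fit_betas(current, data, v=v)
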