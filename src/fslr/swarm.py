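"""Fish-swarm search over logic-regression models.

A school of F fish agents each holds a logic-regression model.  Every
iteration the swarm announces the best agent (f_best, highest score on the
full dataset, ties to the lowest agent id); f_best HOLDs while every other
agent picks one of three swarm behaviors:

* RANDOM — one of the four tree moves uniformly (probability 1/4 each);
* FOLLOW — move toward f_best's size and SNPs, steered by the size-density
  f(s) (a normal density centred on s_best, used directly as a probability
  after clamping to [0,1]) and by the per-SNP selection probabilities derived
  from importance;
* KPDIST — keep a distance from f_best (the mirror-image rules).

A proposal that improves the agent's score is always accepted; a worse one
is accepted with the acceptance probability Q computed from the conjugate
Gaussian fit of both models.  Every ``refresh_period`` iterations the
out-of-bag importance V(j) of every SNP is recomputed (each agent's model is
refitted on its bootstrap rows and scored on its out-of-bag rows with and
without SNP j) and each agent's model is pruned by stepwise F elimination.
The run stops once the best score has been stable for B iterations.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

log = logging.getLogger(__name__)

from .config import RunConfig
from .logic_tree import (
    AND,
    OR,
    Leaf,
    LogicTree,
    Move,
    MoveInfeasibleError,
    OpNode,
    SnpLiteral,
    add_snp,
    alt_opt,
    alt_snp,
    del_snp,
    random_tree,
    split_to_forest,
)
from .regression import (
    AcceptanceParams,
    Dataset,
    PriorConfig,
    RegressionModel,
    acceptance_params,
    acceptance_probability,
    canonicalize_signs,
    fit_and_assess,
    fit_assess_arrays,
    fit_betas,
    leaf_f_statistics,
    model_forest,
    model_log_prior,
    score,
    stepwise_eliminate,
)


class Behavior(Enum):
    HOLD = "HOLD"
    RANDOM = "RANDOM"
    FOLLOW = "FOLLOW"
    KPDIST = "KPDIST"


# ---------------------------------------------------------------------------
# Importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    """Per-SNP importance V(j) and derived selection probabilities."""

    values: np.ndarray
    selection_probs: np.ndarray
    refresh_period: int = 10

    @classmethod
    def uniform(cls, n_snps: int, refresh_period: int = 10) -> "ImportanceTable":
        return cls(
            values=np.zeros(n_snps),
            selection_probs=np.full(n_snps, 1.0 / n_snps),
            refresh_period=refresh_period,
        )


def selection_distribution(
    values: np.ndarray, floor: float = 0.5
) -> np.ndarray:
    """P(j) proportional to max(V(j), eps) + eps; every SNP stays reachable."""
    raw = np.maximum(values, floor) + floor
    return raw / raw.sum()


def size_density(s: float, mu: float, sigma2: float) -> float:
    """Normal density centred on s_best, clamped to [0, 1] for use as a
    behavior-mixing probability."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive (apply the floor first)")
    dens = math.exp(-((s - mu) ** 2) / (2.0 * sigma2)) / math.sqrt(
        2.0 * math.pi * sigma2
    )
    return min(1.0, dens)


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

@dataclass
class FishAgent:
    """One search unit: a model, a bootstrap/OOB data split and an
    independent random stream.

    The agent searches on its bootstrap sample (``model`` carries the
    bootstrap-fitted coefficients; proposals are accepted or rejected by the
    bootstrap score), which is what keeps the school diverse.  ``score`` and
    ``full_model`` are the same structure refitted on the full dataset: the
    swarm communicates (f_best announcement, global best, local bests)
    through full-data scores so agents are comparable.
    """

    agent_id: int
    model: RegressionModel
    boot_score: int
    full_model: RegressionModel
    score: int
    bootstrap_indices: np.ndarray
    oob_indices: np.ndarray
    boot_genotypes: np.ndarray
    boot_phenotypes: np.ndarray
    rng: np.random.Generator
    accept_params: AcceptanceParams | None = None
    local_best_model: RegressionModel = None  # type: ignore[assignment]
    local_best_score: int = -1

    def note_if_local_best(self) -> None:
        if self.score > self.local_best_score:
            self.local_best_model = self.full_model
            self.local_best_score = self.score


@dataclass
class SwarmState:
    agents: list[FishAgent]
    importance: ImportanceTable
    iteration: int = 0
    stable_count: int = 0
    best_model: RegressionModel = None  # type: ignore[assignment]
    best_score: int = -1
    announced_best_id: int | None = None

    def _current_best(self) -> FishAgent:
        return max(self.agents, key=lambda a: (a.score, -a.agent_id))

    @property
    def best_agent(self) -> FishAgent:
        """f_best: the agent announced at the start of the iteration (ties
        to lowest id); falls back to the instantaneous best before any
        announcement."""
        if self.announced_best_id is not None:
            return self.agents[self.announced_best_id]
        return self._current_best()

    def announce_best(self) -> FishAgent:
        best = self._current_best()
        self.announced_best_id = best.agent_id
        return best


@dataclass(frozen=True)
class SwarmReport:
    best_model: RegressionModel
    best_score: int
    best_model_pruned: RegressionModel
    agent_models: tuple[RegressionModel, ...]
    agent_scores: tuple[int, ...]
    local_best_models: tuple[RegressionModel, ...]
    local_best_scores: tuple[int, ...]
    importance: np.ndarray
    pair_counts: dict[tuple[int, int], int]
    triple_counts: dict[tuple[int, int, int], int]
    iterations: int
    converged: bool
    seed: int
    config: RunConfig
    best_log_prior: float = float("nan")
    best_f_stats: tuple[tuple[int, float], ...] = ()


def initialize_swarm(
    data: Dataset, config: RunConfig, seed: int
) -> SwarmState:
    """F agents with random initial trees (size ~ U(1, s_max), SNPs uniform)
    and independent bootstrap/OOB splits; deterministic given the seed."""
    if config.n_agents < 2:
        raise ValueError("F must be >= 2")
    streams = np.random.SeedSequence(seed).spawn(config.n_agents)
    m = data.n_individuals
    agents: list[FishAgent] = []
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        size = int(rng.integers(1, config.s_max + 1))
        tree = random_tree(rng, data.n_snps, size, config.allow_negation)
        boot = rng.integers(0, m, size=m)
        oob = np.setdiff1d(np.arange(m), boot)
        boot_g = data.genotypes[boot]
        boot_p = data.phenotypes[boot]
        structure = RegressionModel(trees=(tree,))
        model, boot_sc, params = fit_assess_arrays(
            structure, boot_g, boot_p, v=config.v
        )
        full_model, full_sc, _ = fit_and_assess(structure, data, v=config.v)
        agent = FishAgent(
            agent_id=i,
            model=model,
            boot_score=boot_sc,
            full_model=full_model,
            score=full_sc,
            bootstrap_indices=boot,
            oob_indices=oob,
            boot_genotypes=boot_g,
            boot_phenotypes=boot_p,
            rng=rng,
            accept_params=params,
        )
        agent.note_if_local_best()
        agents.append(agent)
    state = SwarmState(
        agents=agents,
        importance=ImportanceTable.uniform(data.n_snps, config.refresh_period),
    )
    best = state._current_best()
    state.best_model, state.best_score = best.full_model, best.score
    return state


# ---------------------------------------------------------------------------
# Model-level moves
# ---------------------------------------------------------------------------

def _weighted_choice(
    rng: np.random.Generator, items: list, weights: np.ndarray
) -> object:
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        w = np.ones(len(items))
        total = float(len(items))
    return items[rng.choice(len(items), p=w / total)]


def _model_leaf_positions(model: RegressionModel):
    return [
        (ti, path)
        for ti, tree in enumerate(model.trees)
        for path in tree.leaf_paths()
    ]


def _replace_tree(
    model: RegressionModel, idx: int, tree: LogicTree | None
) -> RegressionModel:
    trees = list(model.trees)
    if tree is None:
        del trees[idx]
    else:
        trees[idx] = tree
    return RegressionModel(trees=tuple(trees))


def model_add_snp(
    model: RegressionModel,
    rng: np.random.Generator,
    config: RunConfig,
    snp_probs: np.ndarray | None = None,
) -> RegressionModel:
    """ADD: attach a new literal inside a tree (new AND/OR parent) or start
    a new single-leaf tree; the SNP is drawn from ``snp_probs`` (uniform if
    None)."""
    slots: list[tuple[int, tuple[int, ...] | None]] = []
    for ti, tree in enumerate(model.trees):
        if tree.size < config.s_max:
            slots.extend((ti, p) for p in tree.node_paths())
    if model.k < config.k_max:
        slots.append((-1, None))
    if not slots:
        raise MoveInfeasibleError("model is at maximum size")
    ti, path = slots[rng.integers(len(slots))]
    if snp_probs is None:
        raise ValueError("snp_probs required")
    j = int(rng.choice(len(snp_probs), p=snp_probs))
    neg = bool(rng.random() < 0.5) if config.allow_negation else False
    lit = SnpLiteral(j, neg)
    if ti == -1:
        return RegressionModel(trees=model.trees + (LogicTree(Leaf(lit)),))
    op = AND if rng.random() < 0.5 else OR
    return _replace_tree(model, ti, add_snp(model.trees[ti], lit, op, path))


def model_del_snp(
    model: RegressionModel,
    rng: np.random.Generator,
    leaf_weights: np.ndarray | None = None,
) -> RegressionModel:
    """DEL: remove one SNP leaf (a size-1 tree disappears entirely)."""
    if model.model_size < 2:
        raise MoveInfeasibleError("DEL requires model size >= 2")
    positions = _model_leaf_positions(model)
    if leaf_weights is None:
        ti, path = positions[rng.integers(len(positions))]
    else:
        ti, path = _weighted_choice(rng, positions, leaf_weights)
    tree = model.trees[ti]
    if tree.size == 1:
        return _replace_tree(model, ti, None)
    return _replace_tree(model, ti, del_snp(tree, path))


def model_alt_snp(
    model: RegressionModel,
    rng: np.random.Generator,
    config: RunConfig,
    victim_weights: np.ndarray | None = None,
    replacement_probs: np.ndarray | None = None,
) -> RegressionModel:
    """ALT SNP: replace one leaf's literal by a different one."""
    positions = _model_leaf_positions(model)
    if victim_weights is None:
        ti, path = positions[rng.integers(len(positions))]
    else:
        ti, path = _weighted_choice(rng, positions, victim_weights)
    tree = model.trees[ti]
    leaf = tree.leaves()[tree.leaf_paths().index(path)]
    for _ in range(1000):
        if replacement_probs is not None:
            j = int(rng.choice(len(replacement_probs), p=replacement_probs))
        else:
            raise ValueError("replacement_probs required")
        neg = bool(rng.random() < 0.5) if config.allow_negation else False
        lit = SnpLiteral(j, neg)
        if lit != leaf:
            return _replace_tree(model, ti, alt_snp(tree, path, lit))
    raise MoveInfeasibleError("could not draw a different literal")


def model_alt_opt(
    model: RegressionModel, rng: np.random.Generator
) -> RegressionModel:
    """ALT OPT: flip one internal AND/OR node."""
    slots = [
        (ti, p)
        for ti, tree in enumerate(model.trees)
        for p in tree.internal_paths()
    ]
    if not slots:
        raise MoveInfeasibleError("no internal node to alter")
    ti, path = slots[rng.integers(len(slots))]
    return _replace_tree(model, ti, alt_opt(model.trees[ti], path))


# ---------------------------------------------------------------------------
# SNP selection distributions for the directed behaviors
# ---------------------------------------------------------------------------

def _uniform_probs(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def _masked_probs(probs: np.ndarray, exclude: set[int], invert: bool) -> np.ndarray:
    """Selection probabilities restricted to SNPs outside ``exclude``;
    ``invert`` draws proportional to 1 - P instead of P."""
    p = (1.0 - probs) if invert else probs.copy()
    p = np.maximum(p, 0.0)
    mask = np.ones(len(p), dtype=bool)
    for j in exclude:
        mask[j] = False
    if not mask.any():
        mask[:] = True  # model covers every SNP; fall back to all
    p = np.where(mask, p, 0.0)
    total = p.sum()
    if total <= 0:
        p = mask.astype(float)
        total = p.sum()
    return p / total


def _victim_weights(
    model: RegressionModel, probs: np.ndarray, invert: bool
) -> np.ndarray:
    """Weight per leaf position: 1 - P(snp) when ``invert`` (drop the
    unimportant), else P(snp)."""
    w = []
    for ti, path in _model_leaf_positions(model):
        tree = model.trees[ti]
        leaf = tree.leaves()[tree.leaf_paths().index(path)]
        p = probs[leaf.snp_index]
        w.append((1.0 - p) if invert else p)
    return np.asarray(w)


# ---------------------------------------------------------------------------
# Behavior steps (proposal generation)
# ---------------------------------------------------------------------------

def random_step(
    agent: FishAgent, data: Dataset, config: RunConfig
) -> RegressionModel:
    """RANDOM: one of the four moves with probability 1/4 each, uniform SNP
    choices; infeasible moves are resampled."""
    rng = agent.rng
    uniform = _uniform_probs(data.n_snps)
    for _ in range(100):
        move = Move(list(Move)[rng.integers(4)])
        try:
            if move is Move.ADD_SNP:
                return model_add_snp(agent.model, rng, config, uniform)
            if move is Move.DEL_SNP:
                return model_del_snp(agent.model, rng)
            if move is Move.ALT_SNP:
                return model_alt_snp(
                    agent.model, rng, config, replacement_probs=uniform
                )
            return model_alt_opt(agent.model, rng)
        except MoveInfeasibleError:
            continue
    raise MoveInfeasibleError("no feasible move for this model")


def _alt_step(
    agent: FishAgent,
    data: Dataset,
    config: RunConfig,
    importance: ImportanceTable,
    victim_invert: bool,
    replacement_invert: bool,
) -> RegressionModel:
    """The 'two ALT operations': ALT SNP or ALT OPT, 1/2 each when both are
    feasible."""
    rng = agent.rng
    has_internal = any(t.internal_paths() for t in agent.model.trees)
    if has_internal and rng.random() < 0.5:
        return model_alt_opt(agent.model, rng)
    victim = _victim_weights(agent.model, importance.selection_probs, victim_invert)
    repl = _masked_probs(
        importance.selection_probs,
        agent.model.distinct_snps(),
        invert=replacement_invert,
    )
    return model_alt_snp(
        agent.model, rng, config, victim_weights=victim, replacement_probs=repl
    )


def follow_step(
    agent: FishAgent,
    state: SwarmState,
    data: Dataset,
    config: RunConfig,
    sigma2: float,
) -> RegressionModel:
    """FOLLOW: move toward f_best's size/SNPs.

    s_i > s_best: DEL with probability f(s_i) (victim drawn with weight
    1 - P(j)), else ALT.  s_i < s_best: ADD with probability 1 - f(s_i)
    (new SNP drawn with probability P(j)), else ALT.  s_i = s_best: ALT
    with probability 1.  Replacement SNPs are importance-seeking by default
    (strict-literal flag inverts them).
    """
    rng = agent.rng
    s_i = agent.model.model_size
    s_best = state.best_agent.model.model_size
    f_s = size_density(s_i, s_best, sigma2)
    imp = state.importance
    repl_invert = config.strict_literal_alt
    if s_i > s_best and rng.random() < f_s:
        try:
            victim = _victim_weights(agent.model, imp.selection_probs, invert=True)
            return model_del_snp(agent.model, rng, leaf_weights=victim)
        except MoveInfeasibleError:
            pass
    elif s_i < s_best and rng.random() < 1.0 - f_s:
        try:
            probs = _masked_probs(
                imp.selection_probs, agent.model.distinct_snps(), invert=False
            )
            return model_add_snp(agent.model, rng, config, probs)
        except MoveInfeasibleError:
            pass
    return _alt_step(
        agent, data, config, imp, victim_invert=True, replacement_invert=repl_invert
    )


def kpdist_step(
    agent: FishAgent,
    state: SwarmState,
    data: Dataset,
    config: RunConfig,
    sigma2: float,
) -> RegressionModel:
    """KPDIST: keep a distance from f_best.

    s_i > s_best: ADD with probability 1 - f(s_i), else ALT.
    s_i < s_best: ALT with probability f(s_i), else DEL.
    s_i = s_best: ADD or DEL with probability 1/2 each.
    SNP choices run away from importance (add unimportant, drop important).
    """
    rng = agent.rng
    s_i = agent.model.model_size
    s_best = state.best_agent.model.model_size
    f_s = size_density(s_i, s_best, sigma2)
    imp = state.importance
    away_add = lambda: model_add_snp(
        agent.model,
        rng,
        config,
        _masked_probs(imp.selection_probs, agent.model.distinct_snps(), invert=True),
    )
    away_del = lambda: model_del_snp(
        agent.model,
        rng,
        leaf_weights=_victim_weights(agent.model, imp.selection_probs, invert=False),
    )
    try:
        if s_i > s_best:
            if rng.random() < 1.0 - f_s:
                return away_add()
        elif s_i < s_best:
            if rng.random() >= f_s:
                return away_del()
        else:
            return away_add() if rng.random() < 0.5 else away_del()
    except MoveInfeasibleError:
        pass
    return _alt_step(
        agent, data, config, imp, victim_invert=False, replacement_invert=True
    )


def choose_behavior(
    agent: FishAgent, state: SwarmState, config: RunConfig
) -> Behavior:
    """HOLD iff the agent is f_best, else sample RANDOM/FOLLOW/KPDIST."""
    if agent.agent_id == state.best_agent.agent_id:
        return Behavior.HOLD
    r = agent.rng.random()
    p_random, p_follow, _ = config.behavior_probs
    if r < p_random:
        return Behavior.RANDOM
    if r < p_random + p_follow:
        return Behavior.FOLLOW
    return Behavior.KPDIST


# ---------------------------------------------------------------------------
# Importance (Eq-5 style OOB drop) and distance
# ---------------------------------------------------------------------------

def _prune_snp(node, snp: int):
    if isinstance(node, Leaf):
        return None if node.literal.snp_index == snp else node
    left = _prune_snp(node.left, snp)
    right = _prune_snp(node.right, snp)
    if left is None and right is None:
        return None
    if left is None:
        return right
    if right is None:
        return left
    return OpNode(node.op, left, right)


def model_without_snp(model: RegressionModel, snp: int) -> RegressionModel | None:
    """Remove every occurrence of ``snp``; None if the model empties."""
    trees = []
    for tree in model.trees:
        pruned = _prune_snp(tree.root, snp)
        if pruned is not None:
            trees.append(LogicTree(pruned))
    if not trees:
        return None
    return RegressionModel(trees=tuple(trees))


def _oob_correct(
    model: RegressionModel | None,
    agent: FishAgent,
    oob_genotypes: np.ndarray,
    oob_phenotypes: np.ndarray,
    v: float,
    refit: bool = True,
) -> int:
    """Correctly classified OOB rows of a model fitted on the bootstrap.

    ``model=None`` means the intercept-only rule (bootstrap majority class,
    ties to case)."""
    if model is None:
        majority = 1 if agent.boot_phenotypes.mean() >= 0.5 else 0
        return int(np.sum(oob_phenotypes == majority))
    if refit:
        model = fit_betas(
            model,
            Dataset(genotypes=agent.boot_genotypes, phenotypes=agent.boot_phenotypes),
            v=v,
        )
    pred = model.classify(oob_genotypes)
    return int(np.sum(pred == oob_phenotypes))


def compute_importance(
    state: SwarmState, data: Dataset, config: RunConfig
) -> ImportanceTable:
    """V(j) = (1/F) * sum_k (N_k - N_k^{-j}): the average drop in correctly
    classified out-of-bag rows when SNP j is removed from each agent's
    model.  SNPs absent from every model have V = 0."""
    n_agents = len(state.agents)
    values = np.zeros(data.n_snps)
    for agent in state.agents:
        snps = agent.model.distinct_snps()
        if not snps or len(agent.oob_indices) == 0:
            continue
        oob_g = data.genotypes[agent.oob_indices]
        oob_p = data.phenotypes[agent.oob_indices]
        # agent.model already carries bootstrap-fitted coefficients
        n_k = _oob_correct(agent.model, agent, oob_g, oob_p, config.v, refit=False)
        for j in snps:
            reduced = model_without_snp(agent.model, j)
            n_k_minus = _oob_correct(reduced, agent, oob_g, oob_p, config.v)
            values[j] += (n_k - n_k_minus) / n_agents
    return ImportanceTable(
        values=values,
        selection_probs=selection_distribution(values, config.importance_floor),
        refresh_period=config.refresh_period,
    )


def agent_distance(
    a: FishAgent, b: FishAgent, importance: ImportanceTable
) -> float:
    """|sum of V over a's SNP set - sum of V over b's SNP set| (the 1-D
    importance embedding of the SNP index sets)."""
    va = sum(importance.values[j] for j in a.model.distinct_snps())
    vb = sum(importance.values[j] for j in b.model.distinct_snps())
    return abs(va - vb)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _propose(
    agent: FishAgent,
    behavior: Behavior,
    state: SwarmState,
    data: Dataset,
    config: RunConfig,
    sigma2: float,
) -> RegressionModel:
    if behavior is Behavior.RANDOM:
        return random_step(agent, data, config)
    if behavior is Behavior.FOLLOW:
        return follow_step(agent, state, data, config, sigma2)
    return kpdist_step(agent, state, data, config, sigma2)


def _interaction_counts(
    models: list[RegressionModel],
) -> tuple[dict[tuple[int, int], int], dict[tuple[int, int, int], int]]:
    """Pairs/triples of SNPs co-occurring inside a single conjunction,
    counted once per model."""
    pairs: Counter = Counter()
    triples: Counter = Counter()
    for model in models:
        seen_pairs: set[tuple[int, int]] = set()
        seen_triples: set[tuple[int, int, int]] = set()
        try:
            conjunctions = model_forest(model).conjunctions
        except (RuntimeError, ValueError):
            conjunctions = tuple(
                c for tree in model.trees for c in split_to_forest(tree).conjunctions
            )
        for conj in conjunctions:
            snps = sorted({lit.snp_index for lit in conj})
            for i in range(len(snps)):
                for j in range(i + 1, len(snps)):
                    seen_pairs.add((snps[i], snps[j]))
                    for k in range(j + 1, len(snps)):
                        seen_triples.add((snps[i], snps[j], snps[k]))
        pairs.update(seen_pairs)
        triples.update(seen_triples)
    return dict(pairs), dict(triples)


def run(data: Dataset, config: RunConfig, seed: int) -> SwarmReport:
    """Run the fish-swarm search until the best score is stable for B
    iterations (or the hard iteration cap).  Deterministic given the seed."""
    state = initialize_swarm(data, config, seed)
    converged = False
    while state.iteration < config.max_iterations:
        state.iteration += 1
        best_agent = state.announce_best()
        s_best = best_agent.model.model_size
        sizes = np.array([a.model.model_size for a in state.agents], dtype=float)
        sigma2 = max(config.sigma2_floor, float(np.mean((sizes - s_best) ** 2)))
        prev_best = state.best_score
        for agent in state.agents:
            behavior = choose_behavior(agent, state, config)
            if log.isEnabledFor(logging.DEBUG):
                log.debug(
                    "iter %d agent %d behavior %s (size %d)",
                    state.iteration, agent.agent_id, behavior.value,
                    agent.model.model_size,
                )
            if behavior is Behavior.HOLD:
                continue
            try:
                proposal = _propose(agent, behavior, state, data, config, sigma2)
            except MoveInfeasibleError:
                continue
            try:
                fitted, boot_sc, params = fit_assess_arrays(
                    proposal, agent.boot_genotypes, agent.boot_phenotypes,
                    v=config.v,
                )
            except (np.linalg.LinAlgError, FloatingPointError):
                continue  # degenerate design: reject with diagnostic state
            accept = boot_sc > agent.boot_score
            if not accept:
                if config.q_against_best:
                    reference = acceptance_params(
                        state.best_model, data, config.v
                    )
                else:
                    reference = agent.accept_params
                q = acceptance_probability(reference, params)
                threshold = (1.0 - q) if config.literal_rejection else q
                accept = agent.rng.random() < threshold
            if accept:
                agent.model, agent.boot_score = fitted, boot_sc
                agent.accept_params = params
                full_model, full_sc, _ = fit_and_assess(
                    proposal, data, v=config.v
                )
                agent.full_model, agent.score = full_model, full_sc
                agent.note_if_local_best()
                if full_sc > state.best_score or (
                    full_sc == state.best_score
                    and full_model.model_size < state.best_model.model_size
                ):
                    state.best_model, state.best_score = full_model, full_sc
        if state.iteration % config.refresh_period == 0:
            state.importance = compute_importance(state, data, config)
            for agent in state.agents:
                if agent.model.model_size < 2:
                    continue
                boot_data = Dataset(
                    genotypes=agent.boot_genotypes,
                    phenotypes=agent.boot_phenotypes,
                )
                pruned = stepwise_eliminate(
                    agent.model, boot_data, f_out=config.f_out, v=config.v
                )
                if pruned.trees != agent.model.trees:
                    fitted, boot_sc, params = fit_assess_arrays(
                        pruned, agent.boot_genotypes, agent.boot_phenotypes,
                        v=config.v,
                    )
                    agent.model, agent.boot_score = fitted, boot_sc
                    agent.accept_params = params
                    full_model, full_sc, _ = fit_and_assess(
                        pruned, data, v=config.v
                    )
                    agent.full_model, agent.score = full_model, full_sc
                    agent.note_if_local_best()
                    if agent.score > state.best_score or (
                        agent.score == state.best_score
                        and full_model.model_size < state.best_model.model_size
                    ):
                        state.best_model = agent.full_model
                        state.best_score = agent.score
        if log.isEnabledFor(logging.INFO):
            log.info(
                "iter %d best score %d (stable %d)",
                state.iteration, state.best_score, state.stable_count,
            )
        if state.best_score > prev_best:
            state.stable_count = 0
        else:
            state.stable_count += 1
        if state.stable_count >= config.stable_iterations:
            converged = True
            break
    # final refresh so the reported table reflects the reported models
    state.importance = compute_importance(state, data, config)
    final_models = [canonicalize_signs(a.full_model) for a in state.agents]
    pairs, triples = _interaction_counts(final_models)
    pruned_best = (
        stepwise_eliminate(state.best_model, data, f_out=config.f_out, v=config.v)
        if state.best_model.model_size >= 2
        else fit_betas(state.best_model, data, v=config.v)
    )
    prior = PriorConfig(alpha=config.alpha, s_max=config.s_max, n_max=config.k_max)
    best_log_prior = model_log_prior(pruned_best, prior, data.n_snps)
    best_f_stats = tuple(
        (pruned_best.trees[ti].leaves()[
            pruned_best.trees[ti].leaf_paths().index(path)
        ].snp_index, f)
        for ti, path, f in leaf_f_statistics(pruned_best, data)
    )
    return SwarmReport(
        best_model=canonicalize_signs(state.best_model),
        best_score=state.best_score,
        best_model_pruned=canonicalize_signs(pruned_best),
        agent_models=tuple(final_models),
        agent_scores=tuple(a.score for a in state.agents),
        local_best_models=tuple(
            canonicalize_signs(m) for m in (a.local_best_model for a in state.agents)
        ),
        local_best_scores=tuple(a.local_best_score for a in state.agents),
        importance=state.importance.values.copy(),
        pair_counts=pairs,
        triple_counts=triples,
        iterations=state.iteration,
        converged=converged,
        seed=seed,
        config=config,
        best_log_prior=best_log_prior,
        best_f_stats=best_f_stats,
    )
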