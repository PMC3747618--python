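"""Case-control simulation with planted Boolean interactions.

The generator emulates the standard coalescent-style simulation protocol for
benchmarking interaction-detection methods:

1. draw a pool of haplotypes with a fixed number of segregating sites, each
   site's derived-allele count following the neutral site-frequency spectrum
   P(count = i) proportional to 1/i (sites independent; an optional msprime
   coalescent backend adds linkage structure);
2. pick a set of causal sites and plant a random Boolean expression over
   them (AND/OR internal nodes, un-negated leaves by default), rejecting
   expressions whose case prevalence in the pool falls outside 5-95% so both
   phenotype classes exist;
3. assign each haplotype the expression output as phenotype with probability
   ``risk`` (the agreement probability; risk = 1 is deterministic);
4. sample ``n_cases`` case and ``n_controls`` control haplotypes without
   replacement and shuffle the rows;
5. flip each sampled allele independently with probability ``noise``
   (applied after sampling, matching the protocol's ordering).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .logic_tree import (
    AND,
    OR,
    Leaf,
    LogicTree,
    Node,
    OpNode,
    SnpLiteral,
    to_infix,
    to_json_dict,
)
from .regression import Dataset


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of one simulated dataset."""

    n_pool: int = 40_000      # haplotypes in the source pool
    n_sites: int = 1_000      # segregating sites
    n_causal: int = 10        # planted causal sites
    risk: float = 1.0         # P(phenotype == expression output)
    noise: float = 0.0        # per-allele flip probability
    n_cases: int = 1_000
    n_controls: int = 1_000
    expression_shape: str = "random"   # "random" | "and" | "or"
    allow_negation: bool = False       # negated leaves in the planted truth
    backend: str = "sfs"               # "sfs" | "msprime"

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk <= 1.0:
            raise ValueError("risk must lie in [0, 1]")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")
        if self.n_causal > self.n_sites:
            raise ValueError("n_causal cannot exceed n_sites")
        if self.n_cases + self.n_controls > self.n_pool:
            raise ValueError("cannot sample more individuals than the pool")


@dataclass(frozen=True)
class SimulatedDataset:
    """A dataset plus the planted truth it was generated from."""

    dataset: Dataset
    causal_indices: tuple[int, ...]
    truth_expression: LogicTree
    config: SimulationConfig
    seed: int

    def truth_json(self) -> str:
        return json.dumps(
            {
                "expression": to_infix(self.truth_expression),
                "expression_tree": to_json_dict(self.truth_expression),
                "causal_indices": list(self.causal_indices),
                "config": asdict(self.config),
                "seed": self.seed,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Haplotype pools
# ---------------------------------------------------------------------------

def simulate_haplotypes(
    n_pool: int,
    n_sites: int,
    rng: np.random.Generator,
    backend: str = "sfs",
) -> np.ndarray:
    """Binary haplotype matrix (n_pool x n_sites); every column segregating."""
    if backend == "sfs":
        return _sfs_haplotypes(n_pool, n_sites, rng)
    if backend == "msprime":
        return _msprime_haplotypes(n_pool, n_sites, rng)
    raise ValueError(f"unknown backend {backend!r}")


def _sfs_haplotypes(
    n_pool: int, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent sites; derived-allele count per site drawn from the
    neutral SFS P(i) proportional to 1/i, i in [1, n_pool - 1], placed on
    uniformly random haplotypes (so every site is segregating by
    construction)."""
    counts_support = np.arange(1, n_pool)
    weights = 1.0 / counts_support
    weights /= weights.sum()
    counts = rng.choice(counts_support, size=n_sites, p=weights)
    matrix = np.zeros((n_pool, n_sites), dtype=np.int8)
    for j, c in enumerate(counts):
        rows = rng.choice(n_pool, size=int(c), replace=False, shuffle=False)
        matrix[rows, j] = 1
    return matrix


def _msprime_haplotypes(
    n_pool: int, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Coalescent backend (optional): haplotypes with linkage structure,
    resimulated until at least n_sites segregating sites exist, then a
    random subset of n_sites columns is kept."""
    import msprime

    mut_rate = 1e-7
    length = 1e6
    ne = 10_000
    msp_seed = int(rng.integers(1, 2**31 - 1))
    for attempt in range(20):
        ts = msprime.sim_ancestry(
            samples=n_pool,
            ploidy=1,
            sequence_length=length,
            recombination_rate=1e-7,
            population_size=ne,
            random_seed=msp_seed + attempt,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mut_rate,
            random_seed=msp_seed + attempt,
            model=msprime.BinaryMutationModel(),
        )
        gm = mts.genotype_matrix().T  # haplotypes x sites
        gm = np.minimum(gm, 1).astype(np.int8)
        seg = np.flatnonzero((gm.sum(axis=0) > 0) & (gm.sum(axis=0) < n_pool))
        if len(seg) >= n_sites:
            keep = rng.choice(seg, size=n_sites, replace=False, shuffle=False)
            return gm[:, np.sort(keep)]
        mut_rate *= 2.0
    raise RuntimeError("coalescent backend failed to yield enough sites")


# ---------------------------------------------------------------------------
# Planted expressions
# ---------------------------------------------------------------------------

def _random_expression(
    causal: np.ndarray, rng: np.random.Generator, shape: str, allow_negation: bool
) -> LogicTree:
    def lit(j: int) -> Node:
        neg = bool(rng.random() < 0.5) if allow_negation else False
        return Leaf(SnpLiteral(int(j), neg))

    nodes: list[Node] = [lit(j) for j in causal]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        i = int(rng.integers(len(nodes)))
        b = nodes.pop(i)
        if shape == "and":
            op = AND
        elif shape == "or":
            op = OR
        else:
            op = AND if rng.random() < 0.5 else OR
        nodes.append(OpNode(op, a, b))
    return LogicTree(nodes[0])


def plant_expression(
    causal_indices: np.ndarray,
    haplotypes: np.ndarray,
    rng: np.random.Generator,
    shape: str = "random",
    allow_negation: bool = False,
    prevalence_bounds: tuple[float, float] = (0.05, 0.95),
    max_resamples: int = 1000,
) -> LogicTree:
    """Random Boolean expression whose leaf set is exactly the causal sites.

    Rejection-resamples the tree shape until the fraction of pool haplotypes
    evaluating to 1 lies inside ``prevalence_bounds`` (both classes must
    exist downstream).
    """
    lo, hi = prevalence_bounds
    for _ in range(max_resamples):
        tree = _random_expression(causal_indices, rng, shape, allow_negation)
        prev = float(tree.evaluate(haplotypes).mean())
        if lo <= prev <= hi:
            return tree
    raise RuntimeError(
        "no expression over these causal sites met the prevalence guard; "
        "try a different number of causal sites or another site set"
    )


def assign_phenotypes(
    haplotypes: np.ndarray,
    expression: LogicTree,
    risk: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotype = expression output with probability ``risk`` (agreement),
    else its complement.  risk = 1 is deterministic."""
    out = expression.evaluate(haplotypes).astype(np.int8)
    agree = rng.random(out.shape[0]) < risk
    return np.where(agree, out, 1 - out).astype(np.int8)


def add_noise(
    haplotypes: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each allele independently with probability ``noise``."""
    if noise == 0.0:
        return haplotypes.copy()
    flips = rng.random(haplotypes.shape) < noise
    return np.where(flips, 1 - haplotypes, haplotypes).astype(np.int8)


def sample_case_control(
    haplotypes: np.ndarray,
    phenotypes: np.ndarray,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement sampling within each class, rows
    shuffled.  Raises if the pool lacks enough of either class."""
    cases = np.flatnonzero(phenotypes == 1)
    controls = np.flatnonzero(phenotypes == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise RuntimeError(
            f"pool has {len(cases)} cases / {len(controls)} controls but "
            f"{n_cases}/{n_controls} were requested; enlarge the pool or "
            "replant the expression"
        )
    chosen = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False, shuffle=False),
            rng.choice(controls, size=n_controls, replace=False, shuffle=False),
        ]
    )
    chosen = rng.permutation(chosen)
    return haplotypes[chosen], phenotypes[chosen]


def simulate(
    config: SimulationConfig,
    seed: int,
    max_attempts: int = 50,
    pool_attempts: int = 10,
) -> SimulatedDataset:
    """Full pipeline; retries with fresh causal sites when the prevalence
    guard or the class counts cannot be met, and resamples the pool itself
    when no causal-site draw over it works (e.g. an AND expression needs
    high-frequency sites the pool may lack)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    last_err: Exception | None = None
    for _ in range(pool_attempts):
        pool = simulate_haplotypes(config.n_pool, config.n_sites, rng, config.backend)
        for _ in range(max_attempts):
            causal = np.sort(
                rng.choice(
                    config.n_sites, size=config.n_causal, replace=False, shuffle=False
                )
            )
            try:
                truth = plant_expression(
                    causal,
                    pool,
                    rng,
                    shape=config.expression_shape,
                    allow_negation=config.allow_negation,
                    max_resamples=50,
                )
                phenotypes = assign_phenotypes(pool, truth, config.risk, rng)
                geno, pheno = sample_case_control(
                    pool, phenotypes, config.n_cases, config.n_controls, rng
                )
            except RuntimeError as err:
                last_err = err
                continue
            geno = add_noise(geno, config.noise, rng)
            dataset = Dataset(genotypes=geno, phenotypes=pheno)
            return SimulatedDataset(
                dataset=dataset,
                causal_indices=tuple(int(j) for j in causal),
                truth_expression=truth,
                config=config,
                seed=seed,
            )
    raise RuntimeError(
        f"simulation failed after {pool_attempts} pools x {max_attempts} "
        f"causal-set draws: {last_err}"
    )


def paper_default_config(**overrides) -> SimulationConfig:
    """The benchmark study design: 40,000-haplotype pool, 1,000 segregating
    sites, 1,000 cases and 1,000 controls."""
    base = dict(n_pool=40_000, n_sites=1_000, n_cases=1_000, n_controls=1_000)
    base.update(overrides)
    return SimulationConfig(**base)
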