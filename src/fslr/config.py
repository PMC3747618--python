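"""Run configuration: every tunable of the search with its default.

Defaults marked "convention" follow common logic-regression practice; the
swarm-specific defaults are this package's own choices and are documented in
docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class RunConfig:
    # swarm
    n_agents: int = 12            # F: number of fish agents
    stable_iterations: int = 50   # B: stop when best unchanged this long
    refresh_period: int = 10      # I_max: iterations between importance
                                  # refresh + stepwise sweeps
    max_iterations: int = 10_000  # hard non-convergence safeguard
    behavior_probs: tuple[float, float, float] = (0.2, 0.5, 0.3)
    # (RANDOM, FOLLOW, KPDIST) mixture for non-best agents
    sigma2_floor: float = 0.25    # floor of the size-density variance
    importance_floor: float = 0.5 # epsilon keeping every SNP reachable
    strict_literal_alt: bool = False  # draw ALT replacement with 1 - P(j')
    literal_rejection: bool = False   # "rejected with probability Q" reading
    q_against_best: bool = False      # compare proposals to f_best, not self
    # model space
    s_max: int = 8                # maximum leaves per tree
    k_max: int = 3                # maximum number of trees per model
    allow_negation: bool = True   # negated literals in search trees
    # regression
    v: float = 10.0               # prior variance of coefficients
    f_out: float = 4.0            # stepwise-elimination F threshold
    alpha: float = 0.5            # size-penalty of the model prior (convention)
    threads: int = 1              # advisory; execution is sequential and
                                  # bit-identical regardless

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents (FOLLOW/KPDIST undefined)")
        if abs(sum(self.behavior_probs) - 1.0) > 1e-9:
            raise ValueError("behavior_probs must sum to 1")
        if min(self.behavior_probs) < 0:
            raise ValueError("behavior_probs must be non-negative")
        if self.s_max < 1 or self.k_max < 1:
            raise ValueError("s_max and k_max must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["behavior_probs"] = list(self.behavior_probs)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "behavior_probs" in d:
            d["behavior_probs"] = tuple(d["behavior_probs"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
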