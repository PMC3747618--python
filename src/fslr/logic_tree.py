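"""Boolean logic trees over binary SNP data.

A logic tree (LT) is a strictly binary tree whose leaves are SNP literals
(a SNP index, optionally negated) and whose internal nodes carry an AND or
an OR operator.  It represents a Boolean interaction among SNPs: on a binary
genotype vector the tree evaluates to 0 or 1.  Trees are edited by four
moves — ADD_SNP, DEL_SNP, ALT_SNP, ALT_OPT — which are the proposal kernel
of the regression search.

Splitting a tree at every OR operator (distributing AND over OR) yields a
*forest* of AND-only conjunctions whose disjunction is evaluation-equivalent
to the original tree.  The forest defines the solution-space embedding used
by the swarm: a tree maps to the coordinate (n, s_vec, Y) where n is the
number of conjunctions, s_vec their sizes and Y the model score.

Negation lives only on leaves; internal nodes are never negated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

AND = "&"
OR = "|"
_OPS = (AND, OR)


class MoveInfeasibleError(RuntimeError):
    """Raised when a tree move cannot be applied (caller should resample)."""


class Move(Enum):
    ADD_SNP = "ADD_SNP"
    DEL_SNP = "DEL_SNP"
    ALT_SNP = "ALT_SNP"
    ALT_OPT = "ALT_OPT"


@dataclass(frozen=True)
class SnpLiteral:
    """A leaf: SNP ``snp_index`` (0-based), optionally negated."""

    snp_index: int
    negated: bool = False

    def evaluate(self, genotypes: np.ndarray) -> np.ndarray:
        col = genotypes[..., self.snp_index]
        return 1 - col if self.negated else col

    @property
    def label(self) -> str:
        return ("!" if self.negated else "") + f"X{self.snp_index + 1}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class Leaf:
    literal: SnpLiteral


@dataclass(frozen=True)
class OpNode:
    op: str
    left: "Leaf | OpNode"
    right: "Leaf | OpNode"

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")


Node = Leaf | OpNode

# Paths address nodes as tuples of 0 (left) / 1 (right) from the root.
Path = tuple[int, ...]


def _node_at(node: Node, path: Path) -> Node:
    for step in path:
        if not isinstance(node, OpNode):
            raise IndexError("path runs past a leaf")
        node = node.left if step == 0 else node.right
    return node


def _replace_at(node: Node, path: Path, new: Node) -> Node:
    if not path:
        return new
    assert isinstance(node, OpNode)
    if path[0] == 0:
        return OpNode(node.op, _replace_at(node.left, path[1:], new), node.right)
    return OpNode(node.op, node.left, _replace_at(node.right, path[1:], new))


def _iter_nodes(node: Node, path: Path = ()) -> Iterator[tuple[Path, Node]]:
    yield path, node
    if isinstance(node, OpNode):
        yield from _iter_nodes(node.left, path + (0,))
        yield from _iter_nodes(node.right, path + (1,))


@dataclass(frozen=True)
class LogicTree:
    """Rooted strictly binary tree of SNP literals and AND/OR operators."""

    root: Node

    # ------------------------------------------------------------------ shape
    @property
    def size(self) -> int:
        """Number of leaves (the tree size s_i)."""
        return len(self.leaf_paths())

    def leaf_paths(self) -> list[Path]:
        return [p for p, n in _iter_nodes(self.root) if isinstance(n, Leaf)]

    def internal_paths(self) -> list[Path]:
        return [p for p, n in _iter_nodes(self.root) if isinstance(n, OpNode)]

    def node_paths(self) -> list[Path]:
        return [p for p, _ in _iter_nodes(self.root)]

    def leaves(self) -> list[SnpLiteral]:
        return [
            n.literal for _, n in _iter_nodes(self.root) if isinstance(n, Leaf)
        ]

    def snps(self) -> list[int]:
        """SNP indices at the leaves, with repeats, in leaf order."""
        return [lit.snp_index for lit in self.leaves()]

    def distinct_snps(self) -> set[int]:
        return set(self.snps())

    @property
    def has_repeats(self) -> bool:
        s = self.snps()
        return len(s) != len(set(s))

    def snp_indicator(self, n_snps: int) -> np.ndarray:
        """Binary indicator vector q_i: q[j]=1 iff SNP j is some leaf."""
        q = np.zeros(n_snps, dtype=np.int8)
        for j in self.distinct_snps():
            if j >= n_snps:
                raise IndexError(f"leaf SNP {j} out of range for N={n_snps}")
            q[j] = 1
        return q

    # --------------------------------------------------------------- evaluate
    def evaluate(self, genotypes: np.ndarray) -> np.ndarray:
        """Evaluate on one genotype (1-D) or row-wise on an M x N matrix.

        Entries must be 0/1; returns 0/1 of the same leading shape.
        """
        genotypes = np.asarray(genotypes)
        n_needed = max(self.snps(), default=-1)
        if genotypes.shape[-1] <= n_needed:
            raise IndexError(
                f"tree references SNP index {n_needed} but input has only "
                f"{genotypes.shape[-1]} columns"
            )
        return _eval_node(self.root, genotypes)

    # -------------------------------------------------------------- structure
    def __str__(self) -> str:
        return to_infix(self)


def _eval_node(node: Node, g: np.ndarray) -> np.ndarray:
    if isinstance(node, Leaf):
        return node.literal.evaluate(g)
    a = _eval_node(node.left, g)
    b = _eval_node(node.right, g)
    return np.minimum(a, b) if node.op == AND else np.maximum(a, b)


def leaf_tree(snp_index: int, negated: bool = False) -> LogicTree:
    return LogicTree(Leaf(SnpLiteral(snp_index, negated)))


# ---------------------------------------------------------------------------
# Tree-editing moves
# ---------------------------------------------------------------------------

def add_snp(
    tree: LogicTree, literal: SnpLiteral, op: str, at: Path
) -> LogicTree:
    """Attach ``literal`` with a new ``op`` parent above the node at ``at``.

    The node previously at ``at`` becomes the left child, the new leaf the
    right child.  Size grows by exactly one.
    """
    target = _node_at(tree.root, at)
    new = OpNode(op, target, Leaf(literal))
    return LogicTree(_replace_at(tree.root, at, new))


def del_snp(tree: LogicTree, leaf_at: Path) -> LogicTree:
    """Delete the leaf at ``leaf_at``; its parent operator node is removed
    and the sibling promoted.  Requires size >= 2."""
    if tree.size < 2:
        raise MoveInfeasibleError("cannot delete the only leaf")
    node = _node_at(tree.root, leaf_at)
    if not isinstance(node, Leaf):
        raise ValueError("DEL_SNP target is not a leaf")
    parent_path, last = leaf_at[:-1], leaf_at[-1]
    parent = _node_at(tree.root, parent_path)
    assert isinstance(parent, OpNode)
    sibling = parent.right if last == 0 else parent.left
    return LogicTree(_replace_at(tree.root, parent_path, sibling))


def alt_snp(tree: LogicTree, leaf_at: Path, literal: SnpLiteral) -> LogicTree:
    """Replace the leaf at ``leaf_at`` by a *different* literal."""
    node = _node_at(tree.root, leaf_at)
    if not isinstance(node, Leaf):
        raise ValueError("ALT_SNP target is not a leaf")
    if node.literal == literal:
        raise MoveInfeasibleError("ALT_SNP must change the literal")
    return LogicTree(_replace_at(tree.root, leaf_at, Leaf(literal)))


def alt_opt(tree: LogicTree, op_at: Path) -> LogicTree:
    """Flip the internal node at ``op_at`` between AND and OR."""
    node = _node_at(tree.root, op_at)
    if not isinstance(node, OpNode):
        raise MoveInfeasibleError("ALT_OPT requires an internal node")
    flipped = OR if node.op == AND else AND
    return LogicTree(_replace_at(tree.root, op_at, OpNode(flipped, node.left, node.right)))


def apply_move(
    tree: LogicTree,
    move: Move,
    rng: np.random.Generator,
    n_snps: int,
    allow_negation: bool = True,
) -> LogicTree:
    """Apply ``move`` with uniform choices over eligible positions/literals.

    Raises :class:`MoveInfeasibleError` when the move's precondition fails so
    the caller can resample a behavior.
    """
    if move is Move.ADD_SNP:
        paths = tree.node_paths()
        at = paths[rng.integers(len(paths))]
        lit = _random_literal(rng, n_snps, allow_negation)
        op = AND if rng.random() < 0.5 else OR
        return add_snp(tree, lit, op, at)
    if move is Move.DEL_SNP:
        if tree.size < 2:
            raise MoveInfeasibleError("DEL_SNP requires size >= 2")
        paths = tree.leaf_paths()
        return del_snp(tree, paths[rng.integers(len(paths))])
    if move is Move.ALT_SNP:
        paths = tree.leaf_paths()
        at = paths[rng.integers(len(paths))]
        current = _node_at(tree.root, at)
        assert isinstance(current, Leaf)
        for _ in range(1000):
            lit = _random_literal(rng, n_snps, allow_negation)
            if lit != current.literal:
                return alt_snp(tree, at, lit)
        raise MoveInfeasibleError("no alternative literal available")
    if move is Move.ALT_OPT:
        paths = tree.internal_paths()
        if not paths:
            raise MoveInfeasibleError("ALT_OPT requires an internal node")
        return alt_opt(tree, paths[rng.integers(len(paths))])
    raise ValueError(f"unknown move {move}")


def _random_literal(
    rng: np.random.Generator, n_snps: int, allow_negation: bool
) -> SnpLiteral:
    idx = int(rng.integers(n_snps))
    neg = bool(rng.random() < 0.5) if allow_negation else False
    return SnpLiteral(idx, neg)


def random_tree(
    rng: np.random.Generator,
    n_snps: int,
    size: int,
    allow_negation: bool = True,
) -> LogicTree:
    """Grow a random tree of the requested leaf count by repeated ADD_SNP."""
    if size < 1:
        raise ValueError("size must be >= 1")
    tree = LogicTree(Leaf(_random_literal(rng, n_snps, allow_negation)))
    while tree.size < size:
        tree = apply_move(tree, Move.ADD_SNP, rng, n_snps, allow_negation)
    return tree


# ---------------------------------------------------------------------------
# OR-split forest and the solution-space coordinate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Forest:
    """AND-only conjunctions whose OR equals the source tree.

    Each conjunction is a frozenset of literals (the commutative law makes
    topology inside a conjunction irrelevant).
    """

    conjunctions: tuple[frozenset[SnpLiteral], ...]

    @property
    def n(self) -> int:
        return len(self.conjunctions)

    def evaluate(self, genotypes: np.ndarray) -> np.ndarray:
        genotypes = np.asarray(genotypes)
        out = np.zeros(genotypes.shape[:-1], dtype=np.int8)
        for conj in self.conjunctions:
            val = np.ones(genotypes.shape[:-1], dtype=np.int8)
            for lit in conj:
                val = np.minimum(val, lit.evaluate(genotypes))
            out = np.maximum(out, val)
        return out

    def contains_conjunction(self, snps: Sequence[int]) -> bool:
        """True if some conjunction's SNP set contains all of ``snps``."""
        want = set(snps)
        return any(
            want <= {lit.snp_index for lit in conj} for conj in self.conjunctions
        )


def complement(tree: LogicTree) -> LogicTree:
    """De Morgan complement: NOT(tree), with negation pushed to the leaves
    (operators swap, leaf negations toggle).  Evaluates to 1 - tree."""
    return LogicTree(_complement(tree.root))


def _complement(node: Node) -> Node:
    if isinstance(node, Leaf):
        lit = node.literal
        return Leaf(SnpLiteral(lit.snp_index, not lit.negated))
    flipped = OR if node.op == AND else AND
    return OpNode(flipped, _complement(node.left), _complement(node.right))


def split_to_forest(tree: LogicTree) -> Forest:
    """Recursively distribute AND over OR until every conjunction is OR-free."""
    return Forest(tuple(_split(tree.root)))


def _split(node: Node) -> list[frozenset[SnpLiteral]]:
    if isinstance(node, Leaf):
        return [frozenset([node.literal])]
    left = _split(node.left)
    right = _split(node.right)
    if node.op == OR:
        return left + right
    return [a | b for a in left for b in right]


@dataclass(frozen=True)
class SpaceCoordinate:
    """Embedding (n, s_vec, Y) of a tree in the search hyperspace."""

    n: int
    sizes: tuple[int, ...]
    score: int

    def __post_init__(self) -> None:
        if self.n < 1 or any(s < 1 for s in self.sizes):
            raise ValueError("coordinate requires n >= 1 and sizes >= 1")


def coordinate(
    tree: LogicTree, score: int, simplified: bool = False
) -> SpaceCoordinate:
    """Map a tree (plus its score Y) to (n, s_vec, Y).

    ``simplified`` replaces the size vector by the scalar size of the
    original tree.
    """
    forest = split_to_forest(tree)
    if simplified:
        sizes = (tree.size,)
    else:
        sizes = tuple(len(c) for c in forest.conjunctions)
    return SpaceCoordinate(n=forest.n, sizes=sizes, score=score)


# ---------------------------------------------------------------------------
# Serialization: parenthesized infix and JSON node records
# ---------------------------------------------------------------------------

def to_infix(tree: LogicTree) -> str:
    return _infix(tree.root, top=True)


def _infix(node: Node, top: bool = False) -> str:
    if isinstance(node, Leaf):
        return node.literal.label
    s = f"{_infix(node.left)} {node.op} {_infix(node.right)}"
    return s if top else f"({s})"


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = self._tokenize(text)
        self.pos = 0

    @staticmethod
    def _tokenize(text: str) -> list[str]:
        tokens: list[str] = []
        i = 0
        while i < len(text):
            c = text[i]
            if c.isspace():
                i += 1
            elif c in "()!&|":
                tokens.append(c)
                i += 1
            elif c in "Xx":
                j = i + 1
                while j < len(text) and text[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise ValueError(f"bad token at {text[i:]!r}")
                tokens.append(text[i:j])
                i = j
            else:
                raise ValueError(f"unexpected character {c!r}")
        return tokens

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of expression")
        self.pos += 1
        return tok

    # expr := term ((&||) term)*   — left-associative, no precedence: the
    # serializer always parenthesizes mixed operators, so flat runs of one
    # operator are folded left.
    def expr(self) -> Node:
        node = self.term()
        while self.peek() in (AND, OR):
            op = self.take()
            rhs = self.term()
            node = OpNode(op, node, rhs)
        return node

    def term(self) -> Node:
        tok = self.take()
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise ValueError("missing closing parenthesis")
            return node
        if tok == "!":
            nxt = self.take()
            if not nxt.upper().startswith("X"):
                raise ValueError("negation must precede a literal")
            return Leaf(SnpLiteral(self._index(nxt), negated=True))
        if tok.upper().startswith("X"):
            return Leaf(SnpLiteral(self._index(tok), negated=False))
        raise ValueError(f"unexpected token {tok!r}")

    @staticmethod
    def _index(token: str) -> int:
        k = int(token[1:])
        if k < 1:
            raise ValueError(f"SNP labels are 1-based; got {token!r}")
        return k - 1


def parse_infix(text: str) -> LogicTree:
    """Parse `(X1 & X2) & (!X3 | X4)`-style text (1-based SNP labels)."""
    parser = _Parser(text)
    node = parser.expr()
    if parser.peek() is not None:
        raise ValueError(f"trailing tokens: {parser.tokens[parser.pos:]}")
    return LogicTree(node)


def to_json_dict(tree: LogicTree) -> dict:
    return {"infix": to_infix(tree), "root": _node_dict(tree.root)}


def _node_dict(node: Node) -> dict:
    if isinstance(node, Leaf):
        return {
            "type": "leaf",
            "snp_index": node.literal.snp_index,
            "negated": node.literal.negated,
        }
    return {
        "type": "op",
        "op": "AND" if node.op == AND else "OR",
        "left": _node_dict(node.left),
        "right": _node_dict(node.right),
    }


def from_json_dict(d: dict) -> LogicTree:
    return LogicTree(_node_from_dict(d["root"]))


def _node_from_dict(d: dict) -> Node:
    if d["type"] == "leaf":
        return Leaf(SnpLiteral(int(d["snp_index"]), bool(d["negated"])))
    op = AND if d["op"] == "AND" else OR
    return OpNode(op, _node_from_dict(d["left"]), _node_from_dict(d["right"]))


def to_json(tree: LogicTree) -> str:
    return json.dumps(to_json_dict(tree))


def from_json(text: str) -> LogicTree:
    return from_json_dict(json.loads(text))
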