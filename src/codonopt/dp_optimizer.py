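"""Optimal codon-path search over the layered codon graph.

Back-translating a protein means choosing one synonymous codon per residue.
Arranged as a layered graph -- one layer per residue, nodes the synonymous
codons, complete bipartite scored edges between consecutive layers -- the
design problem becomes a best-path search through all layers, and the
exponential candidate set (the product of the layer sizes) collapses to a
dynamic program whose work is the state-space size

    S = sum_{i=1}^{K-1} |r_i| * |r_{i+1}|,

the number of edges, linear in protein length for the standard code (layer
widths are at most 6).

Three objectives are supported.  ``best`` maximizes the total context score
and ``worst`` minimizes it (the deoptimized control).  ``unbiased`` seeks a
context-neutral sequence: it minimizes the sum of |junction score|, and for
integer-valued tables breaks ties toward the signed total nearest zero.
All remaining ties are broken toward the lexicographically smallest whole
codon path, which the DP achieves exactly via suffix scores plus a greedy
forward traceback -- so results are deterministic and bit-comparable with
the brute-force oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

from .errors import InputError, ParameterError, SizeError
from .genetic_code import STOP, CodingSequence, GeneticCode, validate_protein
from .pair_scoring import CodonPairScoreTable

MODES = ("best", "worst", "unbiased")

#: absolute tolerance for tie detection with non-integer tables
FLOAT_TIE_TOL = 1e-9

__all__ = [
    "MODES",
    "LayeredCodonGraph",
    "OptimizationResult",
    "build_graph",
    "state_space_size",
    "optimize",
    "brute_force_oracle",
]


@dataclass(frozen=True)
class LayeredCodonGraph:
    """Per-residue layers of codon nodes; edges are implicit.

    Between consecutive layers every node pair is connected (complete
    bipartite), weighted at search time by the score table, so only the
    ordered layers need storing.
    """

    protein: str
    layers: tuple[tuple[str, ...], ...]

    @property
    def edge_counts(self) -> list[int]:
        return [
            len(a) * len(b) for a, b in zip(self.layers, self.layers[1:])
        ]

    @property
    def state_space_size(self) -> int:
        return sum(self.edge_counts)


@dataclass(frozen=True)
class OptimizationResult:
    """A chosen codon path with its score breakdown and search provenance."""

    cds: CodingSequence
    total_score: float
    junction_scores: tuple[float, ...]
    mode: str
    states_explored: int
    ties_encountered: int
    table_provenance: str = "unspecified"
    #: secondary objective value for mode "unbiased" (sum of |junction|);
    #: equals -total for "worst" internally, unused otherwise
    objective_value: float = field(default=math.nan)


def build_graph(
    protein: str, code: GeneticCode | None = None, append_stop: bool = False
) -> LayeredCodonGraph:
    """Build the layered codon graph for *protein*.

    With ``append_stop=True`` a final stop layer (the three stop codons) is
    added so the search also chooses the stop codon; a protein already
    ending in ``'*'`` gets its stop layer either way.
    """
    code = code or GeneticCode.standard()
    protein = validate_protein(protein)
    if append_stop and not protein.endswith(STOP):
        protein += STOP
    layers = tuple(code.synonymous_codons(aa) for aa in protein)
    return LayeredCodonGraph(protein=protein, layers=layers)


def state_space_size(graph: LayeredCodonGraph) -> int:
    """S = sum over junctions of |r_i| * |r_{i+1}| (0 for one layer)."""
    return graph.state_space_size


def _edge_cost(mode: str, score: float) -> float:
    # all modes minimize the transformed edge weight
    if mode == "best":
        return -score
    if mode == "worst":
        return score
    return abs(score)


def _is_tie(a: float, b: float, exact: bool) -> bool:
    return a == b if exact else math.isclose(a, b, rel_tol=0.0, abs_tol=FLOAT_TIE_TOL)


def optimize(
    protein: str,
    table: CodonPairScoreTable,
    mode: str = "best",
    code: GeneticCode | None = None,
    append_stop: bool = False,
) -> OptimizationResult:
    """Find the exact optimum codon path for *protein* under *mode*.

    Runs in time proportional to the state-space size S.  Deterministic:
    among objective-optimal paths the lexicographically smallest codon
    sequence is returned, computed by a backward (suffix) DP followed by a
    greedy forward traceback.  ``ties_encountered`` counts choice points
    where more than one option achieved the local optimum.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; expected one of {MODES}")
    code = code or GeneticCode.standard()
    graph = build_graph(protein, code, append_stop)
    layers = graph.layers
    exact = table.discretized
    n = len(layers)

    # suffix[i][j] = minimal transformed cost of any path from node j of
    # layer i through to the last layer
    suffix: list[list[float]] = [[0.0] * len(layer) for layer in layers]
    states = 0
    ties = 0
    for i in range(n - 2, -1, -1):
        here, nxt = layers[i], layers[i + 1]
        for j, a in enumerate(here):
            best = None
            nbest = 0
            for k, b in enumerate(nxt):
                cand = _edge_cost(mode, table.scores[(a, b)]) + suffix[i + 1][k]
                if best is None or cand < best:
                    if best is not None and _is_tie(cand, best, exact):
                        nbest += 1
                    else:
                        nbest = 1
                    best = cand
                elif _is_tie(cand, best, exact):
                    nbest += 1
            suffix[i][j] = best  # type: ignore[assignment]
            ties += nbest > 1
        states += len(here) * len(nxt)

    opt = min(suffix[0])
    ties += sum(1 for v in suffix[0] if _is_tie(v, opt, exact)) > 1

    # mode "unbiased" on an integer table: among primary-optimal paths pick
    # the signed total nearest zero (ties: non-negative before negative),
    # via an achievable-suffix-totals set DP restricted to optimal edges
    required_total: int | None = None
    totals: list[list[frozenset[int]]] | None = None
    if mode == "unbiased" and exact:
        totals = [[frozenset()] * len(layer) for layer in layers]
        totals[n - 1] = [frozenset({0})] * len(layers[n - 1])
        for i in range(n - 2, -1, -1):
            here, nxt = layers[i], layers[i + 1]
            for j, a in enumerate(here):
                acc: set[int] = set()
                for k, b in enumerate(nxt):
                    s = table.scores[(a, b)]
                    if abs(s) + suffix[i + 1][k] == suffix[i][j]:
                        acc.update(s + t for t in totals[i + 1][k])
                totals[i][j] = frozenset(acc)
        reachable = set().union(
            *(
                totals[0][j]
                for j in range(len(layers[0]))
                if suffix[0][j] == opt
            )
        )
        required_total = min(reachable, key=lambda t: (abs(t), t < 0))

    # greedy forward traceback: lexicographically smallest path consistent
    # with the optimum (layers are stored in codon order)
    path: list[str] = []
    cur = None
    remaining = opt
    rem_total = required_total
    for j, a in enumerate(layers[0]):
        if not _is_tie(suffix[0][j], opt, exact):
            continue
        if rem_total is not None and rem_total not in totals[0][j]:  # type: ignore[index]
            continue
        cur = j
        break
    assert cur is not None
    path.append(layers[0][cur])
    for i in range(n - 1):
        a = layers[i][cur]
        chosen = None
        for k, b in enumerate(layers[i + 1]):
            s = table.scores[(a, b)]
            cand = _edge_cost(mode, s) + suffix[i + 1][k]
            if not _is_tie(cand, remaining, exact):
                continue
            if rem_total is not None and (rem_total - s) not in totals[i + 1][k]:  # type: ignore[index]
                continue
            chosen = k
            remaining = suffix[i + 1][k]
            if rem_total is not None:
                rem_total -= s
            break
        assert chosen is not None
        cur = chosen
        path.append(layers[i + 1][cur])

    cds = CodingSequence(tuple(path))
    total, junctions = table.score_sequence(cds)
    objective = -opt if mode == "best" else opt
    return OptimizationResult(
        cds=cds,
        total_score=total,
        junction_scores=tuple(junctions),
        mode=mode,
        states_explored=states,
        ties_encountered=ties,
        table_provenance=table.provenance,
        objective_value=objective,
    )


def brute_force_oracle(
    protein: str,
    table: CodonPairScoreTable,
    mode: str = "best",
    code: GeneticCode | None = None,
    append_stop: bool = False,
    cap: int = 10**6,
) -> OptimizationResult:
    """Exhaustive enumeration over every candidate coding sequence.

    Independent check for :func:`optimize`: applies the same objective and
    the same tie-breaking (path read as a codon tuple), so on any instance
    within the cap both return identical scores and identical paths.
    Refuses instances whose candidate count exceeds *cap* -- the
    combinatorial explosion the DP exists to avoid.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; expected one of {MODES}")
    code = code or GeneticCode.standard()
    graph = build_graph(protein, code, append_stop)
    count = math.prod(len(layer) for layer in graph.layers)
    if count > cap:
        raise SizeError(
            f"{count} candidate combinations exceed the enumeration cap {cap}"
        )
    exact = table.discretized

    def key(path: tuple[str, ...]):
        junctions = [table.scores[(a, b)] for a, b in zip(path, path[1:])]
        total = sum(junctions)
        if mode == "best":
            primary = (-total,)
        elif mode == "worst":
            primary = (total,)
        elif exact:
            primary = (sum(abs(s) for s in junctions), abs(total), total < 0)
        else:
            primary = (sum(abs(s) for s in junctions),)
        return primary + (path,)

    paths = list(product(*graph.layers))
    best_path = min(paths, key=key)
    best_key = key(best_path)
    n_opt = sum(1 for p in paths if key(p)[:-1] == best_key[:-1])
    total, junctions = table.score_sequence(best_path)
    objective = best_key[0] if mode != "best" else -best_key[0]
    return OptimizationResult(
        cds=CodingSequence(best_path),
        total_score=total,
        junction_scores=tuple(junctions),
        mode=mode,
        states_explored=len(paths),
        ties_encountered=n_opt - 1,
        table_provenance=table.provenance,
        objective_value=objective,
    )
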