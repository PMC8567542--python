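"""Seeded generator of synthetic test inputs.

Everything the suite needs -- random proteins, random discretized score
tables, random usage tables -- is produced here deterministically from a
seed, so no download or external database is ever required.  Generated
score tables draw each of the 4096 cells i.i.d. from {-2,-1,0,1,2}; by
default the three classes are weighted like the rule-derived map
(1/8 rejected, 1/8 preferred, 3/4 neutral).  Proteins are uniform over the
20 standard residues.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .cub_optimizer import CodonUsageTable
from .errors import ParameterError
from .fasta_io import write_fasta
from .genetic_code import GeneticCode
from .pair_scoring import ALL_CODONS, CodonPairScoreTable

#: default cell-value distribution over scores -2..2
DEFAULT_SCORE_PROBS = (0.0625, 0.0625, 0.75, 0.0625, 0.0625)

__all__ = [
    "FixtureSpec",
    "random_protein",
    "random_score_table",
    "random_usage_table",
    "generate_fixtures",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one reproducible fixture set."""

    seed: int = 0
    n_proteins: int = 5
    min_length: int = 3
    max_length: int = 6
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
    score_values: tuple[int, ...] = (-2, -1, 0, 1, 2)
    score_probs: tuple[float, ...] = DEFAULT_SCORE_PROBS

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ParameterError("invalid protein length range")
        if len(self.score_values) != len(self.score_probs) or not np.isclose(
            sum(self.score_probs), 1.0
        ):
            raise ParameterError("score distribution must sum to 1")


def random_protein(rng: np.random.Generator, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def random_score_table(
    rng: np.random.Generator,
    values: tuple[int, ...] = (-2, -1, 0, 1, 2),
    probs: tuple[float, ...] = DEFAULT_SCORE_PROBS,
) -> CodonPairScoreTable:
    draws = rng.choice(values, size=4096, p=probs)
    scores = {
        (c5, c3): float(draws[i * 64 + j])
        for i, c5 in enumerate(ALL_CODONS)
        for j, c3 in enumerate(ALL_CODONS)
    }
    return CodonPairScoreTable(scores, provenance="synthetic random table")


def random_usage_table(
    rng: np.random.Generator, code: GeneticCode | None = None
) -> CodonUsageTable:
    code = code or GeneticCode.standard()
    usage = {c: float(f) for c, f in zip(ALL_CODONS, rng.random(64) + 1e-3)}
    return CodonUsageTable(usage, code=code, provenance="synthetic random usage")


def generate_fixtures(spec: FixtureSpec, outdir: str) -> dict[str, str]:
    """Write proteins FASTA + score/usage TSVs; same seed, same bytes.

    Returns the mapping of fixture name to written path.
    """
    rng = np.random.default_rng(spec.seed)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "proteins": os.path.join(outdir, "proteins.faa"),
        "score_table": os.path.join(outdir, "score_table.tsv"),
        "usage_table": os.path.join(outdir, "usage_table.tsv"),
    }
    lengths = rng.integers(spec.min_length, spec.max_length + 1, size=spec.n_proteins)
    records = [
        (f"protein_{i + 1}", random_protein(rng, int(n), spec.alphabet))
        for i, n in enumerate(lengths)
    ]
    write_fasta(records, paths["proteins"])
    random_score_table(rng, spec.score_values, spec.score_probs).to_tsv(
        paths["score_table"]
    )
    random_usage_table(rng).to_tsv(paths["usage_table"])
    return paths
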