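# codonopt

Codon-pair-context optimization of coding sequences for heterologous
protein expression, by exact dynamic programming over a layered codon
graph.

## The problem

A protein of K residues can be back-translated into
∏ᵢ |rᵢ| distinct coding sequences, where |rᵢ| is the number of synonymous
codons of residue i (up to 6 under the standard code) — already over a
million candidates at twenty two-fold-degenerate residues. Classical codon
optimization sidesteps the combinatorics by picking each residue's most
frequent host codon independently (codon usage bias, CUB), but ignores
*codon-pair context*: hosts such as *Pichia pastoris* strongly favor or
reject particular ordered juxtapositions of adjacent codons, which affects
translational elongation and hence expression.

`codonopt` scores every ordered 5′–3′ codon pair with a 64×64 context
table (negative = rejected context, positive = preferred, 0 = neutral;
published maps discretize to −2…2) and finds the coding sequence whose
junction-score total is exactly optimal. The protein is arranged as a
layered graph G — one layer per residue, nodes the synonymous codons,
complete bipartite scored edges between consecutive layers — and the
optimum path is found by dynamic programming whose work equals the
state-space size

    S = Σᵢ₌₁ᴷ⁻¹ |rᵢ| · |rᵢ₊₁|,

linear in K for the standard code. Modes: `best` (maximize the total),
`worst` (minimize it; the deoptimized control), `unbiased` (most
context-neutral: minimal Σ|junction score|, then total nearest zero), and
`cub` (the classical per-residue comparator). Diagnostic reports classify
every junction (rejected/preferred/neutral), lay the codons into the
16-column context grid, and tally synonymous-codon usage per amino acid.

A built-in default table encodes the four context rules observed in the
*P. pastoris* codon-pair map (5′ codon ending T is rejected before A… and
favored before G…; ending C is rejected before G… and favored before A…);
any user 64×64 table loads from TSV with identical downstream behavior.

## Worked example

```python
>>> import codonopt as co
>>> code = co.GeneticCode.standard()
>>> code.candidate_combination_count("MQVT")      # 1 × 2 × 4 × 4
32
>>> g = co.build_graph("MQVT")
>>> [len(layer) for layer in g.layers], g.state_space_size
([1, 2, 4, 4], 26)
>>> table = co.CodonPairScoreTable.from_rules()
>>> result = co.optimize("MQVT", table, mode="best")
>>> result.cds.dna, result.total_score
('ATGCAAGTCACA', 1)
```

The four layers hold the synonymous codons of M, Q, V, T; the DP examines
S = 1·2 + 2·4 + 4·4 = 26 edge states instead of 32 whole candidates (the
gap widens exponentially with length). The best path scores +1: its only
scorable junction under the rule table is GTC→ACA, a preferred C→A
context; the brute-force oracle (`co.brute_force_oracle`, feasible here
with 32 candidates) confirms both the score and the path.

From the shell:

```sh
codonopt optimize --mode best --in protein.faa --table default-rules
codonopt report --in designed.fna --prefix out/report
codonopt fixtures --seed 42 --outdir fixtures/
```

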