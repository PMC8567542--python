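# Methods

## Model

A coding sequence for a protein of K residues is a path through a layered
graph: layer i holds the synonymous codons rᵢ of residue i (1–6 under the
standard nuclear code, NCBI table 1), and every node of layer i connects
to every node of layer i+1 with weight equal to the context score of that
ordered codon pair. The total score of a coding sequence is the sum of its
K−1 junction scores; a single codon scores 0. The feasible set has
∏|rᵢ| elements, but the optimum decomposes over prefixes (optimal
substructure), so a dynamic program solving each per-node sub-problem once
finds the exact optimum with work equal to the number of edges,
S = Σ|rᵢ|·|rᵢ₊₁| ≤ 36(K−1) — linear in K because layer widths are bounded
by 6.

Score tables are total maps over all 4096 ordered codon pairs. Sign is
the classification contract: negative = rejected context, positive =
preferred, zero = neutral. Published context maps discretize to integers
−2…2; the engine accepts arbitrary reals and records integrality in a
`discretized` flag (integer tables are accumulated in exact arithmetic).
The shipped default table is derived from the four context rules of the
*Pichia pastoris* codon-pair map — (5′ …T, 3′ A…) and (5′ …C, 3′ G…)
rejected, (5′ …T, 3′ G…) and (5′ …C, 3′ A…) favored, magnitude 1 by
default. Each rule fixes one base of each codon, so each covers 16×16
pairs: 512 rejected, 512 preferred, 3072 neutral cells. Junctions
involving stop codons are scored by the same rules (all three stops start
with T, so no rule ever fires into a stop under the default table); a
loaded table may score them however it likes.

## Objectives

* **best** — maximize the total context score (the design output).
* **worst** — minimize it (the deoptimized control). Implemented by the
  same DP; `worst(T)` coincides with `best(−T)` and the suite asserts the
  duality.
* **unbiased** — the most context-neutral design: minimize Σ|junction
  score|. Among ties, the signed total nearest zero is selected
  (non-negative before negative at equal magnitude). That secondary key is
  not edge-decomposable, so it is resolved exactly for integer tables by a
  second backward pass that propagates the set of signed totals achievable
  along primary-optimal suffixes (sets are bounded by the integer score
  range, ≤ 4K+1 values per node). For continuous tables the achievable
  totals are not finitely enumerable and the secondary key is skipped;
  ties then fall through to the lexicographic rule below. "Unbiased" is
  this package's construction; the term is used in the field for
  context-neutral reference designs without a standard definition.
* **cub** — the classical comparator: each residue independently mapped
  to its most frequent synonymous codon in a host usage table (fractions
  normalized within each synonymous set; arg-max, ties lexicographic).
  One codon per amino acid by construction. Because it picks one member
  of the same feasible set the DP searches, its context total is always
  bounded by the worst- and best-mode totals.

## Determinism and tie-breaking

All remaining ties resolve to the lexicographically smallest whole codon
path (A < C < G < T, path compared left to right). The DP achieves this
exactly: a backward pass computes each node's optimal suffix value, then a
greedy forward traceback at each layer takes the smallest codon whose
suffix value is consistent with the global optimum. This global rule — 
rather than a per-backpointer one — makes the result bit-comparable with
the independent brute-force oracle, which enumerates every candidate and
minimizes (objective key, path tuple). The oracle refuses instances above
a configurable candidate cap (default 10⁶) and is the verification route
throughout the suite; it never backs the production path.

Numerical choices: integer tables compare exactly; continuous tables use
an absolute tie tolerance of 1e−9 (tie detection and traceback
consistency). `ties_encountered` counts choice points with more than one
local optimum so users can detect degenerate tables. Degenerate inputs:
empty proteins, internal stops and non-standard symbols are rejected with
typed errors; a single-residue protein yields a one-layer graph with
S = 0; `'*'` as final residue (or `append_stop=True`) adds a stop layer
whose codon is chosen by the same DP.

## Reports

The pair-context report classifies each junction by score sign, checks
the conservation law (class counts sum to codon count − 1), and lays the
codons row-major into a 16-column grid — first codon upper-left, last
(the stop, for a full design) in the final cell, last row ragged —
rendered as text or minimal HTML with the red/green/black convention and
|score|-proportional intensity for discretized tables. The
synonymous-usage report tallies distinct codons per amino acid for
residues occurring at least `min_count` times (default 10; set 1 to
report all). All TSV coordinates are 1-based codon positions.

## Synthetic data

No external database is consulted. The fixture generator draws proteins
uniformly over the 20 standard residues and score tables i.i.d. per cell
from {−2…2} with weights (1/16, 1/16, 3/4, 1/16, 1/16), matching the
class balance of the rule-derived map (1/8 rejected, 1/8 preferred, 3/4
neutral); usage tables draw uniform positive frequencies. Defaults
(5 proteins of length 3–6) keep every fixture within the brute-force
cap so the oracle can cross-check all of them. What this does not
emulate: the empirical block structure of real context maps (rules act on
the wobble/first bases, giving strong 16×16 block correlation), real
amino-acid composition, and any relationship between usage frequencies
and context scores — so passing tests demonstrate algorithmic
correctness, not expression outcomes. The genuine supplementary score
table of the published *P. pastoris* map is not bundled; users supply it
(or any 64×64 table) as TSV in either the long-triples or dense-matrix
dialect.

## Problem sizes

The property suites run 200 oracle-equivalence trials (proteins of length
3–6, fresh random tables, all three DP modes round-robin) and 50
ordering/duality trials (lengths 3–8); report checks use an 80-residue
design. These sizes keep exhaustive enumeration cheap while exercising
every layer-width combination of the standard code.

## Limitations

* One objective at a time: no joint CUB+CPB optimization, no GC-content,
  mRNA-structure or forbidden-motif (restriction-site) constraints — the
  edge set is never pruned.
* No derivation of context scores from a CDS corpus; tables are inputs.
* No CAI, tRNA-adaptation index or codon harmonization.
* Standard nuclear code by default; alternative codes can be supplied but
  selenocysteine/pyrrolysine readthrough is unsupported.
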