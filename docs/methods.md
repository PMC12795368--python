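# Methods

## Model

A database search reports a peptide as a letter sequence plus free-text
variable modifications. Two modification families leave the observed
monoisotopic mass compatible with other letter sequences:

* deamidation, N→D and Q→E, each adding one deamidation shift
  (0.98402 Da, the exact mass(D)−mass(N) = mass(E)−mass(Q) difference);
* N-terminal pyroglutamate, reachable from Q by loss of NH₃ and from E by
  loss of H₂O, making the three N-terminal states Q−NH₃ / pyroGlu / E−H₂O
  isobaric.

Given a validated sequence and its parsed modification profile
(deamidation event count `d`, pyroGlu-from-Q / pyroGlu-from-E flags), the
engine enumerates every isobaric permutation in three stages:

1. **Deamidation.** Every subset of the N/Q positions of size 0..min(d, s₁)
   is substituted N→D / Q→E. The bound is `d` because only a *deamidated*
   N/Q is isobaric with D/E; an unmodified N/Q is 0.984 Da lighter and the
   permutation would not match the observed mass. An N-terminal Q carrying
   pyroGlu is excluded (stage 3 owns that position).
2. **Reverse deamidation.** On each stage-1 result, every subset of the
   input's D/E positions is substituted D→N / E→Q, with no size bound (an
   unmodified D/E is isobaric with a deamidated N/Q at the same position).
   Stage-1-altered positions are untouched — automatic, since stage 1 acts
   on N/Q letters and stage 2 on D/E letters of the *input*. An N-terminal
   E carrying pyroGlu is excluded.
3. **PyroGlu swap.** If a pyroGlu flag is set, each stage-2 result also
   spawns the variant with the first letter swapped (Q↔E); both forms are
   kept.

The three stages act on disjoint position sets, so distinct substitution
choices always produce distinct sequences; deduplication is a formality
and the closed form

```
count = ( Σ_{k=0..min(d,s₁)} C(s₁,k) ) · 2^{s₂} · (2 if pyroGlu else 1)
```

equals the enumerated set size exactly. The test suite checks this, and
set-level equality with an independent brute-force enumerator, over a
randomized grid of short peptides.

**Identity convention.** The permutation set contains the unchanged
sequence whenever at least one substitutable site exists, and is empty
otherwise. This is the only convention consistent with the published
benchmark counts (a 7-Q/6-DE peptide with d=3 gives
(1+7+21+35)·2⁶ = 4096 including the empty substitution, while peptides
with no D/E, no detected deamidation and no pyroGlu have zero MISPs).
Downstream, the identity is *excluded* from LCA comparison and category
assignment — it trivially has the input's LCA — but *included* in the
`total_misps` count column.

**Mass bookkeeping.** Residue masses come from `pyteomics.mass`. For every
permutation, base mass(permutation) − base mass(input) must equal
m × 0.98402 Da with m = |stage-1 subset| − |stage-2 subset|
(±1 for the pyroGlu swap), within 1e-3 Da; this is asserted as an
invariant, not assumed.

## Taxonomic comparison

An LCA is carried with its full root→leaf lineage over the canonical
27-rank NCBI/Unipept order; unranked levels are absent rather than padded.
Taxon `a` is an ancestor of `b` iff `a`'s taxon-id chain is a strict
prefix of `b`'s — rank names are never compared, since ranks can be
missing. This yields four mutually exclusive relations (identical / more
specific / less specific / different) that are antisymmetric by
construction and are tested against a direct tree-ancestry oracle on a
synthetic taxonomy.

Per peptide, relations roll up with priority
**less specific > different > more specific**: one less-specific MISP
undermines a specific taxonomic claim regardless of other matches, so it
dominates; a wholly different lineage is ranked above more-specific
because it is the more consequential finding for interpretation. If every
MISP LCA is identical to the input's, the peptide is `all_identical`; with
no MISP LCAs at all it is `no_alternate`. A MISP LCA appearing when the
input peptide itself has no LCA is anomalous; it is reported as
`different` with an explanatory note rather than inventing semantics.

## Manual-check flag

The engine sees sequences, not MS2 ion coverage, so when the search
software detected fewer deamidation events than the peptide has
deamidatable N/Q residues, the events could sit at several positions and
some generated MISPs may be unsupported by the actual spectrum. A peptide
is flagged for manual verification iff all three hold: `d` < number of
N/Q residues (excluding an N-terminal Q claimed by pyroGlu), `d` ≠ 0, and
its MISPs resolved to ≥ 2 distinct LCAs. The full truth table is tested.

## LCA backends

* **unipept** — batched POSTs (default 90 peptides/request, below common
  public-API limits) over a thread pool (default 8 lanes, one persistent
  session each); transient failures (timeout, connection reset, 5xx, 429)
  retried up to 3 times with exponential backoff `base·2^(n−1)`; other 4xx
  abort as configuration errors. Peptides shorter than 5 or longer than 50
  residues are not sent (service-side constraints) and are reported
  unresolved with a reason. Unresolved-after-retries is kept distinct from
  no-match so failure cannot masquerade as taxonomic absence. I/L equating
  is off by default — treating them as distinct is the conservative choice
  for taxonomic specificity; `--equate-il` enables service-side equating.
* **offline** — a TSV of peptide → (taxon, rank, lineage). Interchangeable
  with the live backend behind the same contract; all tests and the
  acceptance checks run against it with no network.

## Synthetic data

The fixture generator builds a deterministic full k-ary toy taxonomy
(default depth 4, branching 3, ranks in canonical order), then draws
peptides of 7–16 residues with N/Q/D/E oversampled to 40% of positions —
uniform residue draws rarely produce the multi-site cases the engine
exists for — with 0–3 deamidation events and pyroGlu probability 0.15.
Each peptide is planted into one scenario (no MISP LCAs, all-identical,
different, more-specific, less-specific, or a less+more mix) by assigning
its input sequence and a few of its MISPs to tree nodes; the per-peptide
{input ∪ MISPs} sequence sets are kept globally disjoint so planted table
entries cannot cross-contaminate another peptide's lookup. The manifest of
expected outcomes is computed analytically (closed-form counts, direct
tree-ancestry relations), never by running the pipeline, and an end-to-end
offline run must reproduce it byte-stably across thread counts.

What the generator does not emulate: real protein sequence structure,
search-engine scoring noise, uneven database taxon coverage, or LCA drift
as databases grow. Passing tests therefore demonstrate that the screening
logic is correct, not that any particular organism is detectable in real
data.

## Numerical and formatting conventions

* Positions are 1-based with the N-terminus at position 1.
* Permutation output order is lexicographic by sequence; all output files
  are byte-stable for a given input (fixed column order, LF endings).
* Dataset statistics: median is the lower middle for even n; mode breaks
  ties toward the smallest value; the mean MISP count is truncated (not
  rounded) to one decimal — 14629 permutations over 1076 peptides prints
  as 13.5.
* Per-peptide permutation cap: 10⁶ (non-strict: truncate and warn).
  Realistic inputs top out in the low thousands; the cap only guards
  pathological sequences.
* A deamidation count exceeding the number of N/Q sites is tolerated (the
  effective bound becomes the site count) so curated tables whose
  modification column disagrees with the sequence do not abort batch runs.

## Limitations

Only deamidation- and pyroGlu-induced permutations are screened; other
isobaric substitutions (e.g. Ala↔Ser with hydroxylation chemistry) are out
of scope, as are site-specific deamidation probabilities — all permutations
are reported regardless of likelihood, on the rationale that anything
chemically possible should be screened. Automated LCAs inherit the
database and algorithm of the backend; they can differ from manual
BLAST-based assignment and drift over time, so alternate LCAs found here
are leads for manual verification, not final claims.
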