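# Methods

## Seed-match prediction

Prediction is pure pattern matching between the first eight nucleotides
of each mature miRNA (its 5' seed region) and every complete 8-nt window
of the target sequence; window starts run 1..L−7, each evaluated
independently per miRNA, and at most one site is reported per
(miRNA, window). Classification walks a fixed hierarchy: window
position 1 against miRNA position 8 first; if paired, positions 2–6
against 7–3 are mandatory and position 7 against 2 separates OS-6mer
(unpaired) from 8mer/7mer-m8 (split on a literal adenosine at window
position 8); if position 1 is unpaired, positions 2–7 against 7–2 are
mandatory and the adenosine test separates 7mer-A1 from 6mer. The w8
adenosine is a property of the sequence, not a pairing — 8mer and
7mer-A1 sites keep their A even opposite a miRNA whose position 1 would
not pair it.

Watson–Crick pairs are A:U(T), U(T):A, C:G, G:C; T and U are
interchangeable throughout, so DNA input need not be converted. When
G:U wobbles are enabled, at most one wobble (sequence T/U vs miRNA G, or
sequence G vs miRNA U) may substitute for one Watson–Crick pair per
window; the single-wobble budget is consumed greedily in evaluation
order (w1, then w2..w6, then w7) with no backtracking. Because pairing
outcomes per position are deterministic, ordering only matters for which
position the budget is spent on; a window that classifies perfectly is
never altered by enabling wobbles (wobbles are only consulted where
Watson–Crick pairing fails).

Consequences worth knowing:

- Only complete 8-nt windows are scanned, so a 6mer/7mer core lying
  entirely inside the final 7 nt of the sequence is not reported. Users
  placing mutation sites near the 3' end should pad their input with
  real downstream sequence.
- Ambiguity codes (N, R, Y, …) are rejected at input validation rather
  than treated as non-pairing; a silently unmatchable base inside a
  mutation site would be misleading.
- Only the given strand is scanned; miRNA targeting acts on the mRNA
  sense strand.
- The predictor is intentionally over-predicting (no thermodynamics,
  accessibility, conservation or context scoring). That is the right
  bias for this tool: any motif with the potential to be functional must
  be avoided in the mutant. It is the wrong bias for target discovery,
  for which dedicated predictors should be used.

## Mutation sites, regions and the candidate space

A mutation site is the 6-nt core complementary to miRNA positions 2–7,
anchored by the user at the position opposite miRNA position 7 (span
`[anchor, anchor+5]`). Since the largest recognized site is 8 nt, two
spans separated by at least 7 intact nucleotides can never co-occupy one
window; spans closer than that (gap = next start − previous end − 1 < 7,
including overlap) are merged into one mutationally independent region
and mutated as a unit, while all other regions stay byte-identical.

A strategy is (allowed bases ⊆ {A,C,G,T}, changes per site ∈ 2..6,
adjacency flag). "n changes per site" means *exactly* n changed
positions forming one adjacent run within the site span (one admissible
run per site; runs of overlapping sites may be shared but every span
must contain a complete run); a change must install an allowed base
different from the original, so positions whose original base is the
only allowed base kill every run through them. Adjacency can be turned
off, replacing runs by arbitrary n-subsets of the span. Exactly-n
rather than at-least-n is the deliberate reading: it minimizes the
altered surface and therefore the illegitimate-site risk; at-least-n is
recoverable by running the larger n values separately.

Counting: for non-overlapping sites the space is the product over sites
of Σ<sub>runs</sub> Π<sub>positions</sub> |allowed ∖ {original}| — exact,
because distinct runs/base choices always yield distinct sequences (every
changed base differs from the original, so the changed set is readable
off the diff). Overlapping sites are counted by explicit enumeration
with deduplication, since shared positions make the closed form
over-count. With all four bases allowed and two adjacent changes this
gives 45 candidates per site (5 runs × 3 × 3) independent of sequence
content, 45³ = 91,125 ≈ 9 × 10⁴ for a region of three non-overlapping
sites — versus (Σ<sub>k=2..6</sub> C(6,k)·3<sup>k</sup>)³ = 4077³ ≈
6.8 × 10¹⁰ if any combination of two or more changes were allowed —
which is the whole argument for adjacency and for solving regions
independently.

Generation is a seeded random draw → constraint filter → dedup loop,
with an exhaustive-enumeration fast path (shuffled, so downstream
selection is not biased toward low-index runs) whenever the space is at
most 10⁶ candidates. On the sampling path, attempts are capped at
min(100 × space, 10⁷) draws; hitting the cap yields an explicit
"exhaustion uncertain" status distinct from true exhaustion. Streams
are deterministic per seed; per-region seeds are derived from the
project seed so regions are independent but the whole project is
reproducible byte-for-byte.

## Validity

Candidates are evaluated on the **full** mutant sequence, not the
region alone, so windows straddling the region boundary are covered.
The illegitimate set is the mutant's predictions minus the input's,
keyed by (miRNA id, window start) — substitution-only mutagenesis
preserves coordinates, making the positional key sound. A site-type
change at an occupied position (7mer-m8 → 8mer) is therefore not
illegitimate by default; `strict_type_diff` adds the type to the key for
users who want it flagged. G:U handling is symmetric between input and
mutant predictions — an asymmetric setting would fabricate or hide
diffs. The policy bans chosen (site type, perfect/single-G:U)
combinations; anything unlisted is permitted.

Each region's search stops at five valid mutants (the displayed cap) or
exhaustion; a region exhausted with zero valid mutants is surfaced as a
nonzero exit advising a different strategy. After per-region selection,
the assembled sequence is re-verified globally (predict, diff, policy)
and assembly fails closed on any banned new site — impossible when
inter-region gaps are ≥ 7 nt, so a failure indicates a partitioning bug
rather than bad luck. Residual weaker sites for the *targeted* miRNA
(e.g. a surviving wobble 6mer) are reported in the mutant-predictions
table rather than auto-rejected: disruption rests on ≥ 2 core changes,
not on prediction absence.

## Synthetic fixtures

`imirp.fixtures` emulates the inputs the tool sees in practice at desk
scale: a uniform-random background sequence (~100–200 nt, comparable to
the UTR segments used in reporter work), planted seed sites of
controlled types and spacings, a mature.fa-dialect database of random
decoy miRNAs, and optionally a trap miRNA whose seed matches exactly one
specific candidate mutation of one site. Backgrounds are screened by
running the predictor itself — decoys are individually re-drawn until
they match nothing, and the whole fixture is rejected unless predictions
equal exactly the planted set — so fixtures stay valid if site
definitions are ever extended. Planted target seeds are derived from
the sequence (complement of the window) rather than planted over it,
which lets overlapping sites coexist without conflicting constraints;
the forward construction (`plant_site`) is used for predictor-recovery
testing. Uniform base composition means fixtures do not reproduce the
AU-richness, conservation structure or repeat content of real 3'UTRs:
passing tests demonstrate the combinatorial and bookkeeping logic, not
biological site efficacy, which is the reporter assay's job.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere, matching how biologists
  enter positions; windows occupy `[start, start+7]`.
- Internal miRNA alphabet is RNA (T→U on import, as miRBase stores);
  target sequences keep their input alphabet and outputs mirror it.
- Species is inferred from the id prefix (miRBase convention), robust
  across mature.fa header dialects; any mature.fa-dialect file is
  accepted — "high-confidence" membership is a property of the supplied
  file, not recomputed.
- miRNA records shorter than 8 nt are skipped (cannot seed-match);
  duplicate ids are kept with a warning since prediction keys include
  the position.
- Non-interactive selection defaults to the first valid mutant per
  region (lowest generation index) for deterministic batch behaviour;
  interactive choice is available in the CLI.
- Reports carry a deterministic run identifier (digest of the full
  configuration) so re-running a project reproduces every output byte.
- Test and acceptance workloads use ~60–200 nt sequences, miRNA sets of
  ~10–20 records, and exhaustive enumeration for spaces up to ~10⁴ —
  sizes at which every check is exact and the whole suite runs in
  seconds.

## Limitations

- Insertions and deletions are unsupported; an indel-capable version
  would need an alignment-aware illegitimacy key.
- Site types beyond the five canonical ones (6merα, G-bulge, seedless
  3'-compensatory sites) are not identified, and no
  polyadenylation-motif or RNA-structure checks are performed.
- Valid mutants are not ranked; up to five per region are shown and the
  choice is the user's.
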