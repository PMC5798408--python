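# Methods

## Motif model

All motifs are fixed-length patterns over literal residues, residue classes
and pure wildcards; no position-weight matrices or HMMs are used. Spans are
1-based inclusive. Ambiguity codes (X/B/Z/U) never satisfy a literal or
residue-class position; only pure wildcard positions accept them — a
deliberately conservative calling rule, so an ambiguous residue can never
*create* a motif.

**Di-arginine retrieval signals.** A motif is a pair of arginines at
separation 1 (`RR`), 2 (`RxR`) or 3 (`RxxR`); the wildcard may itself be R.
Because overlapping arginine clusters admit several counting conventions,
both are implemented. The default, *greedy*, scans N- to C-terminal and
pairs each unconsumed R with its nearest downstream R at distance ≤ 3,
consuming both: each arginine participates in at most one motif, so `RRRR`
counts 2, not 6. *all_pairs* enumerates every qualifying pair (`RRRR` → 6).
Greedy is the default because it does not inflate one cluster into many
motifs; both modes are exposed and the report records which was used.

**C-terminal retrieval signals.** Only the final five residues are
inspected, in priority order `KKxx`, `KxKxx`, `RKxx`, `RxKxx`, `KxRxx`,
`HxHxx`, `KxHxx`; the first match is reported, at most one per protein —
family statistics need only presence/absence, and the variants are
functionally equivalent retrieval signals. Sequences shorter than five test
only the patterns that fit. Appending residues N-terminally can never change
the result (tested as a property).

**Active-site blocks.** C1 is `K-x6-R-P` (9 residues); C2 is
`[S/T]-[middle]-H` with middle defaulting to {G,S,D,T,L} (G is canonical; S,
D, T and L are observed in active relatives); C3 is `H-x-x-x-[third]` with
third defaulting to {D,E,Q,H}. The `[K]xNØØN` motif is matched as
wildcard-wildcard-N-Ø-Ø-N with Ø = {F,I,L,V}, recording whether the first
position carries the predominant K. Residue classes are configurable. The
loop 3/4 cysteine pair is reported as one hit spanning the first to last
cysteine of the region (count recorded) whenever at least two are present.

**Scanning scope.** When a topology is available, active-site blocks are by
default restricted to luminal loops (the catalytic centre always faces the
lumen) and the cysteine-pair detector runs on loop 3/4 only; di-arginine
hits are assigned to loops and counted cytoplasmic-only or in total. A hit
that straddles a membrane boundary belongs to no loop and is excluded from
side-filtered counts. Without a topology the whole sequence is scanned and
only total counts are produced.

## Topology

A topology is a per-residue string over `i`/`M`/`o`; TMDs are maximal `M`
runs, loops alternate sides across each membrane span (violations are
rejected), and loop *k/(k+1)* lies between TMD k and k+1. Supplied
topologies (two-column TSV or TOPCONS-style consensus blocks; reentrant
`I`/`O` states collapse to `i`/`o`) always override prediction, so
externally predicted topologies reproduce their motif counts exactly.

The built-in predictor is a classic single-sequence heuristic, not a
machine-learning model: mean Kyte–Doolittle hydropathy in a 19-residue
sliding window, centres at or above 1.6 marked as membrane; marked runs
merged across gaps ≤ 3, expanded outward over contiguous residues whose own
hydropathy is ≥ 1.6 (charged flanking residues depress edge windows and
would otherwise truncate helix ends), trimmed symmetrically to ≤ 25 and
discarded below 15. Orientation follows the positive-inside rule: the
assignment (N-terminus in or out) maximising K+R over cytoplasmic-loop
residues within 15 of a TMD end wins; ties default to a cytoplasmic
N-terminus; whole-loop counting is a config option. The predictor is
deterministic. It makes no attempt at signal peptides or reentrant helices.

## Triad assembly and classification

C2 contributes H-1, C3 contributes H-2 with the third triad residue fixed at
H-2+4. With a topology, C2 must sit in a luminal loop and C3 in a *later*
luminal loop (in the 6-TMD architecture C2 closes loop 3/4 and C3 sits in
loop 5/6); same-loop pairs are rejected rather than guessed. Without a
topology any C3 strictly downstream of a C2 is eligible. Among eligible
pairs the one maximising the extended-consensus context score wins, ties
resolved to the smallest H-2 position, then the smallest separation — the
conservation context is what identifies the genuine site when decoys exist.

The context score counts matches to the 14-position extended consensus
`TAØYF-H-TØØ-E-KØØG` (offsets −5…+8 around H-2); out-of-range positions
simply do not score. F at −1 and K at +5 are additionally flagged as the
most conserved satellite positions.

Classification is a total function applied in order: missing block →
`incomplete`; H-2 substituted → `likely_inactive` (the pseudo-enzyme
signature — H-2 is essential for all activity and is always N or S in
LPR/PRG pseudo-enzymes); H-1 substituted → `likely_inactive` by default
(`FITM_variant` in lenient mode, since H-1 substitutions affect substrates
variably in bacterial homologues, but the yeast H-1-A mutant is
non-functional); then by the third residue: D → `LPT_canonical`, E →
`FITM_typical`, Q/H → `FITM_variant`, anything else → `likely_inactive`.

## Localization and family statistics

The localization rule is exactly: C-terminal signal (any variant — they are
counted together) or ≥ 2 di-arginine motifs → ER; exactly 1 → unsure; 0 →
not ER. It is applied to the cytoplasmic count when a topology is available
and to the total count otherwise, and the mode is recorded. The call is
monotone in the di-arginine count (tested as a property).

Family aggregation is purely descriptive — mean and population-SD of the
chosen di-arginine count, members with a C-terminal signal or [K]xNØØN —
with no inferential statistics. The pairwise contrast calls a family "more
ER-like" only when it has both the strictly higher mean and at least as high
a C-terminal-signal fraction; anything discordant is "mixed".

## Synthetic data

The generator exists to make every stage testable with *exact* ground
truth, and its composition model is chosen for that purpose, not for
realism. Loops are drawn uniformly from the background alphabet
`DEGNPQSTY`: hydrophilic residues excluding every motif-forming one (R, K,
H, C and the hydrophobic class F/I/L/V) and also excluding A and W — A
because its Kyte–Doolittle value (+1.8) exceeds the 1.6 window threshold,
so A-rich loops could seed or merge spurious predicted TMDs. TMDs (default
21 residues) are drawn from `LIVF`. Under these alphabets a planted 21-mer
helix yields a marked hydropathy run coinciding with the helix exactly, and
background can never complete a motif pattern on its own.

The one remaining leak — background residues *adjacent to a planted motif*
completing a second pattern (e.g. a background E four residues after a
planted C2 histidine forms a spurious C3) — is closed by a deterministic
repair pass that rescans the assembled sequence and resamples offending
background positions until no unplanned hit remains. Planted and membrane
residues are never touched; plantings whose own residues create extra hits
(motifs closer than ~6 residues, whose arginines cross-pair or whose
histidines complete each other's patterns) are rejected with an error
rather than silently mis-annotated. C-terminal signals must be planted
flush with the sequence end.

Families are per-site mutated copies of one generated protein (default
divergence 5%), substitutions drawn from the loop/TMD alphabet of the
position and never inside planted spans unless `mutate_motifs` is set —
so motif recovery and di-arginine counts survive divergence exactly, while
precision guarantees apply only to the unmutated parent. Member *i* derives
its RNG stream from (seed, *i*), making members independent of family size.

What passing tests on this generator do **not** show: performance on real
protein composition (real loops contain R/K/H/C/A and hydrophobic residues,
so real scans will contain incidental motif matches and the topology
predictor will make the usual single-sequence errors), behaviour on signal
peptides or reentrant helices, and any evolutionary realism (no indels, no
tree structure).

### Stand-ins for the yeast paralogues

No sequence accessions are bundled and the package fetches nothing, so the
published per-protein coordinates are exercised through two synthetic
stand-ins (`synthetic_standins.py`, both labelled synthetic) whose planted
anatomy reproduces them: the Scs3p-like construct (390 aa, 6 TMDs) carries
six di-arginine motifs in cytoplasmic loops and the extended C3 consensus
placing E-3 at 354; the Yft2p-like construct (275 aa, 6 TMDs) carries no
arginines, `SGH` ending at 178 (H-1), the consensus placing H-2 at 239 and
E-3 at 243, [K]xNØØN in loop 1/2 and a cysteine pair in loop 3/4. Tests on
them are planted-ground-truth recovery tests; they say nothing about the
natural sequences themselves.

### Study-condition cohort

The family-level analysis (and the acceptance script) builds a synthetic
cohort to the published family conditions: 40 Scs3p-like members whose
planted whole-sequence di-arginine counts average 3.7 (28 with four, 12
with three; 4 members carry KKxx) and 52 Yft2p-like members averaging 1.6
(31 with two, 21 with one; none with a C-terminal signal — with integer
counts and n=52 the closest attainable mean is 83/52 ≈ 1.596). Counts are
measured by the scanner in high-throughput mode (whole-sequence, no
topology link), not read from the construction.

## Numerical and design choices

* Hydropathy windows use full 19-residue windows only; the first and last 9
  residues cannot be window centres.
* Population SD (n denominator) so single-member families report SD 0.
* Zero-length terminal loops (sequences starting/ending inside the
  membrane) carry `span=None` and the geometrically implied side; interior
  zero-length loops cannot arise from a state string, since adjacent
  membrane runs merge.
* `n_term_side` is defined as the side of the first non-membrane state.
* The C-terminal-fraction ratio of a comparison is undefined (None) when
  the denominator fraction is zero.
* Problem sizes in the test suite and acceptance script (exhaustive R/A
  strings to length 12, 1,000 random 30-mers, 100 random synthetic specs,
  1,000 context windows) were chosen as the smallest sets that exercise
  every code path exhaustively where enumeration is feasible and densely
  where it is not; the whole suite runs in a few seconds.

## Known limitations

* The topology predictor is a hydropathy heuristic; on real proteomes it
  is a fallback, not a substitute for a dedicated predictor, and supplied
  topologies always take precedence.
* Motif calling is pattern-based with no positional weighting; the distance
  of a di-arginine motif from the membrane (which modulates its activity)
  is not used as a filter, matching the counting procedure the statistics
  are built on.
* Orthologue-set construction (database mining, remote-homology search,
  tree building) is out of scope; users supply family FASTA and group
  tables.
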