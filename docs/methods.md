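# Methods

## Model and procedure

`dimerface` treats a protein–protein interface as evidence of one of two
catalogued interaction modes:

- a **domain–domain interaction (DDI)**: an unordered pair of Pfam
  accessions observed to interact (sources such as 3did record pairs seen
  in crystal structures; DOMINE adds high-confidence predictions);
- a **domain–motif interaction (DMI)**: an ELM motif class — a short linear
  motif (SLiM), 3–10 residues, defined by a regular expression, typically in
  disordered regions — paired with the Pfam domain it binds.

**Bottom-up prediction** is binary catalog membership: for two annotated
proteins, every cross-protein (domain occurrence, domain occurrence) pair
whose Pfam pair is in the DDI catalog, and every (domain occurrence, motif
occurrence) pair whose (ELM class, Pfam) pair is in the DMI catalog, becomes
one candidate row. There is deliberately no scoring or ranking; the method's
value is the restriction to *complementary halves of a known pair*.
Candidates are occurrence-level — a repeated domain yields one row per copy —
because the downstream structural filter needs concrete coordinates, and the
rows can directly drive cropped-FASTA export for structure prediction.

**Top-down validation** maps each candidate's two residue ranges onto the
chains of a dimer model and computes the minimum Cα–Cα Euclidean distance
over the cross product of the two selections. A candidate passes cutoff *d*
iff that minimum is ≤ *d*. The minimum (rather than mean or count-based)
aggregate is the natural contact-map reading of "within the contact
distance" and makes the sweep trivially monotone. Contact residues are every
Cα pair within the cutoff, labeled with chain, residue number, amino acid
and distance.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| contact cutoff | user-set; sweep 11 → 4 | Å | 11 Å is the interaction range of simplified Cα elastic-network models; interactions above it are unlikely to be biologically meaningful. 4 Å is a practical floor: at Cα–Cα distances below that, side chains would clash. |
| sweep step | 1 | Å | matches the recommended incremental procedure; the smallest passing cutoff is reported per candidate as its detection distance. |
| `keep_analyses` | {"Pfam"} | — | catalogs key domains by Pfam accession, so only Pfam rows of an InterProScan TSV are usable. |
| numbering offset | 0 per chain | residues | annotation (UniProt/sequence) coordinates are assumed to equal structure residue numbers, which holds for AlphaFold output; the per-chain offset handles renumbered experimental PDB entries. |
| cropped-FASTA flank | 0 | residues | exported candidate regions are exactly the annotated ranges unless the user widens them. |

## Scanning semantics

The SLiM scanner reports **overlapping** occurrences: after each match the
search restarts one position after the match start, so every position at
which the anchored pattern matches is reported (`AA` on `AAAA` → three
hits). Simple left-to-right scanners return only non-overlapping matches;
overlap-aware scanning is chosen because SLiM occurrences can genuinely
overlap and a missed occurrence silently loses a candidate. A strict
non-overlapping mode exists behind a flag for parity testing. `^`/`$` are
interpreted relative to the full sequence; patterns use standard regex
semantics (an `X` residue matches only literal `X` or `.` wildcards — this
is documented rather than special-cased). All coordinates everywhere are
1-based inclusive.

## Catalog normalization

Pfam accessions are normalized by stripping whitespace and any `.N` version
suffix (source releases differ in carrying versions) and validated as
`PF` + 5 digits. DDI pairs are stored **unordered** (canonical form:
lexicographically sorted) because physical interaction is symmetric; as a
consequence a count compiled from the same snapshots as another tool that
stores ordered pairs may differ. Self-pairs are permitted (homotypic domain
interactions exist). Rows with non-Pfam identifiers are skipped and counted,
not fatal. Serialization is a two-column TSV in sorted order (bit-stable
diffs) plus a JSON sidecar of per-pair source provenance; compiling a
catalog from its own output is an identity.

## Structure handling

PDB files are parsed with gemmi; this package's policy on top of the parse:
model 1 only for multi-model files; alternate locations resolved to the
highest-occupancy conformer, ties broken by altloc letter; HETATM residues
dropped unless they are standard amino acids flagged as HETATM; residues
addressed by (number, insertion code), but range selection is by number
ignoring insertion codes (documented limitation). Distances are computed in
double precision and compared with `≤` and no epsilon; the minimum distance
and the contact-pair labeling use the same arithmetic, so the "passes iff a
contact pair exists" equivalence holds even at an exact cutoff boundary. An
optional k-d-tree path prunes the pair search on large regions and re-filters
retained pairs with the same arithmetic, so its pass/fail decisions are
identical to the dense path.

Candidates whose regions have no resolved residues in the model are a third
output category, **unevaluable** — an undefined distance is not a large
distance, and folding such candidates into pass or fail would be silently
wrong either way.

## Synthetic fixtures

The fixture generator emulates the one thing the pipeline must get right —
catalog matching plus interface geometry — with planted ground truth. Each
region pair is laid out as two parallel straight runs of Cα atoms (3.8 Å
spacing, the trans-peptide Cα–Cα value) separated exactly by the target
minimum distance; pairs occupy slots 200 Å apart so cross-pair distances
never interfere. The default study condition per fixture is 3 planted pairs
(2 DDI + 1 DMI) at 4.5–5.5 Å — comfortably inside a 6 Å filter — and 2
decoy pairs (1 DDI + 1 DMI) at 20–40 Å, far outside any biologically
meaningful cutoff; each pair carries private catalog identifiers so
bottom-up emits exactly one candidate per pair. Output is byte-deterministic
per seed.

What passing these fixtures does *not* show: robustness to unresolved
loops, numbering mismatches, near-threshold geometry, motif overprediction
on real disordered sequences, or catalog incompleteness. Real structures
have folded-chain geometry, not line segments; the fixtures validate the
distance logic, not structural realism.

## Problem sizes used in the reported runs

The acceptance script runs 50 seeded fixtures (5 candidate pairs each),
200 random region pairs up to 50×50 residues for the geometry oracle, and
100 random sequences × 5 patterns for the scanner oracle; all complete in
seconds on one CPU. These sizes give exact, enumerable ground truth while
exercising every code path end to end.

## Known limitations

- The bottom-up stage inherits catalog incompleteness and SLiM regex
  overprediction; it delimits plausible regions, it does not assert binding.
- Cα–Cα distance is a coarse interface criterion; hydrogen-bond and
  salt-bridge geometry are out of scope.
- Whether a *single* Cα pair within the cutoff should suffice (versus a
  minimum number of contacts) is an open design point; this implementation
  uses the single-pair minimum, the least restrictive reading.
- mmCIF input, PAE-based confidence and 3D rendering are out of scope; all
  outputs are tabular/JSON for external viewers.
- Network lookups (UniProt sequences, InterPro domain locations) are
  optional, isolated behind an explicit flag and an injectable fetcher, and
  never exercised by the test suite.
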