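# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data the tests rely on, and the
places where a design choice was genuinely open.

## Degenerate motif matching

Patterns (enzyme recognition sites and custom motifs alike) are IUPAC
strings compiled to per-position allowed-base sets. Matching is by subset:
a subject letter matches a pattern position iff every concrete base the
subject letter could denote is allowed there. Consequences: a subject `N`
(common in draft genomes) matches a pattern `N` but never a pattern `A`;
a subject `R` matches pattern `R`, `D`, `V`, `N` but not `A` or `G`. This
is the conservative reading — ambiguous data never creates a site call
that could be wrong — and it is pinned by tests. Scanning compiles the
pattern to a stdlib regex whose character classes enumerate the IUPAC
letters satisfying the subset rule; the overlapping mode wraps the same
regex in a zero-width lookahead. Both modes are verified against a
position-by-position brute-force matcher on random instances.

Two overlap disciplines exist because they answer different questions.
Global-match semantics (default, `non_overlapping`: resume after the match
end) is what scripting-language scan loops produce and is the natural
count for digestion, where a cut consumes its site. Overlapping mode
(resume at start + 1) reports every occurrence of self-overlapping
degenerate motifs and is the right choice for motif censuses. Strand
handling: the default census is forward-strand only; `both` additionally
matches the reverse-complement pattern against the forward text, reporting
those hits with strand `-` and no deduplication (a palindromic site
appears once per strand representation).

Circularity is not modeled: all scans are linear. For a circular
genome an origin-spanning site would be missed; users can append the
first (pattern length − 1) bases manually if that matters for their
replicon.

## Windows and the pre-cut area

A census region is `whole`, or a half-open offset window measured from the
5' or 3' end of *each record* (3' windows are recomputed per record
length; a record shorter than the window contributes what fits and is
tallied as truncated). Matches are assigned by their start coordinate to
in-region, pre-cut (between sequence start and window start), or
post-region; the three partition the whole-sequence count, an identity the
tests enforce. Pre-cut counts are carried into the Best table because
applications with minimum fragment-length requirements care about cuts
upstream of the target window. All coordinates are 0-based, half-open.

## Poly-A preprocessing

Tail detection follows the trimest-style rule set: a tail is seeded by at
least `min_run` = 4 consecutive A whose seed window begins within
`search_window` bases of the 3' end; once seeded, extension toward 5'
ignores the window bound, tolerates isolated single non-A characters, and
terminates at two consecutive non-A. Everything from the tail start to the
sequence end is removed. Poly-T heads are handled as the mirror image: on
detection the read is reverse complemented (restoring 5'→3' orientation)
and the now-3' tail trimmed. Reads with both a plausible head and tail are
resolved by the longer terminal homopolymer run, ties to the poly-A tail —
there is no canonical convention here, so a deterministic rule is pinned
by test. `search_window` defaults to 50 bases; the dial is exposed because
3'-end chemistry varies by library prep. Reads with no recognized tail,
or trimmed to emptiness, go to a rejected set and are not analyzed
further. Whether the seed must touch the terminal base or merely start
within the window is a genuinely open choice; "starts within the window"
is implemented, which also lets a long genuine tail whose run begins
before the window be found and fully removed.

## Census tables

Summary percentages are computed as exact integer ratios and rounded
half-up to two decimals only at presentation. Isoschizomer groups (enzymes
with byte-identical sites) collapse to one row labeled by the
alphabetically first *selected* member with a `*` flag. The Best table is
greedy set cover over in-region coverage: each step takes the pattern with
maximal marginal record coverage; ties break by larger total cut count,
then alphabetical name; rows with zero gain are never emitted. Greedy is
the right trade-off here — the panels are small, the instance sizes are
huge, and the classical (1 − 1/e) guarantee is irrelevant in practice
because transcript coverage saturates within a handful of enzymes; an
exact set-cover solver is out of scope. Every greedy step is verified
against exhaustive marginal computation on random small instances. The
Top table filters Summary at a threshold defaulting to 95%.

## Digestion

Cut coordinate = recognition-site match start + top-strand cleavage
offset, clamped to [0, L]; cuts from all enzymes are pooled, deduplicated
and sorted; fragments are the gaps between consecutive cut points
including the ends. Complete digestion, linear topology. Only the
top-strand offset is modeled: at gel resolution, fragment length is
governed by top-strand cut positions, and sticky-end geometry is
irrelevant to band position. Enzymes catalogued without an offset fall
back to cutting at the site start with a warning — counting work (the
dominant use) is unaffected, and for 4–6-base cutters the band-position
error is at most the site length. Total fragment length always equals
sequence length; adding an enzyme never decreases the fragment count; both
are enforced as properties.

Amplicon prediction treats two custom motifs as PCR oligos: the forward
oligo's matches pair with forward-text matches of the reverse oligo's
reverse complement, every (i, j) pair with j > i and j − i ≤ max_len
yielding an amplicon of length j − i.

## CAPS candidate ranking

Each enzyme digests each allele; two lanes are distinguishable if their
distinct-band-length lists differ in count, or any rank-paired bands
differ by more than the resolution tolerance. The tolerance defaults to 5%
of the larger fragment (bands closer than that co-migrate on standard
agarose); a fixed base-pair resolution can be supplied for higher-
percentage or polyacrylamide gels. Candidates are ranked by resolvable
allele pairs, then by fewest total fragments (simpler patterns read
better), then name; the ranking is invariant to allele input order. The
tolerance relation is not transitive, so the "distinct patterns" count
uses a first-fit grouping over the ordered alleles — adequate for ranking,
not a clustering claim.

## Gel migration model

The model frames migration electrically: fragments experience a
size-specific resistance in the agarose matrix, Ohm's law (I·R = V)
converts the applied potential into a size-specific current, currents read
as velocities, and d = v·t. For the functional form of the size-specific
resistance this package adopts R(L) = r0·ln L,
the simplest form that reproduces the classic agarose observation that
migration distance falls off as 1/log(size) and satisfies every stated
constraint (strict monotonicity, co-migration of equal lengths). Model
constants are fields: V = 70 volts, t = 45 minutes, r0 = c = 1; with the
defaults the raw distance is 3150/ln L. Raw distances are affinely
normalized per model so the largest renderable fragment sits at 0.05 and
the smallest at 0.95 of lane height — a rendering convention, not physics.
The rendering range defaults to 50–3000 bp (the 2% agarose regime);
out-of-range lengths clamp to the edge and draw dashed. One monotone model
is used for all renders, including cases a wet lab would run on
polyacrylamide; band *ordering, co-migration, and lane unions* are the
meaningful outputs, not absolute positions. SVG output is a deterministic
serializer owned by this package: identical lanes and model produce
byte-identical files.

## Synthetic data and what tests do (and do not) show

All test inputs are generated, seeded, with machine-readable ground truth:

- **Poly-T probes** — a recognition site embedded dead-center in a 60-base
  T background, the canonical construct for verifying site identification
  and single-cut gels.
- **Tailed reads** — random cores with appended A-tails or prepended
  T-heads. Cores are constrained so the trim boundary is provably unique
  (last two bases non-A, no seedable A-run inside the 3' search window,
  mirrored for T), which is what makes exact-recovery and idempotence
  assertions valid. Real EST data violates these constraints — internal
  priming, A-rich UTRs — so on real data trimming is correct per the rule
  set but not uniquely "right".
- **SNP allele pairs** — a random template with exactly one site
  occurrence; the alternate allele substitutes one non-degenerate site
  base, verified to destroy the site and create no new one. This is the
  CAPS situation in its cleanest form.
- **Random datasets with planted patterns** — uniform-base records, a
  known fraction receiving one planted occurrence at a recorded position
  (plants never overwrite each other). Planted-position recall is exactly
  checkable; observed Summary rates equal plant rate plus analytic
  background (1 − (1 − 4^−k)^(L−k+1) for a k-mer), and tests require
  agreement within 3 binomial standard errors. The default plant rate for
  the canonical polyadenylation signal is 13.55%, the rate reported for
  that hexamer in a large public EST census.
- **Annotated genome** — n (default 400) forward-strand genes every 200
  bases on a {C,G} background, each gene carrying either no AT-rich
  promoter motif or a *contiguous range* of the nine spacer variants
  (WWWWWW·N4–12·ATG) written upstream so the terminal ATG coincides with
  the annotated start codon; extra motif words are planted intergenically.
  Because A/T occurs only in planted heads and ATG codons, and contiguous
  spacer ranges make the matching family subset exactly the chosen range,
  every per-motif total, gene-associated count, and the all-nine-motif
  gene set are known in closed form, and the census must recover them
  exactly. Boundary bases are pinned to C so no unplanned ATG can form.
  What this shows: the census/association machinery is exact. What it
  does not show: counts on a real bacterial genome, whose AT-rich
  background makes these motifs overlap heavily — there the overlap-mode
  choice materially changes totals. Running the same pipeline on a real
  genome is a two-liner (`read_fasta` + `promoter_census` with gene starts
  from its annotation) but requires the user to fetch the sequence and
  annotation themselves; both overlap modes are exposed for that purpose.

Problem sizes in the default test and acceptance runs (10,000-record
planted census, 1,000 scanner-oracle instances, 500 greedy instances,
1,000 random digests, 400-gene genome) were chosen to keep the full suite
in the tens of seconds on one CPU while leaving the statistical checks
well-powered; all generators scale up by argument.

## Enzyme catalogue

The on-disk enzyme format is a deliberate repo convention: a TSV of
`name`, `site` (caret cleavage notation accepted), optional explicit
offset, with `#` comments — the information content of a restriction-
enzyme database entry without committing to any flat-file dialect. A
converter from full REBASE flat files would slot in as a single parser
function producing the same rows. The bundled starter catalogue carries
~110 enzymes; offsets are included only where they are standard knowledge,
and rows without one rely on the documented digestion fallback. Malformed
lines are never silently dropped; they surface as structured warnings.
Methylation sensitivity is out of scope beyond whatever the user encodes
in names; no live database updates.

## Known limitations

- No mismatch-tolerant or PWM matching; motifs are exact IUPAC patterns.
- No partial digestion, star activity, or methylation blocking.
- No primer design; amplicon prediction assumes the oligos given.
- Linear-molecule assumption throughout (no circular topology).
- Band intensity is a multiplicity proxy, not densitometry.
- The gel model's absolute distances are not calibrated to any particular
  rig; only order statistics of bands are asserted or claimed.
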