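# Methods

## Repeat model and detection criteria

The object of study is the perfect microsatellite: a tract of DNA that is
an uninterrupted repetition of an atomic motif of period 1–6 bp, where
*atomic* means the motif is not a whole-number repetition of a shorter
word. The final unit may be partial, so a 15 bp tract of AC (7 complete
units plus one base) is one dinucleotide locus of length 15. The reported
tract always includes the partial unit; the per-period minimum applies to
complete units only: 12 (mono), 7 (di), 5 (tri) and 4 (tetra/penta/hexa)
units. These minimums are the defaults of `ScanThresholds` and are the
settings under which all packaged survey numbers were produced; they are
adjustable per period.

Detection works per period p on the lag-p match vector
`m[j] = (s[j] == s[j+p] and s[j] ∈ {A,C,G,T})`: a maximal run of matches
of length r is a maximal p-periodic tract of length r + p. A tract is
reported at period p only when p is the smallest period of the whole
tract. That single rule has three consequences that would otherwise need
separate handling:

* the motif (the first p bases of the tract) is atomic — a tract with a
  non-atomic length-p prefix has a smaller period;
* a poly-A tract is never additionally reported as an AA or AAA locus;
* no reported locus can be contained in a reported locus of smaller
  period, because a substring of a q-periodic string is q-periodic.

Tracts of different periods that overlap *without* containment (a
dinucleotide run starting on the last base of a homopolymer, say) are all
reported: they are genuinely distinct structures, and suppressing either
would understate one period class. Any symbol outside {A,C,G,T}
terminates runs (N never matches N), is retained in coordinates, and is
excluded from GC numerators and denominators alike. Coordinates are
0-based half-open internally; TSV output is 1-based inclusive, BED output
0-based. The scanner has no randomness; output order is (sequence input
order, start, end).

The whole-assembly published counts (tens of thousands of loci per
genome) depend on exact semantic agreement with the original mining tool
on points its description leaves open — partial-unit handling and
containment suppression. The desk-scale quantities shipped here
(combinatorics, table arithmetic, correlations) are independent of those
choices; re-scanning a published assembly (e.g. the 223.74 Mb female
mountain pine beetle genome, expected 6,505 loci) is documented as an
external benchmark that localizes any semantic divergence, and is not run
by the test suite because it requires a multi-hundred-Mb download.

## Motif classes

Two motifs name the same repeat when one is a cyclic rotation of the
other (different reading frame) or lies on the opposite strand. Strand
symmetry is implemented as **reverse complement**, the standard
convention in repeat-survey tooling; the class representative is the
lexicographically smallest member (A < C < G < T), and classes are
enumerated exhaustively per period (2, 4, 10, 33, 102, 350 for periods
1–6). Some older surveys print member lists that correspond to the plain
(unreversed) complement instead; a `strand="complement"` flag reproduces
that convention for replication work. The two conventions give identical
classes for periods 1–3 and differ only in how periods 4–6 members group.

## Compartments

From gene/exon/CDS rows of a GFF3 file (types matched case-insensitively,
coordinates converted to 0-based half-open, rows with end < start dropped
with a warning): exon and CDS are the merged annotated intervals, intron
is gene − exon, and intergenic is the complement of merged gene spans
over [0, L) — the "complement" convention, which includes sequence ends
and makes gene/intergenic an exact partition of every sequence. The
stricter reading (only gaps strictly between two genes) is available as
`intergenic_convention="between"`. CDS is kept as its own compartment
even though CDS ⊆ exon double-counts coding bases across categories,
because coding and exonic distributions are reported separately.

Interval arithmetic (merge, subtract, intersect, complement) is written
in-house on sorted half-open intervals and is verified in the tests
against a per-base bitmap oracle; replicating subtract/intersect
behaviour exactly, rather than delegating to an external interval stack,
is part of the package's contract.

Assignment is multi-label: a locus receives every compartment it overlaps
by ≥ 1 bp, so a tract spanning an exon/intron boundary counts in both and
compartment percentages need not sum to 100. Percentages are reported per
compartment against the total locus count. Region frequencies/densities
use the whole-assembly megabase by default (`assembly_mb`), making
percentage and frequency proportional across compartments;
`compartment_mb` divides by the compartment's own span instead, which is
the more biologically interpretable rate but not comparable across
compartments of very different sizes. Loci on sequences absent from the
annotation are labelled intergenic with a logged note. Strand is ignored
throughout: compartments are coordinate sets.

## Summary metrics

All metrics are exact ratios of integer counts over integer base pairs,
with 1 Mb = 10^6 bp exactly: relative frequency = loci/Mb, relative
density = tract bp/Mb, SSR content = 100 × tract bp / assembly bp, GC of
a locus set = 100 × ΣGC / Σlength (length-weighted). Rounding to two
decimals is presentation-only, applied in the TSV writers. Conservation
identities (per-type counts and bp sum to the assembly totals) are
asserted on every CLI run. "Top motif" ranking uses the locus count with
lexicographic tie-break. Assembly GC excludes ambiguity codes from both
numerator and denominator and is reported as missing when no A/C/G/T
base exists.

## Correlations

Cross-assembly association uses the Pearson product-moment correlation
with the two-sided t-test on n − 2 degrees of freedom, computed from the
centered sums directly (scipy supplies only the t distribution); tests
cross-check against `scipy.stats.pearsonr` to 1e-12. The suite covers the
pairs (number, frequency), (number, density), (size, number),
(SSR GC, number), (size, frequency), (size, density), flagging
significance at 0.05 and 0.01 with no multiple-testing correction — the
convention of the surveys this mirrors, with n the number of assemblies
supplied (12 in the packaged table). Perfectly collinear inputs are
clamped to |r| = 1 with p = 0; zero-variance input is an error, not a
NaN. The packaged twelve-assembly table carries no SSR-GC column, so the
GC pair is skipped there.

## Synthetic data

The generator emulates what the analysis assumes about real assemblies —
AT-rich background (default GC 0.44, matching the weevil genomes
surveyed), multiple contigs, N runs, a period/motif mix dominated by
mono–trinucleotides, and loci distributed across annotation compartments
— while deliberately omitting what the analysis does not model:
imperfect/compound repeats, repeat-length mutational dynamics,
chromosome-scale structure, and realistic gene architecture beyond
alternating exon/intron blocks. Passing tests therefore demonstrate
correctness of detection, assignment and bookkeeping on genomes that
satisfy the perfect-repeat model, not robustness to assembly artefacts or
degenerate repeats.

Backgrounds are drawn i.i.d. at the requested GC and made SSR-free by
rejection-repair (scan, redraw found tracts, repeat; error after 50
passes) — chosen over a Markov construction because the guarantee is
verified by the scanner itself. Planted tracts replace background bases
at uniform positions ≥ 2 bp apart (inside a chosen compartment interval
when one is requested); after planting, the sequence is re-scanned and
background bases flanking any mismatch are redrawn until the scan equals
the planted truth exactly, so junctions can never extend a tract
silently. Truth coordinates are authoritative: tests compare scanner
output to truth, never the reverse. N runs are inserted last, clear of
all tracts. Everything derives from a single `numpy` generator seeded by
the spec, so a (spec, seed) pair reproduces the dataset byte-for-byte.

## Problem sizes

The test suite fuzzes the scanner against a brute-force definition
checker on ~1,050 seeded sequences up to 5 kb spanning uniform, two- and
three-letter, N-containing and threshold-boundary constructions; the
end-to-end regression plants 500 loci on a 0.6 Mb five-contig annotated
genome and requires exact recovery of the per-type, per-motif and
per-compartment tables. `scripts/acceptance.py` uses 300 fuzz sequences
up to 3 kb plus the same 500-locus genome; these sizes give the oracle
comparisons full coverage of the rule set while keeping a complete run in
tens of seconds.

## Known limitations

* Only perfect repeats: a single mismatch splits a tract, matching the
  survey definition but undercounting degenerate repeat fields.
* The contig-length filter (200 bp in the survey that motivated it) is
  off by default and applied before scanning when enabled; whether the
  original pipeline filtered before or after scanning is not documented.
* Compartment tables inherit whatever redundancy the annotation has
  (CDS ⊆ exon; overlapping genes merge).
* `compartment_mb` frequencies are undefined (reported as missing) for
  empty compartments.
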