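# Methods

## Library model and coordinate conventions

The pipeline analyzes single-end reads sequenced *outward* from the two
termini of an integrated element. In an integration at pre-insertion
coordinate *t* on a contig (element in forward orientation), 3′-end reads
run rightward on the forward strand and their trimmed flanks align starting
at *t*; 5′-end reads run leftward, their flanks align on the reverse strand
ending at *t − 1*. The junction coordinate of an alignment is therefore the
flank terminus adjacent to the element: `start` for a forward-strand flank
(direction *rightward*), `start + L − 1` for a reverse-strand flank
(direction *leftward*). One element end produces forward-strand flanks on
one side of the insertion point and the other end reverse-strand flanks on
the other side — two clusters extending in opposite directions away from
(nearly) the same base, which is exactly the both-end divergence criterion
the caller enforces. For a reverse-orientation integration the ends swap
sides; the caller only requires opposite directions, so orientation never
needs to be known in advance.

All coordinates are 0-based half-open internally. TSV reports are 1-based
inclusive; BED output is 0-based half-open.

Because outward reads start inside the element, the terminal motifs relate
to the element sequence as follows: the 5′ motif is the reverse complement
of the element's first bases (`ATAAT` ⇒ the element begins `ATTAT…`), and
the 3′ motif is its last bases read forward (`…ATTATTG`). `IceElement`
validates this invariant whenever the full sequence is supplied.

## Filtering

A read is a junction read when either terminal motif occurs within the
first `max_offset` (default 3) bases with at most `max_mismatch` (default 0)
substitutions; `N` never satisfies a motif position. "Occurs at a small
offset" rather than "is the exact prefix" absorbs ligation artifacts at the
read start. The earliest offset wins; at equal offset the longer (3′) motif
wins, being the more specific evidence. Trimming removes everything through
the motif end and then strips a trailing C-homopolymer of ≥ `ctail_min_run`
(default 5) bases — the C-tail added during library preparation is sequence
of no genomic origin, and a 5-base threshold keeps genuine short C runs in
the flank. Flanks shorter than `min_flank_len` (default 20 nt) are rejected:
20 nt is the shortest flank the builtin aligner places uniquely on the
megabase-scale catalogs this package targets. Filter statistics partition
the input exactly (`n_input = n_five + n_three + n_no_motif + n_too_short`).

## Alignment

Flanks are 20–70 nt with few substitutions, so alignment is gap-free by
design. The builtin engine indexes exact 15-mers of the catalog forward
strand, anchors every candidate placement containing at least one intact
seed (both query strands), and verifies by capped Hamming distance. A
placement is retained only if its mismatch count is ≤
`floor(max_mismatch_frac · L)` (default fraction 0.1) and it is the unique
best hit; ties are dropped, because a multi-mapping flank cannot support
"a single position on a contig". A placement whose errors disrupt every
15-mer window is invisible to the seeded engine; at ≤ 1% substitution error
on ≤ 75 nt flanks this requires ≥ 4 adversarially spaced errors and is
negligible — and such placements would normally fail the mismatch cap
anyway. The independent `brute_force_align` oracle scans every position of
both strands with vectorized mismatch counting and is held equal to the
seeded engine in the test suite.

Catalog genomes that already carry the element would soak up flanks at
resident copies, so regions sharing merged exact 31-mer runs ≥
`min_match_len` (default 100 bp) with the element are hard-masked to `N`
before alignment. On an error-free planted catalog the masked intervals
equal the planted spans exactly; masking is idempotent.

External mapper output is accepted as SAM: mapping quality < 20 or a
secondary/supplementary flag marks a record non-unique, and leading soft
clips shift the reported start so coordinates always refer to the full
flank. The builtin engine's alignments are themselves serialized as SAM
(MAPQ 60/0 encodes uniqueness, `ZE` tag carries the element end), and the
write→parse round trip is exact.

## Calling and quantification

Junction coordinates on the same contig from the same end and direction are
clustered around modal positions with a ± `merge_window` (default 2 bp)
window — enough to absorb trimming jitter while keeping nearby sites
distinct; ties in the mode break to the smaller coordinate. Per contig,
each 5′ cluster is greedily paired with the nearest unused opposite-
direction 3′ cluster within `max_gap` (default 20 bp; generous because a
target-site duplication of unknown length separates the two junctions), ties
to the leftmost partner. `min_reads_per_end` defaults to 1 — presence of
reads from both ends is the calling criterion; raise it for noisy libraries.
Unpaired clusters are reported with a reason (below-support, single-end,
same-direction). The reported site position is the rightward cluster's
junction (the first host base after the element), and the signed
`junction_gap` lets users infer the target-site duplication length.

Site percentages are computed independently per element end:
`pct_end(site) = 100 · n_end(site) / Σ n_end` over retained calls, so each
end's vector sums to 100 whenever at least one call exists. The two ends
thus give two independent estimates of the same site-frequency profile.

## Characterization

Site context windows (default 50 nt) center on `floor((j5 + j3)/2)`.
The degenerate consensus covers, at each position, every base with
frequency ≥ `min_base_freq` (default 0.25) using IUPAC codes, with
ambiguous input bases excluded from the denominators.

Element boundaries between two carrier sequences follow a strict
100%-identity rule: anchor on a k-mer (default 31) unique within each input
and shared between them, extend exact matching in both directions, and
report the maximal block. Any internal variant splits the block; the larger
fragment is returned with a warning, since a single resolved interval is
what a boundary annotation needs. The procedure is symmetric in its inputs.

Genome abundance uses reads-per-kilobase-per-million:
`rpkm_g = count_g/(len_g/10³)/(total/10⁶)`, renormalized to percentages
summing to 100 across genomes. `total` defaults to the summed counts but
can be the library's full mapped-read total.

## Synthetic data

The generator emulates the targeted library: random genomes (one contig per
genome) at a configurable G+C fraction; element copies planted at loci
matching a degenerate IUPAC target-site pattern — default `WWTAWW`, an
AT-rich choice consistent with integrases that prefer degenerate AT-rich
targets, since no exact motif is established — with random orientation, ≥
200 bp from contig ends and ≥ 1 kb apart; an optional target-site
duplication length (default 0, as duplication behavior is not established).
Reads are 75 nt from fragments ~ Normal(500, 75) bp truncated at the read
length; per site and end the read count is Poisson around
`reads_per_junction` (or explicit per-site depths); the terminal motif sits
at a configurable offset (default 0); a C-tail of 3–10 C's is appended to
the fragment end distal to the primer and becomes visible only when the
flank is shorter than the read; substitution errors are uniform at
`error_rate`; `offtarget_fraction` of the library are random catalog
fragments (the spike-in/mispriming analogue), which may still contain a
motif by chance — the chance pass rate is itself a tested analytic quantity
(≈ 4·0.25⁵ per read for the 5-base motif at offset ≤ 3). All outputs are
byte-deterministic under the seed, with independent RNG streams per stage.

What the simulator does **not** model: PCR duplicates, indels, quality
decay, paired ends, chimeras, or strain-level catalog redundancy. Passing
recovery tests therefore demonstrates correctness of the junction logic
under the stated library model, not robustness to assembly artifacts or
near-identical catalog genomes — on real data the mapping-uniqueness filter
carries that burden, which is why dereplicated catalogs are the expected
input.

## Problem sizes and scenario choices

The reference validation scenario uses five 200 kb genomes (1 Mb catalog),
a 5 kb element, six insertions (four in one genome, exercising multi-site
recovery within one species), 100 reads per junction end, 0.5% substitution
error and 20% off-target reads — a desk-scale analogue of a community
screen that keeps every guarantee checkable exactly against planted truth.
Oracle-equivalence checks run 200 flanks against a 500 kb catalog; filter
analytics use 100,000 random reads; boundary detection plants a 5 kb
element in two 50 kb backgrounds. Real screens use multi-thousand-genome
catalogs and full-length (~115 kb) elements; every algorithm here is
size-independent, and the external-mapper adapter is the intended route at
that scale.

## Known limitations

* The builtin aligner is exact-seeded and gap-free; flanks spanning indels
  or highly repetitive loci should go through an external mapper via the
  SAM adapter.
* Boundary detection reports a single maximal exact block; diverged or
  rearranged element copies need a proper aligner.
* Greedy nearest pairing can mis-pair two genuine insertions closer than
  `max_gap` on the same contig; at realistic inter-site distances this does
  not arise.
* Percentages are relative within a sample; they are not absolute abundance
  of carrier cells.
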