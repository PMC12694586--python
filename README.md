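# iceseq

Junction-read analysis for tracking an integrative and conjugative element
(ICE) across the strains of a microbial community.

## The problem

ICEs are mobile DNA elements that integrate into a host chromosome and move
between species by conjugation; some carry a complete type VI secretion
system (T6SS) and can reshape competition inside a gut community. Finding
*which* strains of a complex community carry such an element is hard:
screening isolates is biased toward what grows, and in shotgun metagenomes
the repetitive element cannot be assigned to a host genome.

Targeted junction sequencing ("ICE-seq") solves this by amplifying outward
across the element's two termini: genomic DNA is sheared (~500 bp), C-tailed,
and amplified with primers annealing just inside each element end, then
sequenced as 75 nt single-end reads. Every informative read therefore starts
with a short known element prefix — the **terminal motif** (by default
`ATAAT` at the 5′ end and `ATTATTG` at the 3′ end) — and runs across the
junction into host flank. Mapping those flanks onto a genome catalog reveals
the insertion sites, and with them the carrier strains.

## The method

For a sample's read set the pipeline:

1. **Filters** reads containing a terminal motif within the first few bases
   (default offset ≤ 3, exact match), assigns each to the 5′ or 3′ element
   end, and trims away the element prefix and any trailing C-homopolymer,
   leaving pure genomic flank.
2. **Masks** resident element copies in the catalog (exact 31-mer runs
   ≥ 100 bp) and **aligns** each flank gap-free (exact 15-mer seed + extend,
   substitutions only), keeping only unique placements with ≤ 10% mismatches.
   An exhaustive scan oracle and a SAM adapter for external mappers share the
   same contract.
3. **Calls insertions**: each alignment yields a junction coordinate (the
   flank terminus adjacent to the element) and a direction; coordinates
   within a 2 bp window merge into clusters, and a site is called only when a
   5′-end and a 3′-end cluster **diverge in opposite directions from the same
   position** (gap ≤ 20 bp). Single-end or same-direction pileups are
   reported as dropped, not called.
4. **Quantifies** each site as the percentage of junction reads it carries,
   computed independently for the two element ends (each end's percentages
   sum to 100 within a sample).
5. **Characterizes**: extracts site windows and their AT content, builds an
   IUPAC degenerate consensus of target sites, locates element boundaries
   between two carrier genomes as the maximal 100%-identity block, and
   summarizes genome abundance as reads-per-kilobase-per-million (RPKM)
   percentages: `rpkm_g = count_g / (len_g/10³) / (total/10⁶)`, renormalized
   to sum to 100 across genomes.

A first-class **simulator** generates random genome catalogs, plants element
copies at loci matching a degenerate AT-rich target-site pattern (default
`WWTAWW`), and emits reads under the library model above with full ground
truth — the oracle for every recovery guarantee in the test suite.

## Worked example

Simulate a two-genome community with three planted insertions and analyze it:

```
iceseq simulate --seed 4 --n-genomes 2 --contig-length 80000 \
    --insertions 0:2,1:1 --reads-per-junction 50 --error-rate 0.005 \
    --offtarget-fraction 0.2 --ice-length 5000 --out demo/sim
# simulated 3 insertion site(s), 404 reads -> demo/sim

iceseq run --ice demo/sim/ice.fa --reads demo/sim/reads.fq \
    --catalog demo/sim/catalog.fa --map demo/sim/contigs.tsv \
    --out demo/run --sample mouse1
# 3 insertion call(s) (5' reads: 167, 3' reads: 146)
```

`demo/run/report.tsv` (1-based coordinates):

```
sample   genome      contig      site_pos_1based  junction_five_1based  junction_three_1based  junction_gap  n_five  n_three  pct_five  pct_three
mouse1   genome00    genome00_c1 15995            15995                 15994                  -1            52      49       31.14     33.56
mouse1   genome00    genome00_c1 63757            63757                 63756                  -1            49      44       29.34     30.14
mouse1   genome01    genome01_c1 9491             9491                  9490                   -1            66      53       39.52     36.30
```

All three calls sit exactly at the planted coordinates recorded in
`demo/sim/truth_sites.tsv` (15995, 63757, 9491). `n_five`/`n_three` are the
junction reads supporting each site from either element end; `pct_*` are the
per-end site percentages (each column sums to 100); `junction_gap` is the
signed separation of the two junctions, which exposes any target-site
duplication. The output bundle also contains the flank FASTA, alignments in
SAM, a BED of called junctions (0-based half-open), site-context FASTA, and
a config snapshot.

Other subcommands: `filter`, `align`, `call`, `characterize`, `boundaries`,
`abundance` expose the individual stages; every stage is equally available
as a library function.

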