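# Methods

## Coordinate model

A transcript is a set of non-overlapping exon intervals on one chromosome
strand plus CDS bounds in spliced-transcript coordinates. Internally all
interval arithmetic is 0-based half-open; 1-based inclusive coordinates
appear only at HGVS strings and file formats, so off-by-one handling is
centralized at the I/O boundary.

Coding positions follow HGVS `c.` semantics restricted to the CDS and its
introns: `base ≥ 1`, a `+k` offset hangs off the last coding base of an
exon, `-k` off the first coding base of the next exon. 5′UTR (negative) and
3′UTR (`*`) coordinates are rejected, never clamped — the events this
package models are CDS-internal. Mapping a genomic position back to a
coding position assigns intronic bases to the nearer exon boundary; for an
even-length intron the two central bases receive `+` and `-` respectively,
so per intron the two offset populations differ in size by at most one.
Both strands are fully supported (mirrored offset direction,
reverse-complemented extraction) and are exercised by mirrored synthetic
genes. The lexicographic order on `(base, offset)` is exactly
transcript-plus-intron order, which makes span arithmetic on the unspliced
axis trivial.

## Pseudoexon events

An event is defined by the acceptor's first and the donor's last exonized
base, both anchored to the same upstream exon boundary. The intronic GT
begins one nucleotide 3′ of the donor's last exonized base and the AG ends
one nucleotide 5′ of the acceptor's first — the canonical dinucleotides are
*not* part of the inserted segment. Inserted length is the inclusive
offset span; frame remainder is that length mod 3.

Two routes produce an event: explicit boundaries (when sites are known from
sequencing of the aberrant product) and discovery via `scan_cryptic_sites`,
which enumerates GT dinucleotides within a window (default 300 nt) of the
predicted donor-gain position, pairs each with upstream AGs subject to a
minimum pseudoexon length (default 20 nt, below which spliceosomal
inclusion is implausible), suppresses any pair whose exonized span contains
a GT strictly closer to the predicted donor position (that donor would
outcompete the distal one), and ranks remaining pairs by
|length − window/2|, nearest acceptor first on ties. The ranking is a
design choice of this package: real acceptor choice depends on branch-point
and polypyrimidine context that is out of scope, so the scanner prefers
lengths typical of included pseudoexons and reports *all* viable pairs for
inspection.

The protein consequence splices the insert into the reference CDS and
translates codon by codon. Frameshifts are reported in the printed style
`p.(<Ref><idx><New>fs<k>*)` where the first altered residue counts as
position 1 of the shifted frame and `k` is the stop's ordinal; in-frame
insertions are reported as `ins` of the novel residues; a frameshift that
exhausts the transcript without a stop is reported as `fs?`, not raised.
NMD is *predicted* (the flag is named accordingly, since rule-based
prediction is not an expression measurement) by the 50-nt rule against the
exon–exon junctions of the mutant transcript, threshold configurable.

## Prioritization

Five independent predicates are applied in the fixed order quality → panel
→ frequency → duo → splice; because they are independent, the final
candidate set is order-invariant (property-tested) while per-stage counts
are not. Defaults: DP ≥ 20, alt AD ≥ 5, VF in [0.2, 0.8] in the affected
sample (conventional germline heterozygous-call heuristics — they are
configuration, not published cut-offs), population AF strictly < 0.01 with
missing AF treated as novel and kept, genotype pattern affected-carrier /
unaffected-non-carrier with missing unaffected genotypes dropped and logged
as indeterminate, and max splice delta strictly > 0.2 with unscored
variants dropped. Splice scores are consumed from a pluggable INFO key
(default `SPLICEAI`, ten pipe-delimited fields); the predictor itself is
upstream of this package. Multi-allelic records are split on read, with AD
re-paired per alt.

## RNA assays

Allelic imbalance at a heterozygous exonic marker is the ratio-of-ratios
(alt/ref)_cDNA ÷ (alt/ref)_gDNA; gDNA normalization cancels allele-specific
amplification and detection bias, and the statistic is invariant to
rescaling either template's peaks. Peak areas and peak heights are
interchangeable here because only within-template ratios enter. Under
complete aberrant splicing with NMD efficiency *e*, the expected ratio is
1 − *e*; a ratio near 0.5 therefore reads as "the variant-phased transcript
is reduced by about half". The imbalance call uses a symmetric threshold
(default 0.8: imbalanced iff ratio < 0.8 or > 1.25), chosen so that
halved-expression ratios in the 0.5–0.6 range classify as imbalanced.

Completeness of the aberrant event is adjudicated from wild-type-selective
amplicons: *complete* iff every gDNA-heterozygous tagging SNP shows exactly
one allele and all such SNPs agree on phase; any het marker showing both
alleles makes it *incomplete*; no het markers, *uninformative*. Phase
disagreement between markers is reported as incomplete since it is
inconsistent with a single complete event on one haplotype.

Amplicon prediction is exact string matching of the forward primer and the
reverse primer's reverse complement against each spliced isoform; with
flanking primers the aberrant-minus-normal difference equals the pseudoexon
length, and a primer inside the pseudoexon amplifies only the aberrant
isoform.

## Classification

The point scheme is taken at face value: exactly PVS1 = 8 and
PM2 = PP1 = PP3 = PP4 = 1, pathogenic iff the sum ≥ 10 (inclusive); all
other outcomes are reported as `not_demonstrated` because the scheme
defines no benign-side or intermediate classes, and no weights are invented
for criteria it never assigned points to. Auto-assertion encodes the
interpretive chain: PM2 from absent/zero population AF, PP3 from the splice
gate, and PVS1 only when the event is out of frame *and* complete *and*
NMD-predicted — completeness is what elevates the aberrant transcript to a
null allele, which is this package's documented reading of when a splice
event counts as loss of function. PP1 (segregation) and PP4 (phenotype)
are family-level observations and are never inferred from molecular data;
they enter only as user flags. Missing upstream results mark criteria as
`not_evaluable` rather than silently unasserted.

## Synthetic data

The generator is a pure function of a `ScenarioSpec`; identical specs give
byte-identical FASTA/VCF/tables. Defaults encode the worked study
conditions: six exons, host intron after coding base 531, a 56-bp
pseudoexon at offsets +1422..+1477, the A>G variant five nucleotides
downstream of the cryptic donor (+1482), donor-gain delta 0.93 planted in
the VCF, 500 background variants, NMD efficiency 0.5, peak noise CV 5%.
The host intron is sized to at least twice the variant offset so the
variant's canonical HGVS description keeps the donor-side `+` form, and a
guard region around the scan window is scrubbed of GT/AG dinucleotides so
the planted pair is provably the unique viable one. The CDS is built from
non-stop codons (ATG…TAA), introns are canonical GT…AG.

Background variants are drawn across six classes — low quality, off panel,
common AF, shared by the duo, below the splice gate, and missing unaffected
genotype — so every filter's rejection path (not just its accept path) is
exercised, and by construction exactly the planted variant survives the
chain. A `negative scenario` flag (`in_frame=True`) lengthens the
pseudoexon to 57 bp to exercise PVS1 withholding.

Peak simulation scales the cDNA alt-allele quantity by 1 − *e* under
mean-one multiplicative log-normal noise at the stated CV (σ² = ln(1+CV²));
at CV = 5% the relative bias of the ratio-of-ratios, exp(2σ²) − 1 ≈ 0.5%,
is far inside the ±0.03 recovery tolerance used in the tests. What the
generator does *not* emulate: read-level data and alignment artifacts,
sequencing error, real population AF spectra and linkage, branch-point or
splice-strength sequence context, heteroduplex bands, or PCR saturation —
so passing tests demonstrate the correctness of the *interpretation logic*
under the stated model, not robustness to those real-data effects.

## Problem sizes and determinism

The test suite runs the coordinate round-trip exhaustively on 30 random
transcripts, the translation oracle on 100 seeded genes, NMD-efficiency
recovery at five efficiencies × 50 replicates, and a 20-seed end-to-end
sweep with 500 background variants per seed; these sizes keep the whole
suite in a few seconds while leaving Monte-Carlo error well below the
asserted tolerances. All randomness flows from explicit integer seeds
through `numpy`'s `default_rng`; hypothesis profiles are derandomized.

## Known limitations

Single-pseudoexon events only; no multi-transcript projection, UTR
coordinates, liftover, or full HGVS grammar (delins, inversions, repeats);
no splice-site strength or branch-point scoring; the NMD flag is a rule
prediction, not a measurement; the ACMG engine implements exactly the
five-criterion point scheme, not the full 28-criterion framework.

## Configuration

All thresholds (depth/AD/VF gates, AF and splice gates, NMD distance,
imbalance threshold, ACMG weights and threshold, sample names, seed) live
in a strictly-validated sectioned YAML file; unknown sections or keys are
rejected, and `pseudoexon show-config` prints the effective values so no
cut-off is hidden. Flat key = value pairs grouped into sections were the
design intent; YAML was chosen as the field-standard concrete syntax for
exactly that shape.
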