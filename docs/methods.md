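# Methods

This note documents the models, conventions and design choices behind
`fosjump`, in the order the pipeline runs.

## Vector geometry

The package models two circular vector layouts. The `pHZAUFOS3`-style map
(8 kb) carries four I-SceI sites: two flanking the cloning site — releasing
the insert together with the two vector end stubs, VES1 (348 bp) and VES2
(300 bp) — and two in the skeleton, so that digesting the empty vector
yields only 2–3 kb pieces (652 / 2449 / 2449 / 2450 bp by default). oriV and
CmR sit on opposite sides of the cloning site, ~0.5–1 kb outside the VES
arcs. The `pcc2FOS`-style map has two sites flanking the cloning site and
oriV/CmR on the same side. The true backbone sequences are not public; the
module synthesises a fixed placeholder sequence honouring all published
lengths and the genuine 18-bp I-SceI recognition motif (TAGGGATAACAGGGTAAT),
because every downstream step depends only on the geometry.

Conventions: coordinates are 0-based half-open and wrap modulo the circle
length; I-SceI cuts are modelled blunt, at the motif's lowest coordinate
(the enzyme's staggered 4-nt overhang has no downstream consequence); the
motif is searched on both strands (it is non-palindromic, so strand matters
for placement, not for cutting). Cloning excises the 4-bp cloning-site
interval and splices the insert in its place, so VES1/VES2 are exactly
adjacent to the insert.

## Simulator

Defaults are the study conditions throughout:

| parameter | default | meaning |
|---|---|---|
| insert_mean / insert_sd | 38 000 / 2 200 bp | Fosmid insert model |
| insert_select | 30 000–45 000 bp | gel size selection |
| shear_mean / shear_sd | 15 000 / 2 000 bp | mechanical shearing |
| shear_select | 12 000–18 000 bp | second gel selection |
| pe_select | 5 000–10 000 bp | released-molecule selection |
| end_len_mean / end_len_sd | 7 000 / 2 000 bp | direct route, per pair |
| read_accuracy | 0.90 | long-read per-base accuracy |
| coverage | physical clone coverage | clone-span bases / genome |

Sampling details: clone count accumulates inserts until the target physical
coverage is reached (count ≈ coverage × genome / mean insert); normals are
rejection-truncated to their windows; positions are uniform on contigs
weighted by length and inserts never wrap contig ends. Shearing linearises
the clone circle at a uniform point and cuts sequentially with truncated-
normal piece lengths. Fragment categories (paired/single/insert-only/
vector-only) follow junction content; selection requires full containment
of oriV and CmR. Released molecules are assembled segment-exactly
([VES1|endA|Amp|endB|VES2], Amp tag 1218 bp), so every genomic base maps to
exactly one recorded donor interval. Single-end fragments release a
one-sided molecule plus vector debris up to the nearest skeleton cut;
fragments without any I-SceI site stay circular and are lost.

Two routes produce paired-end molecules. The **mechanical** route above is
the geometric model; its summed genomic end length is emergent,
≈ shear_mean − vector arc ≈ 7 kb, but the 5–10 kb molecule selection clips
the upper tail, so the realised mean is ~6.3 kb. The **direct** route draws
the summed end length from Normal(7 kb, 2 kb) per clone (split uniformly
with a 50-bp floor, no molecule-level selection), matching how simulated
read sets are usually parameterised, and is the route used for parameter-
recovery checks. The choice is a config switch, not a hidden behaviour.

Chimaeras are injected by cyclically deranging end B across a chosen subset
of molecules, so the injected fraction is exact and both donors stay in the
truth record. This mimics the observed phenotype (wrong partner / wrong
spacing) without modelling ligation chemistry.

The read error model is i.i.d. per base at rate 1 − accuracy, split 1:1:1
substitution:insertion:deletion, with constant Phred quality derived from
the accuracy; no homopolymer or quality-decay structure. This is sufficient
to stress tag detection at 0.90 accuracy, which is what the extraction
thresholds were chosen for. Everything is driven by a single
`numpy.random.default_rng` seed; fixed seed ⇒ byte-identical FASTQ and
truth tables.

Structural variants are injected through a per-contig segment plan
(deletion, tandem duplication, inversion; translocation as a reciprocal
tail swap with no length), which yields exact donor↔reference coordinate
maps, an event ledger (1-based inclusive on disk), and an exact inverse
(`revert_svs`) used as a round-trip oracle.

## End extraction

Tags (VES1, VES2, Amp) are located with exact 13-mer seeds clustered by
diagonal (≥ 3 seeds per candidate), then scored by edlib infix alignment of
the full tag in the candidate window, on both strands. Identity is
1 − edits/tag_length, so missing coverage also penalises identity; defaults
(identity ≥ 0.75, cover ≥ 0.5) were chosen for 0.90-accuracy reads, where
≥ 95% of Amp tags are recovered. Reads with two Amp hits are rejected as
ambiguous rather than split. Layout resolution accepts
VES1–genomic–Amp–genomic–VES2 on either strand; one VES plus the Amp tag
yields a single end, and a spurious partial second VES (single-end
molecules can carry vector debris with one) falls back to the consistent
single-end reading.

Emission convention: FES-1 is the VES1-adjacent genomic segment written
5'→3' away from the junction (id suffix `/1`); FES-2 is the VES2-adjacent
segment written 5'→3' *into* the insert, i.e. reverse-complemented relative
to the molecule (`/2`). A true pair therefore aligns convergently, and the
outer span equals the insert length. VES stubs are excluded from the
reported FES sequences. Ends shorter than 50 bp are removed (a 50-bp end is
kept); a pair with one short end degrades to a single end.

## Classification and summaries

Unambiguous pairs have both ends aligned at mapping quality > 0 (an SV
preset with minimum mapq 60 is available). Span is the outer-to-outer
distance; orientation is convergent / divergent / tandem from the canonical
(leftmost-first) order. Labels: different contigs → `chim_intercontig`;
non-convergent → `chim_orientation`; convergent span < 20 kb →
`chim_short`, > 50 kb → `chim_long` (additionally flagged when > 100 kb);
otherwise `correct`. Duplicates collapse on identical 5' start sites on
both sides (strict identity; first read id represents). The reported
chimaera rate is, by default, every non-correct unique pair ("results"
convention); a stricter "methods" convention (orientation anomalies,
inter-contig, and spans > 100 kb only) is selectable. The span histogram
uses 1-kb bins over unique same-contig pairs, as percentages.

Best-alignment tie-breaks when loading SAM/BAM/PAF: higher mapq, then
higher score, then lexicographic contig/position — deterministic.

## Built-in aligner

Simulated, error-free ends are placed by exact 31-mer anchor voting against
a sorted-array k-mer index: one supported placement cluster → mapq 60,
several (exact repeats) → mapq 0, none → unaligned. The split mode chains
anchors into collinear, strand-consistent segments (diagonal tolerance
100 bp, ≥ 3 anchors per segment) for small-SV signatures. The aligner
exists to make the pipeline self-contained on simulations; real data should
arrive as SAM/BAM/PAF from a production aligner.

## SV calling

Discordant jumps cluster by single linkage within a shared signature
(label, orientation, contig pair). Intra-contig jumps link when their
inner-gap intervals lie within `merge_dist` (default 3 × insert_sd) of each
other — pairs supporting one event all contain the rearranged interval in
their inner gap, so overlap, not end proximity, is the right criterion
(end footprints spread over a full insert length). Inter-contig jumps link
when their implied junction positions agree within one insert length
(default 45 kb). Interpretation: convergent-long → deletion (size = median
span − insert mean), convergent-short → duplication (insert mean − median
span), orientation anomalies → inversion (a config flag reads tandem
clusters as duplications instead; conventions differ between callers),
inter-contig → translocation (length reported as "Non"-equivalent None).
Breakpoint intervals use the inner boundary convention (shared inner gap);
sizes are statistical estimates with standard error ≈ insert_sd/√support.
Calls need ≥ 9 independent (non-duplicate) pairs by default.

Small events come from split alignments of long single ends used as
whole-genome reads: reference gap ≥ 30 bp → deletion; reference overlap →
tandem duplication; extra read sequence → insertion; strand flip →
inversion, whose signature interval spans the whole inverted region
(the flipped segment maps to the far edge of the inversion), so one
crossing read already estimates the inversion length. Signatures cluster
at ± 500 bp by type; calls need ≥ 7 distinct reads. Reads crossing large
events also produce split signatures, so the two callers overlap on
intermediate sizes — by design, as cross-confirmation.

Output: VCF 4.2 (SVTYPE/END/SVLEN/SUPPORT; translocations as mated BND
records) plus a TSV mirroring the support/type/length/coordinate layout of
rearrangement tables; coordinates 1-based inclusive on disk.

## Scaffolding

An aligned end joins its contig's tail when on the + strand and its head on
the − strand; the gap estimate is insert_mean − (two end-to-edge
distances), averaged per link. Links need ≥ 2 supporting jumps. Greedy
acceptance (support, then combined length, then lexicographic) joins free
contig ends under a union-find cycle guard; self-links and occupied ends
are rejected and logged. Negative gaps clamp to a single N (no overlap
merging). A post-hoc pass independently verifies that every adjacency in
the output is backed by a link joining exactly the facing ends. Assembly
statistics follow the standard definitions (N50 by cumulative half; the
"< 30 kb" count uses strict inequality). Parity with any specific
production scaffolder is a non-goal; the acceptance surface is truth
recovery on simulations and N50 monotonicity.

## Problem sizes used in the test suite

The default suite simulates 1-Mb genomes at 10–20× physical coverage for
fidelity and scaffolding checks, 2-Mb two-contig genomes at 20× for SV
recovery (with single-end reads at 20× sequence coverage for the split-read
caller — single ends act as whole-genome reads there), and ≥ 2 000 pairs
per point for chimaera-rate calibration. These sizes give statistical
margins (3 SE bounds, support ≫ thresholds) while keeping a full run in
tens of seconds.

## What the simulations do and do not show

The generator reproduces the construction geometry, selection logic, error
rate and chimaera phenomenology, with exact truth. It does not model
cloning bias (GC, chromatin), PFGE trapping physics, polymerase/ZMW
behaviour, CCS consensus, quality-score structure, or biological repeat
landscapes beyond what random sequence contains. Passing tests therefore
demonstrate correctness of the pipeline's logic and its statistical
behaviour under the stated models — not performance on real genomes, where
repeat content and alignment ambiguity dominate. Real-data use should go
through a production aligner and treat the built-in one as a harness
component.

## Known limitations

* The extraction thresholds are tuned for ~0.90 accuracy; much noisier
  reads will need looser identity/coverage settings.
* Duplication/inversion orientation conventions vary across callers; both
  are exposed but only the defaults are exercised end-to-end.
* Inversions are called from split reads; the paired-jump inversion route
  (tandem-orientation clusters) is implemented but typically under-supported
  for small inversions at realistic physical coverage.
* The scaffolder does not fill gaps, merge overlaps, or correct contigs.
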