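# Methods

`dipscreen` models the computational core of a mammalian-cell domain-insertion
optogenetic screen: a transposase scatters a photosensor domain (AsLOV2,
residues 408–543 of *Avena sativa* phototropin 1) across every nucleotide
position of a target coding sequence (here the Gal4(1–147)-VP64 transcription
factor), the library is expressed one variant per cell from a genomic landing
pad, and iterative dark/light FACS sorting enriches variants whose
transcriptional output switches with illumination. The package implements the
construction arithmetic, a synthetic sequencing readout, the junction-read
mapper, the selection-dynamics simulator, the coverage/enrichment statistics,
and the in-vitro binding-affinity fits used to characterise hits.

## Construction model

**Coordinates.** An insertion position `p` is a 0-based gap coordinate: the
number of target-CDS nucleotides 5′ of the insertion point, `0 ≤ p ≤ L`. Mu
transposition duplicates `d` target bases at the insertion point (`d = 5` by
default — the canonical MuA target-site duplication; the screen's own
protocol does not pin the length, so it is exposed as configuration). The
fusion for a forward insertion is

```
cds[0 : p+d] + s5 + domain + s3 + cds[p : L]
```

so the d-mer `cds[p:p+d]` appears on both sides of the cassette. Locally
repetitive targets make neighbouring `p` values produce identical fusions;
every position (simulated or mapped) is therefore *normalised to the leftmost
consistent `p`* (`p → p−1` while `cds[p−1] == cds[p+d−1]`), which makes
simulator truth and mapper output comparable without ambiguity.

**Frame variants.** The cassette exists in three versions differing only in
scar length: LOV01 adds one base 5′ of the domain, LOV02 two bases at each
end, LOV03 one base 3′. With `d = 5` and a domain length divisible by 3,
each variant preserves the downstream reading frame, and the domain itself is
in frame iff `(p + d + len(s5)) mod 3 == 0`. The three variants therefore
claim the residue classes p ≡ 0, 2, 1 (mod 3) respectively — a partition: at
every nucleotide position exactly one variant yields a fully in-frame fusion.
Frame arithmetic depends only on scar *lengths*; the default scar base
identities (`G`, `GG`/`CC`, `C`) are a documented convention and configurable.

**Site naming.** A functional construct is labelled by the longest common
prefix of the fusion's translation and the intact target protein ("insertion
after residue N"). This is computed by translation rather than closed-form
arithmetic because the duplicated/scar codons can extend the conserved prefix
(a scar codon may coincidentally encode the target's next residue — a wobble
effect that makes any closed-form bound slightly leaky). On the packaged
Gal4-VP64 target the three in-frame LOV02 insertions at p = 62, 65 and 83 are
assigned sites 22, 23 and 29 — insertions after Ser22, Lys23 and Ala29, the
hit cluster in the zinc-finger DNA-binding domain. Note the duplication
attribution: the in-frame position *inside* Ser22's codon (p = 65) preserves
Lys23's codon intact within the duplicated segment and is therefore the
site-23 construct; the site-22 construct is the neighbouring in-frame
position p = 62, whose 5-bp duplication window covers Ser22's codon.

**Packaged sequences.** The bundled target and domain CDSs are *synthetic
reconstructions* (`*_synthetic_cds.fasta`): canonical protein sequences
(Gal4 DNA-binding domain 1–147 with its six zinc-coordinating cysteines,
a GS-linked 4×VP16 activation domain, AsLOV2 408–543) reverse-translated
with a fixed one-codon-per-residue table. Downstream arithmetic depends only
on lengths and local bases, not codon choice. One consequence of the naive
reverse translation is that the four VP16 repeats are exact 33-nt repeats, so
flank k-mers inside the activation domain map to multiple loci and the mapper
counts such reads as ambiguous — a conservative, realistic behaviour.

## Synthetic sequencing readout

The simulator draws `n_clones` insertion events i.i.d. from a position
distribution (uniform by default) × an orientation Bernoulli
(`reverse_fraction = 0.5`; Mu inserts in both orientations), defaulting to
190-fold clone coverage of the available positions, the colony coverage
measured for the transposition reaction. Amplicons (plasmid flanks + fusion)
are sheared to fragments of 300–400 bp (uniform start and length), and one
single-end 300-nt read is taken from a uniformly chosen fragment end/strand —
the MiSeq-like readout. Substitution errors are i.i.d. at `per_base_error`
(default 10⁻³); indels are not simulated (negligible at this scale for the
platform modelled), though the mapper's anchor search tolerates them. Quality
strings are constant at the Phred encoding of the error rate, since nothing
downstream is quality-aware. Read names carry full provenance (source event,
fragment coordinates, strand), which is what makes the zero-noise
simulate→map round-trip an exact, testable inverse.

What the generator deliberately does not emulate: PCR and GC bias, duplicate
fragments, paired-end structure, genome-extraction inefficiency, and
quality-score decay along the read. Passing round-trip tests therefore show
the mapper is correct on the declared error model, not that it is robust to
every artefact of real libraries.

## Junction mapping

Reads are scanned (in both orientations) for the four cassette-end anchors —
the first/last 15 nt of `s5+domain+s3` and their reverse complements — with
≤ 1 edit (exact substring search first, edlib infix alignment as the tolerant
fallback; the alignment's end coordinate is used for right-side flanks
because an anchor truncated by a fragment boundary aligns with a deletion
that would otherwise shift the junction by one base). The target-derived
flank adjacent to a junction is looked up in an exact k-mer index of the CDS
(k = 20, both strands), with a 3k-neighbourhood fallback tolerating one
mismatch. Left junctions give `p = offset + k − d`, right junctions
`p = offset`; both are normalised leftmost, so the two junctions of one
insert always agree. Reads are accounted exhaustively:
`total = mapped + unmapped + ambiguous + non-junction`, where ambiguous
covers multi-locus flanks and conflicting junctions, and non-junction covers
reads without an anchored junction carrying ≥ 20 nt of target flank. There is
no read deduplication (random shearing makes fragment starts near-unique) and
no external aligner: the targets are sub-kilobase, so exact k-mer lookup is
both faster and easier to reason about.

## Screen simulator

Single-cell GFP is autofluorescence floor (10 AU) plus a log-normal with the
variant's condition mean and CV 0.6 — a stand-in chosen to look like flow
histograms, not fitted to any. Four phenotype classes span the observed
library: dead (floor in both conditions; out-of-frame or disruptive
insertions), constitutive (high in both), truncation-like (intermediate in
both; insertions clipping some VP16 repeats retain partial activity), and
photoswitchable (high in dark, floor under blue light — full shutoff, since
strong switchers are indistinguishable from autofluorescence when lit).

A sort assigns cells to variants multinomially (`n_population`, default
5×10⁵), draws expression under the gate's condition, applies a keep-high or
keep-low gate at an absolute threshold or a quantile of the current
population (default: the median), and subsamples passers without replacement
to `n_sorted` (default 10⁵ cells, the number sorted per round in the screen
modelled). Regrowth between rounds is neutral multinomial resampling — no
fitness differences.

**Schedule.** The default is three alternating dark-keep-high /
light-keep-low pairs ("three rounds of dark/light selection"). The
alternative preset — one dark recovery followed by light-low sorts only — is
provided, but with quantile gates it discriminates photoswitchable from dead
variants only once (the two classes are identical under light), which cannot
reliably float a single photoswitcher above a thousandfold excess of dead
variants; the alternating schedule re-applies the dark discrimination each
round and does. Real gate placements were tuned by eye round-to-round;
quantile gates are the package's explicit, reproducible stand-in.

## Coverage, enrichment, clustering

Library calculators: fold coverage = clones/sites; expected fraction of sites
seen at least once under Poisson sampling = 1 − e^(−fold); union coverage of
k independent libraries = 1 − (1 − p)^k. With the measured single-library
coverage p = 0.803 and the three frame-shifted libraries, the union is
99.24% — the basis of the ">99% of amino-acid insertion sites" claim.
Coverage plots use log10(x+1) so zero-count positions survive a log axis.

Enrichment between two profiles is log2((f_b + ε)/(f_a + ε)) on
*within-profile frequencies*, with ε = pseudocount / n_positions (positions
in the union of both profiles). Making ε a pure frequency constant keeps the
table antisymmetric under profile swap and exactly invariant to sequencing
depth — the property that makes rounds of different depth comparable. Hit
clustering is 1-D single linkage over amino-acid sites with a 5-residue gap;
by default only functional (forward, in-frame, stop-free) insertions are
aggregated into sites, with other categories tallied separately.

## Binding model and fits

Anisotropy titrations are modelled as r = r_free + (r_bound − r_free)·b with
the exact single-site, ligand-depletion-corrected bound fraction

```
b = ((P + T + K_D) − sqrt((P + T + K_D)² − 4·P·T)) / (2T)
```

The depletion-corrected quadratic is the default because the probe (T = 2 nM
labelled DNA) is comparable to K_D (~6 nM) in the experiment modelled; the
hyperbola b = P/(P + K_D) is available for comparison and is recovered as
T → 0. The simulated titration protocol mirrors the instrument protocol: a
protein-free baseline point (anchoring r_free), then a doubling series from
6.2 nM until the probe is >98% bound at the ground truth, Gaussian noise of
sd 0.005 anisotropy units, two technical replicates. Plateau defaults
(r_free = 0.10, r_bound = 0.25) are typical for a ~27-bp labelled duplex and
a ~30 kDa binder.

Fitting is pooled nonlinear least squares over (log K_D, r_free, r_bound) —
the log-parameterisation enforces positivity — initialised from the curve
endpoints and the half-rise concentration, with standard errors from the
Jacobian at the optimum and an explicit converged/boundary flag. Ground
truths used in the recovery analyses are the screen's measured constants:
6.4 nM (dark state), and 8.6 / 16.6 nM for the slow-photocycling V416L
variant in dark / blue light. The light value is taken as the larger of the
pair on mechanistic grounds: illumination suppresses DNA binding in this
system, and the V416L dark state should resemble the wild-type dark-state
affinity, which 8.6 nM matches.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng`; a single pipeline
  seed is expanded with `SeedSequence` into independent per-stage streams, so
  any stage can be rerun in isolation and full reruns are byte-identical.
- Degenerate inputs fail loudly: non-ACGT bases, frame-breaking designs,
  out-of-range positions, over-stringent gates (zero passers), malformed
  FASTQ records (with the record number), and non-converged or boundary fits
  are all errors or flags, never silent.
- Tie-breaks: hit-cluster top sites prefer the smaller site on equal counts;
  anchor search takes the leftmost occurrence.
- Problem sizes in the shipped analyses and tests (populations of 10⁵ cells,
  2×10⁴ sorted, thousands of reads, 200 titrations) are scaled-down working
  sizes chosen so every analysis re-runs in seconds while keeping Monte-Carlo
  margins interpretable; all are configuration, not constants.

## Known limitations

- The screen simulator has no mCherry/BFP co-selection, growth-rate or
  cell-cycle effects, and no induction kinetics; selection acts on GFP alone.
- The mapper handles single-domain insertions only — no general structural
  variants, no SAM/BAM emission, and frame-variant identity comes from
  per-library configuration rather than scar-base inference by default.
- Binding fits ignore photocycle kinetics; dark/light are metadata labels on
  curves, and the model cannot represent partially cycling populations.
- The packaged CDSs are reconstructions; analyses that depend on exact codon
  identity of the real plasmids (none in this package) would need the real
  sequences.
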