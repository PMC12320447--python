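# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Cassette model and frame arithmetic

A SEED cassette is assembled as

```
LHA · SA-block · filler5 · [elements per 3′ variant] · RHA
```

where the SA block is polypyrimidine tract + branchpoint + 3′-AG acceptor
and the four 3′ variants are: second P2A + splice donor (`P2A_SD`, the
default — reuses the endogenous downstream exons and poly(A)); no second
P2A (`OPEN_READTHROUGH` — the payload open reading frame is completed
in-frame by the endogenous downstream exons, as used for receptor chains
built on an endogenous constant domain); stop + exogenous poly(A)
(`POLYA`); and a promoter-driven payload with the spliced target transcript
terminated immediately after the acceptor (`EXOGENOUS_PROMOTER_STOP`).

Frame closure is pure modular arithmetic. Let `u` be the cumulative coding
length of the retained upstream exons mod 3 and `p` the phase of the exon
that resumes after the donor (cumulative CDS length upstream of it, mod 3).
The 5′ filler has length `(−u) mod 3`; because every internal element (P2A,
payload) is a multiple of 3, the 3′ filler alone re-creates the downstream
phase and has length `p`. Both fillers are < 3 nt, which makes the solution
unique — the test suite checks all nine `(u, p)` cases against exhaustive
enumeration.

**Splicing model.** `simulate_splice` honors exactly one synthetic
acceptor/donor pair and predicts the mature mRNA as upstream exons +
synthetic exon (+ downstream exons when a donor is present). It then
translates from the annotated start codon and *fails loudly* (`FrameError`)
if no in-frame stop exists, the payload translation is not contained
verbatim in the predicted protein, or the downstream endogenous peptide is
out of frame. This is a validation engine, not a splice-site predictor:
cryptic splice sites, acceptor/donor strength and exon-definition effects
are explicit non-goals. Loci are strand-normalized on GFF3+FASTA ingest so
all downstream logic is strand-agnostic.

**Element defaults.** The SA block, donor, poly(A) signal and promoter
defaults are short synthetic elements chosen to be recognizable and
unambiguous in sequence searches; real constructs should substitute
validated elements via `CassetteElements` (strict mode makes this
mandatory). The P2A default is the canonical GSG-linked porcine
teschovirus 2A (66 nt, `GSGATNFSLLKQAGDVEENPGP`); recorded cleavage offsets
point at the terminal proline. Homology arms default to 500 nt, a typical
length for AAV-delivered repair templates. The integration-site rule —
cut site intronic and strictly between the signal-peptide and
transmembrane annotations when present — encodes the requirement that the
truncated target keeps its targeting signal but loses surface display.

## Scanning and saturation library design

At each scanned position the substitution set is: alanine, plus the top
`n = 4` other residues ranked by BLOSUM80 score against the native residue
(`n = 5` matrix picks when the native residue is alanine), plus any residue
observed at that column of a homolog alignment and not already chosen.
Ranking ties break alphabetically by one-letter code, making the design
deterministic. Each substitution gets up to two codons, ranked by human
codon-usage frequency (per-mille table embedded in `codons.py`;
configurable); single-codon amino acids (M, W) contribute one. Controls
per position: one synonymous swap (highest-usage codon differing from the
reference codon; skipped where none exists), one single-residue deletion,
and a TGA stop at a configured subset of positions. Every member's oligo
is the reference DNA of the segment with exactly the designed codon
replaced (or removed), so the member table doubles as the exact-match
reference for quantification. `validate_member_table` re-translates every
oligo and checks it realizes exactly its annotated change — the same
machinery validates externally synthesized oligo tables.

Saturation libraries expand an IUPAC degenerate codon (NNN default, NNK
supported) at one residue: 64 (or 32) members, stop codons flagged as stop
controls, native-residue codons as synonymous.

Residue numbering is 1-based with a configurable offset
(`first_residue_number`, default 101) so positions can be reported in
domain numbering.

## Amplicon quantification

Reads are searched for the literal upstream anchor, then the downstream
anchor after it; no mismatches are tolerated in anchors, and the region
between them maps to members only by exact identity — matching the
zero-mismatch workflow this kind of short, fully enumerated library allows.
Orientation is handled by trying the read and then its reverse complement;
in paired-end mode R1 is tried first and R2 only if R1 fails, so a fragment
counts at most once (the library region fits in one 250-nt read, so merging
is unnecessary). Base qualities are ignored.

Abundance of member *m* is `count(m) / Σ counts` over **non-control**
members; stop and deletion controls are excluded from the denominator
(synonymous members count toward it). All reads are conserved by
construction: `reads_in = no-anchor discards + unmapped regions + Σ member
counts`, and this identity is asserted on every run.

## Enrichment and epitope calls

With abundances `a_bin`, `a_in`:

- fold enrichment `(a_bin + ε)/(a_in + ε)`; the default pseudocount is one
  read on the abundance scale of the shallower sample,
  `ε = 1/min(mapped_noncontrol)`, which keeps zero-count members finite
  without dominating well-covered ones. Linear and log2 scores are both
  reported.
- bin ratio = enrichment in the antibody-bound bin / enrichment in the
  unbound bin; members are ranked ascending (least → most conservative),
  ties broken by bound-bin enrichment then member id.
- per-amino-acid scores are unweighted means over the codons tested for
  that amino acid at that position.
- a substitution *escapes* when `log2(mean bin ratio) ≤ −1` (a two-fold
  preference for the unbound bin); a position is called part of the epitope
  when ≥ 50 % of its non-native substitutions escape. Both thresholds are
  configurable; the defaults are the package's own choice of a conservative
  round number, validated against the simulator's planted truth.

## ddPCR

Naive mode (default): `100 × FAM⁺/HEX⁺`. Poisson mode:
`100 × λ_FAM/λ_HEX`, `λ = −ln(1 − k/N)`. The two differ by a factor
`≈ 1 + (k_FAM − k_HEX)/2N`: they converge as droplet occupancy vanishes,
and with FAM far rarer than HEX the Poisson-corrected ratio is slightly
*below* the naive one (the reference channel is inflated more). Saturated
channels (`k = N`) are an error in Poisson mode.

## The synthetic screen generator

The generator emulates a pooled knock-in sort-seq screen end to end:

1. **Truth.** Each member gets a binding-loss probability — the chance a
   cell expressing it escapes antibody binding. Substitutions at planted
   escape positions draw from U(0.80, 0.95); other substitutions from
   U(0.0, 0.2) (residual, continuous variation that avoids degenerate rank
   ties); synonymous members are exactly 0; deletions and stops are 1.0
   (no surface receptor, but they are excluded controls anyway). Library
   composition is Dirichlet(50) over members — mild, realistic unevenness.
2. **Sorting.** 50 000 cells are allocated multinomially to members; each
   cell routes to the antibody-negative bin with its member's binding-loss
   probability, otherwise to the positive bin.
3. **Sequencing.** 100 000 reads per bin (input, negative, positive)
   sample the bin composition; each read carries the 20-nt upstream anchor,
   the member's library region and the 20-nt downstream anchor, centered in
   a 250-nt read with random flanks, plus independent per-base substitution
   errors at rate 10⁻³. A fixed seed makes the FASTQ byte-identical.

Because `P(neg bin) = b` and `P(pos bin) = 1 − b`, the expected bin ratio
is monotone in `b` (∝ (1−b)/b up to bin-size normalization), so rank
recovery of the planted effects is the designed behavior, degraded only by
sampling noise, sequencing error and the pseudocount. At the default scale
(~810 members, 100 k reads/bin) the Spearman correlation between true
binding loss and −log2(bin ratio) is ~0.89 and the planted positions are
recovered exactly; these sizes run in well under a minute on one CPU.

What the generator does **not** emulate: PCR amplification bias and
chimeras, index hopping, quality-score structure, indel sequencing errors,
cell-sorting impurity, expression-level variation among substitutions, and
receptor-assembly effects. Passing recovery tests therefore demonstrates
the correctness of the counting/enrichment arithmetic under the stated
sampling model, not robustness to those real-data artifacts.

The default scanning design on the synthetic segment yields ~760–810
members depending on the seed (the count is an output of the design rules
— picks, homolog additions, codon multiplicities — applied to the random
segment and homolog set). The segment generator avoids adjacent identical
codons, since deleting either of two identical neighboring codons yields
the same oligo and exact-match counting requires unique member sequences.

## Numerical and degenerate-input choices

- Coordinates 0-based half-open throughout; residue numbers 1-based with
  offset.
- Duplicate member oligo sequences are an error at table load, not silently
  merged.
- All mapped reads on controls → error ("no usable reads") rather than a
  0/0 abundance.
- Zero enrichment denominators without a pseudocount → error.
- Epitope-call thresholds must be positive; empty amino-acid groups are
  simply absent from profiles.
- RNG: a single integer seed threads through every generator
  (`numpy.random.default_rng`); default 42.

## Known limitations

- The splice simulator validates the designed acceptor/donor pair only; it
  cannot detect cryptic splicing or weak elements.
- Exact matching discards any read with a single error in anchors or
  region (~20 % of 250-nt reads at error rate 10⁻³); this loses depth but
  never miscounts, which is the right trade-off for a fully enumerated
  library and is how the per-sample audit counts (reads in / anchored /
  mapped / control) should be read.
- The codon-usage table is the standard human per-mille table; organism
  choice affects which two codons are synthesized per substitution, not
  the amino-acid design.
- ddPCR mode choice matters above ~2 % droplet occupancy; both modes are
  reported deliberately.
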