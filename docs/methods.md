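# Methods

## Motif model

The two signatures are short gapped consensi: the toxin RNase motif
RX₄HXY and the antitoxin nucleotidyltransferase motif GSX₁₀DXD (15
residues: G, S, ten ANY, D, ANY, D). The pattern grammar covers
everything these need: a letter is an exact residue, `X` is ANY, an
integer suffix is a fixed repeat, `(a,b)` a repeat range (the ranged
RNase core `RX(4,6)H` uses it), `[ACD]` a residue set. Scanning reports
every distinct `(start, end)` window satisfying the pattern, anywhere in
the sequence, overlapping hits included — downstream pairing only needs
"at least one hit", so no non-maximal suppression is applied. Ambiguity
codes in input sequences (B, Z, J, U, O, X) match ANY positions but
never a specific-residue position; this is deliberately conservative and
cannot create a false motif call.

Two scanning modes exist because consensus scanning and PWM scanning
answer slightly different questions. The exact mode is the default for
mining. The PWM mode builds a base-2 log-odds matrix from counted sites
with background-proportional pseudocounts,
`log2(((c_ia + pc·b_a)/(n + pc))/b_a)`, and assigns each window score an
**exact** p-value: scores are discretized (×1000, rounded — FIMO-like
precision at negligible cost for widths up to ~20), and the null score
distribution is the convolution of per-column score distributions under
the background; the p-value is the discrete survival function. For
widths ≤ 4 this is verified against exhaustive enumeration of all 20^k
sequences to 1e-9. The default background is the residue composition of
the scanned set; tests use the uniform background, under which the
information content of an invariant column is log2(20) ≈ 4.32 bits and
of a background-shaped column 0 bits.

## Pairing and classification

"Neighboring genes" defaults to adjacent locus ranks on the same contig
(rank distance 1), any strand, with at most 500 bp between gene ends
(negative gaps, i.e. overlaps, always qualify). All three knobs are
configurable; the default mirrors the canonical arrangement of the
antitoxin gene immediately upstream of the toxin gene in an operon.
Coordinates are 1-based inclusive at the GFF3 boundary and 0-based
half-open internally.

Each gene joins at most one pair, to prevent double counting in the
census. The assignment is a maximum-cardinality matching (blossom
algorithm via networkx) over the candidate toxin–antitoxin edges, with
strictly distinct edge weights preferring (1) smaller rank distance,
(2) an upstream antitoxin at equal distance, (3) earlier locus ranks.
A simple greedy pass was rejected because it is suboptimal on
alternating toxin/antitoxin runs (T-A-T-A-T-A: greedy keeps 2 pairs
where 3 disjoint adjacent pairs exist); the weighted matching reproduces
the greedy answer in ordinary layouts and is deterministic because the
optimum is unique.

Classification is the conjunction of family labels and motif evidence:
Class I requires a toxin in PF01934 or PF08780 **with** an RX₄HXY hit
and an antitoxin in PF01909 with a GSX₁₀DXD hit; Class II requires a
toxin in PF05168 with **zero** RX₄HXY hits and the same antitoxin
evidence. The stricter both-motifs conjunction is used for Class I
rather than family membership alone; a PF05168 toxin that does carry
RX₄HXY fits neither definition and is emitted unclassified with an
explicit flag rather than silently binned. Domain labels are consumed
as an input table (protein_id, family, clan); no HMM searching is
performed. Motifs are scanned on all proteins first and intersected
with labels afterwards — the intersection is order-independent, and
scanning first keeps each stage independently testable.

The census counts classified pairs per taxon and class: total pairs,
total/n_genomes, and 100 × (genomes with ≥ 1 pair)/n_genomes, with
zero-pair genomes kept in denominators. Unclassified pairs are reported
in the pairs table but never counted in the census, so census totals
summed over taxa equal the number of classified pairs.

## Mass analysis

All masses derive from one constants table: IUPAC standard atomic
weights (average) and principal-isotope masses (monoisotopic), with
amino-acid residue masses computed from residue formulas so protein and
small-molecule masses share provenance. Average masses are the default:
intact-protein ESI-TOF and LC-MS small-molecule values are
average-mass-scale quantities; monoisotopic mode is available
throughout. The AMP residue — the mass each phosphodiester-linked AMP
adds — is free 5′-AMP minus one water: C₁₀H₁₂N₅O₆P, 329.21 Da average
(329 at integer precision), 329.05 monoisotopic.

**Cleavage products.** An observed mass is matched against a candidate
table (shipped: the four 5′-NMPs and adenosine; extensible TSV) within a
tolerance (default 0.5 Da). A unique match is returned only when exactly
one candidate fits; two candidates inside the tolerance yield an
explicit "ambiguous" outcome, never a silent best pick.

**Stoichiometry.** An intact-protein mass shift is decomposed over a
set of adduct candidates (shipped: AMP, phospho, acetyl) by exhaustive
enumeration of count vectors with bounded total (default 10), keeping
the vector within tolerance (default 1.5 Da, the scale of intact-mass
accuracy at ~16 kDa) that minimizes total count first and |residual|
second, with name-order tie-breaks — parsimony first, and the signed
residual is always reported. Three average-mass AMP residues predict
987.63 Da; the observed 987.45 Da shift therefore resolves to
{AMP: 3} with residual −0.18 Da, an instrument-scale discrepancy the
tolerance absorbs and the output exposes.

**Deconvolution.** Neutral masses are inferred from positive-mode ESI
charge ladders by a deterministic grid scorer: for each candidate mass
M on a grid (default step 1 Da) the score sums the spectrum's
interpolated intensity at (M + z·1.007276)/z over z in [5, 30],
restricted to the recorded m/z range. Species are extracted greedily:
the best-scoring mass is refined by parabolic interpolation of the score
apex, its predicted ladder positions are removed from the working
spectrum (±1 m/z), and the grid is rescored; extraction stops below a
noise-adaptive threshold (the larger of 30% of the initial maximum and
median + 5·MAD of the score surface). The greedy peel is what suppresses
harmonic artifacts: an M/2 ladder coincides with every even charge state
of M and would otherwise score comparably to M itself. This scorer is a
deliberate, reproducible simplification standing in for the
maximum-entropy deconvolution used on commercial instruments; it is
adequate for the one- and two-species cases this pipeline reasons about,
and makes no attempt at isotope patterns, adduct ladders or abundance
quantification.

## Synthetic data

The generator emulates the mining input universe at desk scale.
Defaults — the package's study conditions: 50 genomes across four taxa
(Proteobacteria 0.4, Firmicutes/Actinobacteria/Euryarchaeota 0.2 each),
30 genes per genome on one contig, one Class I and one Class II pair
planted per genome (antitoxin upstream, same strand, operon-style), and
each of four decoy kinds planted per genome with probability 0.1:
a lone toxin-motif gene, a lone antitoxin-motif gene, a motif pair at
rank distance 3, and a HEPN-labelled gene beside an antitoxin whose
motif ends RX₄H + not-Y. Each decoy violates exactly one mining rule,
so each rule is independently falsifiable. Protein lengths are uniform
on 80–200 aa, intergenic gaps on 20–200 bp, and background residues
i.i.d. uniform over the 20 canonical amino acids — a deliberately
neutral composition that makes accidental motif hits rare but possible,
handled by rejection.

Background proteins are resampled until motif-free (and asserted so in
tests); planted sites have their X positions drawn from the background,
so planted instances vary realistically rather than repeating one
string. Planted units are laid out with at least one background gene
between them, so a decoy can never sit adjacent to a real pair's genes.
The global seed fans out to per-genome child seeds via
`numpy.random.SeedSequence.spawn`, making each genome independently
reproducible and all outputs byte-identical per seed.

Spectra are profile-mode: Gaussian peaks (σ = 0.2 m/z) of equal height
per charge state (an idealized flat charge envelope) on a 0.05 m/z grid
over 600–2000, with optional multiplicative Gaussian intensity noise.

What passing tests on these fixtures show — and what they do not: the
pipeline's rules are each enforced (sensitivity and precision are
exactly 1.0 against the manifest because planted motifs are exact
instances and decoys violate single rules), but real proteomes have
non-uniform composition, degenerate motif variants, annotation errors
and operon structures the generator does not model, so perfect recovery
here bounds correctness of the implementation, not expected performance
on real genomes. Likewise the deconvolution figures (max error ≪ 1 Da
noise-free, < 0.5 Da at 1% noise over 100 masses in 10–30 kDa) reflect
idealized peak shapes and flat envelopes, not instrument reality.

## Numerical choices and degenerate inputs

- PWM score discretization ×1000; survival function exact on that
  lattice; p-value of the minimum achievable score is 1 by construction.
- `information_content` uses pseudocounted frequencies
  `(c + pc·b_a)/(n + pc)`; zero background with nonzero frequency is an
  error, 0·log 0 = 0.
- Empty sequence → empty hit list; sequence shorter than the PWM width →
  no hits; empty genome annotation → empty pair set and census, success.
- Parabolic refinement clamps the apex offset to ±half a grid step;
  grid-edge maxima are returned unrefined.
- Stoichiometry "no solution" is a return value (None), not an error;
  zero shift returns the empty count vector with residual 0.
- All TSV outputs carry a comment line stating column semantics and the
  coordinate convention (0-based half-open).

## Problem sizes

Test and reproduction runs use 50-genome universes (~1,500 genes), 100
deconvolution spectra, 1,000 random 200-mers per scanner-equivalence
check, and exhaustive PWM enumeration up to width 4 (160,000 sequences)
— sizes chosen so the full suite runs in seconds while every check
exercises the same code paths as larger inputs would.

## Known limitations

- The per-taxon census of the original database-scale survey (tens of
  thousands of genomes) is reproduced in mechanism, not in numbers:
  those counts depend on a proprietary database snapshot and are out of
  scope by design.
- No HMM/Pfam searching; domain labels are trusted input.
- Deconvolution assumes protonation-only positive mode and does not
  model isotopes, adducts, or abundance; the charge-envelope shape is
  ignored by the scorer.
- Nucleotide-level sequences in the synthetic GFF3 are coordinates
  only (self-consistent, but no codon-level sequence is emitted).
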