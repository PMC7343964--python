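# Methods

## Mass model

All arithmetic is monoisotopic. Residue masses are the standard
monoisotopic residue masses to five decimals; the fundamental constants
(proton 1.007276, water 18.010565, ammonia 17.026549, hydrogen 1.007825,
sulfur 31.972071, H₂S 33.987721 Da) are fixed to six decimals. A peptide's
neutral mass is the residue sum plus one water; m/z is (M + z·H⁺)/z.
Average masses are deliberately unsupported: every reference value in this
domain is printed as monoisotopic.

Reported m/z values are rounded half-up on the 6-decimal representation
(`round_mz`). This matters only at decimal ties: the dehydroalanine ion of
`CSEIWDR` is exactly 874.405350 Da, which binary floating point would
otherwise round down to 874.4053 while the conventional printed value is
874.4054.

Built-in variable modifications are carbamidomethyl (+57.021464 Da on
Cys), oxidation (+15.994915 on Met) and acetyl (+42.010565 on the protein
N-terminus); users can register others. A cross-linked cysteine can never
carry carbamidomethyl — an alkylated thiol cannot be in a disulfide — and
this is enforced at the type level.

## Digestion

Cleavage is C-terminal to K/R, suppressed before proline by default. The
proline rule is configurable because conventions differ between search
engines; the default matches the prevailing Trypsin/Lys-C behaviour.
Defaults: ≤2 missed cleavages, peptide length 6–60. Coordinates are
1-based inclusive, so site calls read like Cys598 or Cys75. No automatic
N-terminal Met clipping is performed; N-terminal acetylation is modelled
as a variable modification instead.

The reporter-isobaric screen digests each protein and its full reversal
and flags any cysteine peptide whose neutral mass falls within the
precursor tolerance of the reporter's. The motivating case is a protein
tail reading `RDWLESC`, whose reversal is the tryptic peptide `CSELWDR` —
isobaric with the `CSEIWDR` reporter because Leu and Ile share a residue
mass. Such decoys absorb genuine reporter-anchored spectra as
high-scoring decoy matches and corrupt the FDR estimate. The search
engine's default is to omit reporter-isobaric peptides from the decoy
side of the index only; the forward database is left intact and conflicts
are reported for the user to act on.

## Cross-link model and the fingerprint

A cross-link's neutral mass is the chain sum minus two hydrogens. b/y
fragments of either chain that contain the linked cysteine carry the
other chain as a constant offset (partner neutral mass − 2H); fragments
without the linked cysteine are independent of the partner, which is what
makes reporter-chain ions diagnostic. Disulfide cleavage yields the
reporter triplet: thiol MH⁺, persulfide MH⁺ + S (homolytic cleavage
leaving both sulfurs on the reporter) and dehydroalanine MH⁺ − SH₂. The
spacings are exactly +31.972071 and −33.987721 Da for any reporter
sequence.

The default fingerprint is {y2, y3, y4, y5, y6, y2*, y3*, MH⁺, MH⁺+S,
MH⁺−SH₂}. y1 is excluded by design: for Arg-terminated tryptic peptides
it is shared with every other Arg-terminated peptide (175.1190) and
carries no reporter specificity. The intact-disulfide "MH⁺ − 2H" species
(906.3774 for `CSEIWDR`) is available as an optional eleventh ion but is
off by default to keep the canonical 10-ion set. Ammonia losses are
generated for reporter y2/y3 only (a flag extends them to all chains).
a-ions, internal ions and isotope peaks are not generated.

One reference-value discrepancy is worth recording: the persulfide ion of
`CSEIWDR` is 940.3651 (= 908.3931 + 31.9721); a figure legend in the
source literature prints 970.3652 for this species, which is not
consistent with a +S gain and is treated here as a typographical slip.

## Scanning

The scanner counts, per spectrum, the fingerprint ions with at least one
peak within an absolute 0.01 Da tolerance, irrespective of intensity.
Matching is per target (one peak may satisfy several targets; nearest
peak wins, exact distance ties break toward higher intensity). The
scanner is identification-free: a full fingerprint flags a candidate
cross-link spectrum but naming the partner requires the search engine.
The default reporting cutoff is 8 of 10 ions. For de novo fingerprint
discovery from confidently matched spectra, a histogram mode counts peak
occurrence across spectra on a 0.001 Da grid.

For uniform random peaks the false full-fingerprint probability has a
closed form (product over ions of per-ion hit probabilities); at 200
peaks over m/z 100–1500 it is ~4×10⁻²⁶, so a full fingerprint in a
negative control is effectively impossible — which the tests confirm
empirically on simulated linear-only and random spectra.

## Search

The search is deliberately a reporter-anchored special case of cross-link
search: one chain is fixed to the reporter (plus configurable
missed-cleavage anchor variants such as `EGSLLRCSEIWDR` and
`CSEIWDRITTHPK`), so the partner is recovered by a mass-window lookup
(precursor neutral mass − anchor mass + 2H, 20 ppm default) over a
mass-sorted index of cysteine tryptic peptides. General all-vs-all
cross-link search is out of scope. Candidates enumerate every cysteine as
the potential linked residue and all variable-modification placements up
to 3 per peptide. Decoys are full-protein reversals; the reporter itself
is never reversed.

Scoring is an additive information score: each matched theoretical
fragment (20 ppm) contributes −log₁₀ of its chance random-match
probability, `p = n_peaks · 2·tol(m/z) / span`, using the spectrum's own
peak density. The score was chosen for analyzability — its null is a sum
over independent near-Bernoulli events with a closed form that the tests
check by simulation — not to emulate any production search engine's
scale. It is deterministic and intensity-free; ranked output uses stable
tie-breaks (score, target-before-decoy, partner sequence, accession,
position), and equal-scoring top candidates (Leu/Ile isobars) are flagged
ambiguous rather than silently resolved.

Spectrum-level FDR keeps the best PSM per spectrum, estimates FDR at
score s as `#decoys ≥ s / #targets ≥ s`, and converts to q-values by a
running minimum; the default acceptance threshold is q ≤ 0.01.
Peptide-level FDR repeats this on the best PSM per partner
(sequence + modifications); protein-level output is a simple grouping
report, not a calibrated protein FDR. Spectra whose precursor charge is
known are searched at that charge only; unknown charges try 2–6 (singly
charged cross-link precursors are rare enough to skip by default).
Reporter×reporter matches are flagged as self-links (probe
self-trapping), not discarded.

## Synthetic data

The generator emulates the study conditions end to end. Proteomes are
i.i.d. residue strings at cysteine frequency 0.0186 (the Arabidopsis
proteome fraction; the other 19 residues uniform), length ~N(300, 60²)
clipped at 60, with every protein guaranteed at least one fully tryptic
cysteine peptide of partner-compatible length (bounded resampling, so a
zero cysteine frequency fails fast). Cross-link spectra place the
precursor at the true m/z at charges drawn from
{2: 5%, 3: 50%, 4: 30%, 5: 10%, 6: 5%} (~95% at ≥3+, matching the charge
profile typical of cross-linked precursors), plant each singly charged
b/y fragment of both chains with probability 0.9, add 50 uniform noise
peaks over m/z 100–1500, and jitter fragment and precursor m/z by a
5 ppm-sd Gaussian so that 20 ppm search windows capture essentially all
true peaks. The ten fingerprint ions are planted at their exact m/z: a
centroided high-resolution peak sits well inside the scanner's 0.01 Da
window, and exact planting keeps the planted-positive truth deterministic
rather than dependent on jitter tails. Intensities are log-normal and
purely cosmetic — no downstream computation reads them.

Negative controls are linear-peptide-only spectra (same coverage and
noise model, no reporter chain) and pure-noise spectra with random
precursors. Every spectrum gets exactly one truth row; all randomness
derives from a mandatory seed via numpy's seeded generator, and
fixed-seed runs produce byte-identical FASTA/MGF output.

What the generator does **not** emulate — chromatography, isotope
envelopes, co-isolation, intensity structure, homologous/shared peptides
beyond chance, real modification prevalence — bounds what passing tests
show: they validate the arithmetic, the matching logic, and FDR behaviour
under the stated noise model, not performance on real instrument data.

## Validation problem sizes

The replicated search validation runs 20 seeded replicates of a
500-protein proteome with 300 planted cross-link and 300 noise spectra
each (~2 minutes on one CPU): every replicate must recover ≥95% of
planted partners at the 1% FDR threshold, and the empirical false
discovery proportion pooled over all replicates must stay ≤2%. Digestion
is checked against a substring-enumeration brute-force oracle on 1,000
random sequences; the hypergeometric enrichment tail is checked against
exhaustive subset enumeration at N = 12.

## Known limitations

- Exact-string peptide-to-protein matching treats Leu and Ile as
  distinct letters (database convention) even though they are isobaric
  for mass purposes; mass-level ambiguity is surfaced via the PSM
  ambiguity flag instead.
- The enrichment background defaults to all cysteines in the supplied
  background table; restricting to identified proteins is the caller's
  choice of table.
- MGF is the only spectrum format (mzML/mzXML/RAW are out of scope), and
  no centroiding or deisotoping is performed.
- Protein-level FDR is a grouping report only.
- Representative-peptide tie-breaking (fewest proteins, then shorter
  sequence, then lexicographic) is a package convention beyond the
  fewest-proteins rule.
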