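# Methods

This note documents the models behind `histoscope`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and the
numerical conventions. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Modification model

A modification is a signed elemental composition plus a target set (residue
letters and/or the `N-term`/`C-term` markers), an origin class
(`biological`, `chemical-label`, `artifact`) and a set of residues at which
it blocks enzymatic cleavage. The monoisotopic delta is always derived from
the composition with the standard atomic-mass table (via `pyteomics.mass`);
no delta is stored as a decimal. This makes mass arithmetic associative and
exact: the delta of a multiset of modifications equals the delta of the
summed composition, which is why conflicts such as
propionyl + methyl vs butyryl (both C4H6O net) are detected as *exact*
isobars — their reported mass difference is exactly zero by construction,
not a small float.

Choices worth flagging:

- **Citrullination** is modelled as the net deamidation chemistry on
  arginine (−NH, +O; +0.984016 Da), the standard community definition.
- **Overpropionylation** of S/T/Y is the same C3H4O group as the lysine
  label but registered as a separate `artifact` entry; the resulting exact
  Propionyl/Overpropionyl conflict is intentional — it *is* the chemical
  noise the artifact class exists to mark.
- **Blocking defaults**: every biological K-mark and the propionyl label
  block cleavage at K; the R-marks (methyl states, citrullination) block at
  R. Whether the GG (ubiquitin remnant) should block exactly like the acyl
  marks is not settled; the default is "blocks", and the registry's YAML
  round-trip lets users override any blocking set without code changes.

## Digestion model

A protease rule is (cleavage residues, proline exclusion, respects-blocking
flag). Cut points are computed once per protein from the sequence and the
fixed site-modification map; peptides are all spans between cut points with
at most `max_missed` internal points, with coordinates 1-based inclusive and
`sequence == protein[start..end]` enforced everywhere downstream.

- **trypsin** cleaves after K and R, not before proline (the common search
  engine convention; configurable — the choice matters only at K/R-P
  junctions), and respects blocking.
- **argc** cleaves after R and respects R-mark blocking.
- **grx** (RgpB) cleaves after R and *ignores* blocking — this single flag
  is what reproduces the qualitative finding that missed-cleavage and
  citrulline/methyl-arginine enrichment differs between the two
  arginine-specific enzymes. Whether RgpB truly cleaves citrullinated (as
  opposed to methylated) arginine is unproven; the default treats all
  R-marks as cleavable by GRX and is configurable.

ArgC's empirical lack of specificity is deliberately *not* modelled as a
stochastic mis-cleavage process inside the digest engine; aspecific
products enter only through `semi_specific_expand` (search-space side) and
through the synthetic generator's degradation pool (data side).

Derivatization (`propionylation`) marks every K that is unmodified or
carries only a mono-methyl with a propionyl group and flags peptide
N-termini for the N-terminal label. A mono-methylated K thus carries
methyl + propionyl, whose summed delta equals butyryl exactly — the
indistinguishability case above. The initiator methionine is taken as given
in the FASTA; no automatic M-clipping is performed.

## Spectral libraries

Peptidoform enumeration produces, per peptide: the unmodified form, one
form per subset of curated sites inside the peptide, every combination of
at most `max_variable` variable modifications over compatible sites, and
the fixed labels applied last (a site already carrying a mark is not
labelled). Enumeration is capped (default 10 000 forms per peptide) and a
truncation is always reported with the skipped count, never silent.

Fragmentation generates all singly charged b_i/y_i ions (1 ≤ i ≤ n−1), with
each placement's delta assigned to the fragment containing its residue
(N-terminal labels ride with the b series). Complementarity
b_i + y_(n−i) = M + 2·m_proton is a tested invariant. Intensities are a
pluggable strategy with a uniform default: the toolkit uses libraries for
coverage and search-space assessment, where peak *positions* carry the
information; a learned intensity model would change none of the downstream
comparisons. Retention-time prediction is likewise out of scope. Default
precursor charges are {2, 3}, fragment charge 1, precursor window
m/z 50–5000 (a typical acquisition range), minimum peptide length 4 — the
last is a declared cutoff (very short peptides neither retain on the column
nor score), configurable.

## Coverage matrices

The backbone row counts PSMs spanning each residue; each modification row
counts PSMs placing that modification at that position — spectral counts,
i.e. one increment per PSM, not per distinct peptidoform. Ambiguous site
localization is *not* resolved: placements are counted as reported, which
is a real limitation of search output that the matrix inherits by design.
Rendering scales colours relative to each protein's own maximum (the grid
is normalized to fractions, so a global rescaling of counts produces a
byte-identical image); absolute scaling is available for cross-workflow
panels.

## Workflow metrics

- `%CV` uses the sample (n−1) standard deviation. Undefined cases (single
  value, non-positive mean) are reported as missing rather than raising.
- The decomposition computes per-feature total %CV over independently
  prepared replicates and instrumental %CV over repeated QC-pool
  injections, on **raw** abundances — normalizing first would shrink
  exactly the variance being measured, and the equal starting amounts make
  raw values comparable. Features missing any run value are excluded
  pairwise and counted, never imputed.
- Normalization factors are median log2-ratios to a reference run
  (default: the run closest to the median profile) over non-zero pairs of
  the chosen feature subset (`all`, `annotated`, `specific`). This is a
  standard robust estimator, declared in the output metadata; commercial
  packages use their own proprietary variants. After applying factors the
  subset median log-ratio to the reference is 0 (tested to 1e-9).
- Charge-state deconvolution transfers annotations from z ≥ 2 ions to
  co-eluting unannotated z = 1 ions when neutral masses agree within a ppm
  tolerance and retention times within a window (defaults 10 ppm / 0.5 min,
  both plain config values). Assignment is greedy one-to-one by smallest
  mass error with |ΔRT| as tie-break; existing annotations are never
  overwritten.
- The PCA view log10(x+1)-transforms and mean-centres run profiles before
  decomposition — the transform is a documented choice, not a claim about
  any particular upstream software.

## Synthetic experiments

The generator emulates a four-workflow comparison (Tryp, PropTryp, ArgC,
GRX; five replicates each; QC pools interspersed) at laptop scale, with every
random draw tied to one integer seed and byte-identical outputs on rerun.

Structure per workflow: digest under the enzyme/derivatization bundle
(default one missed cleavage, minimum length 4), enumerate peptidoforms
with curated sites, then give each ion

- a base abundance, log-normal with log10 mean 6 and sd 0.6 (a typical
  LC–MS dynamic range of ~3–4 orders of magnitude);
- a charge from the workflow's charge model — defaults
  PropTryp {1: 0.50, 2: 0.40, 3: 0.10}, ArgC/GRX {1: 0.20, 2: 0.55,
  3: 0.25}, Tryp {1: 0.30, 2: 0.55, 3: 0.15}; the PropTryp excess of 1+
  ions encodes the charge-blocking effect of the propionyl group. These are
  fixture parameters mirroring the qualitative pattern, not measurements;
- a retention time from a Kyte–Doolittle-style additive hydrophobicity
  index rescaled to a 5–55 min gradient, plus 2 min per propionyl group
  (only the ordering is meaningful);
- replicate abundances = base × LN(prep CV) × LN(instrument CV) with
  unit-mean log-normal factors (defaults 20% preparation, 5% instrument CV,
  5% dropout); QC runs apply instrument noise only, to the mean of the
  mixed workflows' bases.

Mechanisms: singly charged ions are present as features but never
annotated and never reach the identification CSVs (the DDA selection rule);
a fraction (default 0.2) of multiply charged ions also emits a co-eluting
1+ satellite of the same species at half abundance, the substrate for
deconvolution; ArgC diverts half of its specific signal (default loss 0.5)
into a semi-specific degradation pool shared with GRX at a low level
(0.15), which is what makes subset-restricted normalization factors
diverge between the two enzymes.

What the generator does **not** emulate: isotope envelopes, chromatographic
peak shapes, spectral noise, localization ambiguity, FDR, real histone
sequences or real modification frequencies. Passing recovery tests
therefore demonstrates that the *estimators* are correct under the stated
noise model — not that any particular laboratory protocol has these CVs.

## Problem sizes and numerical notes

The default synthetic design produces roughly 400–700 features per workflow
(six proteins of 120–160 residues, K/R density 0.25, eight curated sites
each), enough for stable medians at five replicates; the full suite runs in
seconds. Digestion is validated against a brute-force substring oracle on
hundreds of random sequences up to 60 residues. Mass comparisons use
absolute tolerances: 1e-9 Da for algebraic identities, 5e-4 Da where a
value is checked against independently hand-computed arithmetic on a
5-decimal atomic-mass table. Ties in deconvolution are broken
deterministically (mass error, then |ΔRT|, then table order), and library
output order is canonical (accession, coordinates, placements, charge), so
all primary outputs are reproducible byte-for-byte.

## Known limitations

- The identification-CSV dialect is a defined canonical column set with a
  mapping hook; real search-engine exports vary and may need a column map
  and the positional modification-string decoder.
- Coverage counts inherit whatever localization errors the upstream search
  made.
- The digest model is combinatorial, not kinetic: enzyme concentration,
  time and partial-cleavage probabilities are out of scope.
- Peptide *detectability* (retention, ionization, fragmentation quality) is
  only caricatured in the synthetic generator; in particular, observed
  peptide-length differences between workflows in real data are largely
  LC-retention effects that pure digest arithmetic cannot reproduce.
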