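# Methods

## The measurement model

`xlquant` quantifies crosslinker-modified peptides from a 2-plex isobaric,
amine-reactive reagent pair. Both reagents add the same intact mass, but a
single ¹³C sits either on the reporter arm or on the balance arm, so HCD
fragmentation of a modified peptide releases a
1-imino-2,6-dimethylpiperidin-1-ium reporter cation at one of two m/z values
depending on the sample of origin:

* channel 126: C₈H₁₆N⁺, m/z 126.127726
* channel 127: C₇(¹³C)H₁₆N⁺, m/z 127.131081

Both m/z values are recomputed in `masschem` from hard-coded IUPAC/CODATA
atomic masses (intrinsic-cation convention: subtract one electron mass), as
are the modification deltas of the reagent, the labeled diacid C₁₅H₂₆N₂O₅
carrying one ¹³C:

* crosslink delta = diacid − 2 H₂O = 279.1664 Da (two amide bonds formed)
* monolink delta = crosslink delta + H₂O = 297.1770 Da (one arm hydrolyzed)

The reporter region was chosen clear of unmodified b₁⁺ ions (Leu/Ile 114.09,
Asn 115.05, Asp 116.03 m/z), which Qlinker-modified peptides — unlike
TMT-labeled ones — do produce, because digestion happens after labeling and
peptide N-termini stay free. `masschem.b1_ion_mz` documents that table.

## Reporter extraction and impurity correction

For each identified MS2 spectrum the two reporter intensities are extracted
within ±0.005 Da (≈40 ppm at 126 m/z) of the theoretical m/z. Peaks in the
window are **summed** by default (configurable to max); summing is robust to
split centroids and reduces to the single-peak case otherwise.

Observed intensities I = (I126, I127) mix the true channel signals
A = (A126, A127) through a 2×2 purity matrix M whose column j distributes
channel j's true signal over the observed channels:

    M = [[0.90754, 0.01],
         [0.09246, 0.90724]]

The 126 channel bleeds upward through natural ¹³C abundance; the 127 channel
bleeds downward through incomplete (99%) ¹³C enrichment. Correction solves
M·A = I with a linear solve; the closed forms obtained by Gaussian
elimination, A126 = (I126 − I127·0.01102)/0.906521 and
A127 = (I127 − I126·0.10188)/0.906221, are kept in the code base as an
independent route and the two are tested to agree to 1e−4 relative. The
matrix entries are treated as opaque reagent-lot configuration and are
overridable per lot.

A corrected channel that comes out non-positive is **flagged and excluded**
from ratios, not clamped to zero — clamping would fabricate infinite ratios.

## Ratios and aggregation

Per spectrum, the log2 ratio of the corrected channels is computed in a
declared orientation (127/126 by default; the swap analyses use 126/127).
Ratios are undefined (never ±∞) when a channel is missing. Per site — a
modified residue for monolinks, an unordered residue pair for crosslinks,
canonicalized lexicographically — the site ratio is the unweighted
arithmetic mean of its spectra's log2 ratios, with SD and n reported.
Intensity weighting is deliberately not used; the site mean is the method's
stated summary statistic.

When input stoichiometry differs between channels for one protein (e.g. a
protein present in two of the pooled reactions on one channel and one on the
other), that protein's intralinks can be re-centered: `quant.recenter`
shifts a selected group so its median sits at a chosen target, logs the
shift, and leaves all other sites untouched.

## Spectrum-quality rule

A crosslink spectrum match is accepted when, for **each** peptide, at least
four consecutive b or y ions are observed (±20 ppm, charges 1–2) and the
majority of observed fragment-ion intensity is annotated. "Majority" is
implemented as annotated fraction of total MS2 ion intensity ≥ 0.5
(configurable); intensity rather than ion count was chosen because a single
dominant unexplained peak is stronger evidence of a wrong match than many
tiny ones. Peaks below 132 m/z (reporter/immonium region) are excluded from
the denominator since they are not backbone fragmentation. The crosslinked
partner peptide plus the crosslink delta is treated as a fixed mass on the
linked residue — the linker is not MS-cleavable, so no stub ions exist.

## Study-level analyses

* **Mixing series** (`experiments.evaluate_mixing`): observed log2 ratios
  regressed on expected log2 ratios over a named design (default levels
  10:1, 5:1, 1:1, 1:5, 1:10) by unweighted OLS; slope ≈ 1 indicates accurate
  relative quantification, a constant intercept indicates a global mixing or
  recovery offset.
* **Label swap** (`experiments.swap_join`, `classify_changes`): two
  experiments with channel assignments exchanged are outer-joined on site
  key; the OLS fit uses only sites quantified in both. A site is *changed*
  only if |log2 ratio| ≥ log2(fold) (default fold = 2) in **both**
  experiments with anti-correlated signs — the direction consistency the
  swap design implies. Same-signed above-threshold pairs are flagged
  *inconsistent* (handling artifacts); single-experiment sites are never
  called changed, only flagged when above threshold.
* **Null summary** (`ratio_distribution_summary`): fraction of sites within
  ±0.5 log2 units, per link class, the readout used to confirm that a
  condition without conformational change produces no abnormal ratios.
* **Interference scan** (`quant.interference_scan`): fraction of spectra in
  an arbitrary (non-reporter) run containing any peak within 40 ppm of the
  reporter m/z values, the empirical justification for the chosen reporter
  region.

## Structural interpretation

`structure` maps quantified sites onto coordinates (PDB/mmCIF via gemmi,
first model, highest-occupancy altloc):

* **Cα–Cα restraint**: default maximum 30 Å for a lysine–lysine link,
  by analogy with the well-characterized bound for an NHS-ester crosslinker
  of similar (~10–11 Å) spacer length; configurable because no
  reagent-specific bound is established. Residues absent from a model
  (disordered regions) yield an `unmappable` verdict, not an error.
* **Salt bridges**: Asp OD1/OD2 and Glu OE1/OE2 within 4.0 Å (default) of
  the lysine side-chain nitrogen NZ. An engaged ε-amine is a poor NHS-ester
  nucleophile, so formation/breakage of such a bridge is the mechanistic
  reading of large monolink/crosslink abundance changes at otherwise equally
  exposed lysines. The 4 Å default separates reported engaged bridges
  (2.7–3.8 Å) from broken ones (≥5 Å).

## Synthetic data generator

`synthetic.simulate_run` inverts the measurement model: per spectrum it
draws a base intensity from a log-normal (median ≈ 5×10⁴ counts, σ = 0.6 in
log space — positive and heavy-tailed like real reporter intensities),
applies the site's true log2(127/126) ratio multiplicatively to the 127
channel, optionally perturbs the ratio with per-spectrum Gaussian noise
(`ratio_noise_sd`, log2 units — the generator's model for all
spectrum-to-spectrum ratio scatter: fragmentation efficiency, co-isolation,
counting noise), forward-mixes through the purity matrix, and emits the raw
reporter peaks, the b/y ladder of the modified tryptic peptide (linked K
treated as uncleavable), and uniform noise peaks over 100–1500 m/z that
avoid the reporter windows unless interference is explicitly requested.
Matched identifications (interchange TSV) and ground truth are emitted
alongside; everything is a pure function of the config seed.

Peptides come from a bundled **synthetic toy proteome** — random sequences
at realistic yeast-polymerase subunit lengths under familiar names — so site
keys look realistic with no downloads. `simulate_swap` builds label-swapped
experiment pairs: a site's effect (log2(126/127) in experiment I) flips sign
in experiment II; unchanged sites are 0 plus noise.

What the generator does **not** emulate: chromatographic elution and
co-isolation interference, isotope envelopes beyond the 2×2 purity model,
false identifications/decoys, intensity-dependent noise, and missingness
correlated with abundance. Passing tests therefore demonstrate correctness
of the quantification arithmetic and pipeline plumbing under the stated
statistical model, not robustness to every artifact of real acquisitions.

## Problem sizes and numerical choices

The test suite and examples run, by design, at desk scale: ratio-recovery
checks use 10 sites × 50 spectra at true log2 ratios {−2,−1,0,+1,+2} with
ratio noise SD 0.2 (site means are then verified within 3 standard errors
and the observed-vs-expected OLS slope within [0.95, 1.05]); the null design
uses 300 single-spectrum sites at SD 0.2, where the expected fraction within
±0.5 is 2Φ(2.5)−1 ≈ 0.988; swap classification uses 50 sites × 10 spectra
with 10% planted changes at |log2| = 1.5. Interference scans are exercised
on planted background runs of a few thousand spectra; the percentage
arithmetic is shared with `interference_percent` so larger published counts
can be checked through the same code path.

Window bounds are inclusive, with a few-ulp guard so exact-boundary peaks
are included deterministically. Reporter extraction defaults to the Da
tolerance (0.005) rather than its ppm equivalent. Degenerate inputs are
defined rather than accidental: empty runs warn, constant regressions return
slope 0, empty joins flag the fit as undefined, missing structure residues
return `unmappable`.

## Known limitations

* Only the 2-plex design is implemented end to end; the correction
  architecture admits an n×n matrix but nothing larger is specified or
  tested.
* pLink2 CSV support covers the common filtered-spectra layout (Title,
  Peptide, Proteins); other native engine formats go through the interchange
  TSV.
* The mzML/mzXML readers cover centroided peak data with the metadata the
  pipeline consumes; they are not general-purpose PSI-format parsers.
* No significance testing for ratio changes — fold-change rules with swap
  consistency only, as specified for the workflow.
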