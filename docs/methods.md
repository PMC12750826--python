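# Methods

## The prediction problem

Electrospray ionization efficiency spans several orders of magnitude
across analytes and depends on compound structure and eluent chemistry.
`ioneff` models logIE (log10, relative scale) two ways: from structure
(molecular fingerprint + eluent aqueous-phase pH) and, for unknowns,
from MS2 fragmentation alone (cumulative neutral losses + precursor
monoisotopic mass + pH). Both are regression problems solved with
leaf-wise-grown gradient-boosted tree ensembles. The pH of the aqueous
phase is the only experimental covariate either model sees; deliberately
excluding instrument and mobile-phase descriptors keeps the models
applicable to archived data where such metadata is missing.

## IE aggregation

Replicate logIE measurements of one compound scatter strongly across
instruments and sources, so measurements are grouped by (InChIKey,
rounded pH) and averaged — both pH (unrounded values) and logIE, with
the group size retained. Rounding is half-away-from-zero (2.5 → 3), a
documented choice where plain "nearest whole number" is ambiguous.
Compound identity is the full 27-character InChIKey. Measurements with a
missing identifier, pH or logIE are rejected with a per-record report,
never dropped silently; no record is excluded on experimental metadata.
Aggregation conserves the measurement count (Σ n_source) and the
n_source-weighted mean logIE, and is idempotent — all three are tested.

## Fingerprints

The selected structure representation is an 881-bit PubChem-style
substructure fingerprint implemented here from explicit rules: element
counts (115 bits), ring counts by size, composition and saturation plus
aromatic-ring counts (148 bits), bonded element pairs (64 bits), and a
curated SMARTS section for common organic functional groups, short
bonded-atom paths and heterocycles. Unimplemented indices in the SMARTS
sections are fixed at 0, and every implemented bit carries a
human-readable description used when reporting feature importance.
Ring perception uses RDKit's SSSR; bit-level parity with PubChem's own
(ESSSR-based) implementation is not claimed, self-consistency is, and
the bit semantics are pinned by hand-derived expectations on ~30 small
molecules. MACCS (166 bits) and Morgan (1024 bits, radius 2) come from
RDKit; `apc2d` is a 2D atom-pair count fingerprint (element-pair ×
topological distance 1–10, 450 counts) optionally concatenated with the
PubChem ring block to restore cyclicity information. Other families of
the original sixteen-variant comparison are registered as unimplemented
placeholders behind the same interface. Hash collisions in Morgan bits
are accepted as-is.

## Leverage-stratified splitting

Leverage h_i = x_i(XᵀX)⁻¹x_iᵀ measures how structurally unusual a
compound is relative to the fingerprint matrix X. Binary fingerprints
make XᵀX routinely singular, so the diagonal is computed via SVD
(equivalent to a Moore–Penrose pseudo-inverse), giving 0 ≤ h_i ≤ 1 and
Σh = rank(X) exactly; values are clipped to [0,1] after a 1e-9 sanity
check. "Ten equal parts" of the leverage distribution is read as ten
equal-count quantile strata — equal-width bins could leave strata too
small to honour an 80/20 draw. Within each stratum, round-half-up
(size × ratio) compounds go to test via a seeded uniform draw, with a
deterministic correction pass so the overall test count equals
round(N × ratio); 1000 compounds at ratio 0.2 always yield exactly 200.
Splitting operates on *unique compounds*, never on entries or spectra,
which is what prevents leakage when one compound contributes many rows.
Leverage is used only for splitting, not for applicability-domain
warnings at prediction time.

## Spectra and CNLs

MSP and MGF libraries are read and written through matchms. The quality
filter retains positive-mode [M+H]+ spectra (dialect adduct strings are
normalized first) with ≥ 1 fragment, resolution ≥ 5000 and a present
InChIKey; spectra with *missing* resolution are rejected — the
conservative reading — and tallied under their own counter so the choice
is auditable. Each spectrum is tallied under the first criterion it
fails, in a fixed order. CNLs are precursor m/z minus fragment m/z;
fragments heavier than the precursor beyond the 20 mDa tolerance are
artifacts, dropped and counted.

## CNL vocabulary, encoding, consensus

Losses are counted in 0.01 Th bins (matching the two-decimal resolution
CNL features are reported at), each spectrum contributing at most once
per bin; the 400 most frequent bins form the vocabulary (ties break
toward smaller mass — an explicit choice). Encoding then uses an
interval test, not bin equality: bit j is set when any loss lies within
±20 mDa of bin j, so one loss can set two bins closer than 40 mDa.
Consensus construction groups the losses of all spectra of one compound
by a single-linkage ascending sweep with a 20 mDa gap threshold — the
same tolerance as encoding, and deterministic — and keeps groups present
in ≥ S_min of the spectra (inclusive, so S_min = 0.25 keeps a fragment
seen in 1 of 4 spectra; S_min = 0 keeps everything). The "replace"
algorithm substitutes one consensus row per compound (one row, not n
copies, to avoid duplicating training weight); "filter" intersects each
spectrum with the consensus, preserving per-spectrum identity. Spectra
left with fewer than CNL_min losses are discarded before and after the
consensus stage. Consensus filtering applies to training compounds only;
the workflow's preprocessing passes test-side CNL sets through as the
same objects, and a contract test asserts it. The model matrix prefixes
the bits with precursor mass / 1000 and pH / 14 — numerically cosmetic
for trees, kept for feature-magnitude uniformity.

## Models

The backend is LightGBM, whose native leaf-wise (loss-guided) tree
growth matches the required grow policy; `num_leaves` is bounded by
2^depth (capped at 255) so the depth grid stays meaningful, and fits are
single-threaded and deterministic so a fixed seed reproduces runs bit
for bit. Randomized search samples hyperparameter configurations
uniformly — number of trees 100–1400 (step 100, FP track) or
{600, 800, 1000} (CNL track), minimum samples per leaf {4,7,10,13,25},
learning rate {0.05–0.15} (FP) / {0.01–0.1} (CNL), depth 6–10, bagging
and feature-sampling fractions, and random state 1–5; the CNL track
searches CNL_min (0–5), S_min {0, 0.1, 0.2, 0.25} and the consensus
algorithm jointly with the model, re-running the consensus stage inside
the loop. Configurations are scored by 5-fold cross-validated RMSE on
the training split only (the selection criterion is this package's
choice). Shipped defaults are the mid-range of each domain — explicitly
*not* tuned optima. Q² centres on the evaluated set's own mean (the
alternative — centring the test set on the training mean — is equally
computable from the residuals). Feature importance uses the backend's
gain measure normalized to percentages (descending, summing to 100);
when a model contains no splits the importance is reported as zeros with
the method marked `none`. The FP-vs-CNL comparison reports per-row
residuals (CNL − FP), their RMSE, the fraction within an absolute bound,
and error factors 10^|residual| with inclusive factor-3 and factor-10
fractions.

## Formula annotation

Important CNL features are plain masses; the annotator enumerates all
CHNOSP formulas within per-element bounds (defaults C≤20 H≤40 N≤5 O≤10
S≤3 P≤2, sized for neutral-loss-scale masses) and keeps those matching
the query within ±20 mDa as a neutral/[M]+ species or, adding a proton
(1.007276 Da — the proton, not the hydrogen atom), as [M+H]+. No
ring-double-bond-equivalent filter is applied: plausibility ranking is
expert judgment, out of scope here, and signed mass deltas are reported
so users can do it. The isotope mass table is pinned to IUPAC values at
≥ 5 decimals.

## Synthetic data: what it emulates and what it does not

The generator assembles compounds combinatorially (alkyl chain length
1–15; 0–2 amines; 0–2 carboxylic acids; 0–2 hydroxyls; optional benzene
ring and methyl branch; ~1400 distinct valid structures), and plants:

* **logIE** = −1.0 + 0.5·n_N + 2.0·(M/1000) + 0.3·pH + N(0, σ), with
  σ = 0.1 logIE units by default — measurement-scale noise. Over the
  default pH range (2–10) the pH term carries the largest variance, so
  pH is the planted dominant feature; the nitrogen term is second. Each
  compound is measured at two whole-number pH levels, two replicates
  each, at ±0.3 jittered pH, exercising the rounding aggregation.
* **MS2 spectra**: precursor = monoisotopic mass + proton; fragments =
  precursor − planted losses with 3 mDa Gaussian jitter plus
  Poisson-rate noise fragments at random m/z. Losses are deterministic
  functions of structure (water always; ammonia ≥1 amine; a 34.05 Da
  marker for diamines; CO2 and formic acid for acids; ethylene for
  chains ≥ 3; acetylene for aromatics; formaldehyde for hydroxyls), so
  the CNL bit vector genuinely carries the structural information the
  planted logIE depends on.
* **Filter violations** (negative mode, low resolution, missing
  InChIKey, wrong adduct) injected as copies of clean spectra at known
  rates, giving filter tallies exact expectations.

Passing recovery tests therefore show the *pipelines* are correct —
aggregation, splitting, encoding, consensus, training and evaluation
compose without leakage and recover a planted signal through the CNL
representation. They do not show that real logIE is predictable to
Q² ≈ 0.98: real fragmentation is not a fixed loss table, real logIE is
not linear in three covariates, and real libraries are far more diverse.
Fragment *intensities* are uninformative in the generator, matching
their absence from the CNL representation.

## Problem sizes and numerical choices

Default study sizes — 125 compounds × 2 pH levels × 2 spectra (~500 CNL
rows) for recovery runs, 1000 compounds for split-ratio checks, 50
random matrices for the leverage oracle — are chosen so the whole
synthetic study, including both model tracks, runs in well under a
minute on one CPU while leaving no stage trivially small. Tolerances:
20 mDa everywhere a mass is matched (encoding, consensus grouping,
annotation, heavy-fragment cutoff); 0.01 Th vocabulary bins; leverage
values checked to 1e-9 before clipping; the leverage oracle agrees to
1e-8. Vocabulary ties break toward smaller mass; search ties keep the
earliest sampled configuration; the split correction pass adjusts the
strata with the most extreme rounding remainders, lowest stratum index
first.

## Known limitations

* Positive mode ([M+H]+) only, mirroring the scope of the available IE
  data; other adducts are filtered out, not modelled.
* The PubChem-style fingerprint implements a documented subset of the
  SMARTS sections; unimplemented bits are constant 0 (harmless to tree
  models, but those substructures are invisible to the FP model).
* Leverage on near-complete binary matrices can saturate at h = 1 for
  exotic compounds; they all land in the top stratum, which is the
  intended behaviour of the stratification.
* `predict` requires an explicit pH; none is assumed.
* Spectral records with missing resolution metadata are discarded, which
  on sparse libraries can be a large fraction — the tally makes it
  visible.
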