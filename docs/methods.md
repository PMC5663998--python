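# Methods note

This note records the models, parameters and numerical choices behind
`pgcglycomics`. It makes no empirical claims beyond what the test suite
and `scripts/acceptance.py` compute.

## Mass model

Glycans are treated as compositions over five building blocks with
standard monoisotopic residue (dehydrated) masses:

| residue | mass (Da) |
| --- | --- |
| Hex (Gal/Man/Glc) | 162.05282 |
| HexNAc (GlcNAc/GalNAc) | 203.07937 |
| dHex (Fuc) | 146.05791 |
| Neu5Ac | 291.09542 |
| sulfate (+SO3) | 79.95682 |

Neutral mass = Σ residues + H2O (18.01056) + 2.01565 for reduced
(alditol) glycans. Negative-mode m/z = (M − z·1.00728)/z for z ∈ {1,2,3}.
N-glycan compositions written as "antenna + core" fold in the
(Man)3(GlcNAc)2 core; N-compositions must satisfy Hex ≥ 3, HexNAc ≥ 2.
Isomeric hexoses/HexNAcs are distinguished only at the topology level
(condensed IUPAC strings such as `Gal(b1-4)GlcNAc(b1-2)Man(a1-3)...`),
where identities map back to the same residue masses.

## Composition search

GlycoMod-style bounded enumeration: nested loops over Hex 0–12,
HexNAc 0–8, dHex 0–4, Neu5Ac 0–4, sulfate 0–2 with early mass pruning,
class constraints, and a 6000 Da cap for unbounded queries. The observed
m/z is converted to the neutral-mass scale before applying the tolerance
(default 0.5 Da). Candidates sort by |Δ|, then size. The test suite
checks exact equivalence against an independent brute-force oracle on 50
random queries.

## Fragment prediction and motif diagnosis

For a topology, singly charged B/C/Y/Z ions are generated for every
glycosidic edge. The D ion is the 6-arm antenna subtree + bisecting
GlcNAc (when present) + the branching β-mannose, minus a proton; D−221
(loss of HexNAc + H2O = 221.08993) is emitted only when a bisecting
GlcNAc exists. F ions (1,3A cross-ring) add 59.0133 to each complete
antenna. Peak matching is nearest-neighbour within a 0.3 Da default
tolerance, with shared-peak ambiguity flags.

Motif calls per candidate structure:

- *bisecting*: all predicted D and D−221 ions matched;
- *LacdiNAc*: the antenna B (405.151) **or** F (465.172) ion matched
  (either suffices, both raise coverage);
- *sialyl-LacdiNAc* (696.247) vs *sialyl-LacNAc* (655.220): antenna B
  ions.

Candidates are gated on precursor m/z agreement (0.5 Da) and ranked by
diagnostic-ion coverage, then overall fragment coverage, then input
order. On 200 synthetic spectra (jitter σ 0.05, 20 % decoys) the true
structure ranks first in ≥ 90 % of trials.

## EIC integration and isomer assignment

The trace is smoothed with a centered moving average (window 5 points);
apexes are local maxima above 1 % of the trace maximum (suppressing
baseline-noise ripples, which otherwise chain peak-group merging);
adjacent apexes split only where the connecting valley drops below 10 %
of the lower apex. Areas are trapezoidal over the raw signal. Isomer
labels are assigned purely by elution order against an expected list with
α2,6-containing forms first (the PGC retention rule); surplus peaks pool
as unassigned, missing peaks flag low confidence. The α2,6 percentage is
abundance-weighted over a glycan subset.

## Classification rules

Five N-glycan types with precedence:

1. *paucimannose*: HexNAc 2, Neu5Ac 0, and Hex ≤ 3 or (Hex 4 with dHex);
2. *high-mannose*: HexNAc 2, Hex 4–9, dHex 0 — Man4 is classified
   high-mannose (composition rule chosen over a conflicting table entry;
   topology evidence can override);
3. *hybrid*: HexNAc 3; with a topology, an unsubstituted Man arm decides,
   otherwise Hex ≥ 4;
4. *complex*, split into *neutral* vs *sialylated* by Neu5Ac.

Antennae are complete LacNAc/LacdiNAc disaccharides on core α-Man arms;
bisecting GlcNAc and bare GlcNAc stubs do not count.

## Statistics

- Two groups: Wilcoxon rank-sum (exact for n ≤ 25 without ties, else
  asymptotic); three groups: Kruskal–Wallis. BH adjustment via
  statsmodels; constant features are flagged with p = 1.
- `GlmnetSelector`: L1 `LogisticRegressionCV` (saga, 25 penalties over
  logspace(−2.5, 2.5), neg-log-loss, stratified shuffled folds); support
  is any |coef| > 1e−10.
- `OOBPermutationForestSelector`: hand-rolled bagging of CART trees
  (sklearn `DecisionTreeClassifier`, gini, sqrt features) because
  sklearn's forest does not expose OOB permutation importance; importance
  is the mean OOB-accuracy drop on permuting each feature; top-k (default
  4) defines support. Default 500 trees; a warning fires below 50.
- ROC via sklearn `roc_curve` + trapezoidal AUC (equals U/(n1·n2), tested
  on 100 random instances); operating point by Youden's J with ties
  resolved toward higher specificity. Panel scores are fitted
  probabilities of an unpenalized logistic model on standardized
  features.
- LDA: Wilks' Λ = det(W)/det(T) (slogdet; 1e−8 ridge with a `ridged_`
  flag when singular), Rao's F approximation for the p-value,
  cross-checked against statsmodels MANOVA in the tests.
- qPCR: 2^−ΔCq against the mean of the reference genes, rescaled so the
  minimum sample is 1.

## Synthetic cohort generator

Design: diagnosis groups OC/PC of 14/14, or sites ovary/omentum/
peritoneum of 14/11/3; a 37-mass N-glycan panel whose per-group means sum
to 100 % and reproduce the published aggregate features (sialylated total
in the 66.3–68.5 % band, bisecting ≈ 6.9 %, tri/tetra-antennary in the
4.4–5.7 % band).

The LacdiNAc block total L is Bernoulli(presence) × Gamma, with the
conditional Gamma moment-matched so the *unconditional* mean and SD equal
the preset values exactly (OC: 2.775 ± 2.005 %, presence 0.93; PC:
0.1247 ± 1.312 %, presence 0.22). The anchor disialylated species is
always present when the block is; other members appear with a
member-presence probability and split L Dirichlet-wise. The background
splits 100 − L by a Dirichlet draw (concentration = 2 × mean %), so
expected shares equal the preset means and rows are exactly compositional.
A Gamma was chosen over the more conventional lognormal because for the
PC group (SD ≫ mean) no lognormal matches both moments with a usable
shape, while the Bernoulli×Gamma mixture matches them exactly in all
groups.

Limitations: glycans are independent apart from compositional closure (no
biological covariance structure); presence probabilities for non-anchor
members and site-preset intermediates are interpolations, not published
values; EIC noise is white and spectra use uniform decoys.

EICs are sums of Gaussians (width 0.25 min) with optional clipped white
noise; spectra are the theoretical fragment list with N(0, σ²) m/z jitter
and a fraction of uniform decoy peaks. All generators are seeded with
`numpy.random.default_rng`.

## Problem sizes and budgets

The full test suite runs in well under 15 min on one CPU (≈ 3–4 min
here); the acceptance script (`--seed`, `--out`) recomputes the ten
theoretical m/z anchors closed-form and the generator-fidelity grand mean
over 200 cohorts (2800 OC samples) in a few seconds. The ±2 SE
Monte-Carlo tolerance on the grand mean admits ≈ 5 % seed-level
exceedances by construction; the generator itself is unbiased (the block
mean is exact by moment matching, and profile closure preserves it).
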