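# Methods

## Model and assumptions

tagnovo treats de novo sequencing as path search in a typed spectrum
graph. The operative assumptions are:

* Fragmentation is dominated by y- and b-type ions; every deisotoped ion
  is represented once, with no artifact vertices for missing complements.
  The four edge types (arrow, vertical bar, forward slash, backslash)
  cover all pairwise mass relationships two y/b ions adjacent to a single
  residue can have, given the neutral parent mass P.
* On high-resolution spectra, fragment mass error — not intensity — is the
  discriminative signal. Relative mass errors of true edges concentrate
  near zero (correlated calibration error cancels in differences and
  complementary sums); false edges from unrelated ion pairs are roughly
  uniform over the tolerance window. The half-normal weight
  ω = 2(1 − Φ(ε/(Δ/2))) encodes exactly this contrast and nothing else.
* Tags are directionless: M_p R₁…R_m M_q ≡ M_q R_m…R₁ M_p. All reporting
  canonicalizes to the lexicographically smaller direction.

The zero-mass anchor ion (m₀ = 0, 100%) participates in the graph like any
ion, which is what lets a tag reach the N-terminal residue via an arrow to
b₁ (and the complementary slash to y_{n−1}); without an ion at mass P or
P − H₂O the final C-terminal residue is structurally out of reach, so a
complete ladder yields a top tag of length n − 1, never n.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| Δ (`delta`) | 0.01 | Da | relative-mass-error tolerance for all four edge conditions; also Φ's scale via σ = Δ/2 |
| `min_tag_length` | 3 | residues | tags below this are discarded |
| `score_cutoff` | 4.0 | — | minimum top-tag score for a spectrum to count as sequenced |
| `max_paths` | 10⁶ | paths | per-component enumeration budget; an exceeding component flags the spectrum unsequenced rather than stalling the run |
| mass-filter window | 0.05 | Th | isotopic-peak match window in MS1 scans |
| mass-filter threshold | 0.02 | Da | cut on median-normalized parent-mass error |

Residue masses are computed from elemental compositions (pyteomics), not
from a literal 5-decimal table: this keeps compositional identities exact
in floating point (M(G)+M(A) = M(Q), 2·M(G) = M(N)), which matters because
those identities are precisely the Q↔GA and N↔GG ambiguities the error
analysis quantifies. Per-residue overrides (`mass.C = …` in a config file)
accommodate fixed modifications such as carbamidomethyl-cysteine.

## Design choices where the design was open

* **Sequence-vertex construction.** A vertex for residue Ω is two site
  groups of ≤ 2 ions each: vertical-bar partners within a site, Ω-labeled
  edges across sites. Rather than growing candidates greedily, all
  consistent extensions of every Ω-labeled seed edge are enumerated and
  only set-maximal candidates kept — maximality is then a guarantee the
  tests assert, not a heuristic outcome, and no tie-breaking rule is
  needed.
* **Traversability.** Two vertices are traversable when some pairing of
  one site from each merges into a single cleavage site (union ≤ 2 ions;
  if 2, they must be vertical-bar partners) while the two remaining sites
  stay disjoint from each other and from the merged site. Everything else
  ion-sharing is a short circuit.
* **Orientation chaining.** A path must enter each vertex through one site
  and leave through the other, so it reads a strictly alternating site
  sequence; paths that are pairwise-traversable but cannot be chained are
  invalid. Abstract graphs without site information (used in oracle tests)
  are unconstrained.
* **Residual-mass estimator.** Each ion at each site along the path can be
  read directly (prefix mass m) or through its complement (P − m). Both
  readings of every ion are projected back to the first cleavage site by
  subtracting the accumulated residue mass; the readings consistent with
  one direction of the tag form the largest cluster, and M_p is their
  mean. This uses every ion on the path instead of a single boundary ion
  and is exact on error-free data.
* **Consensus ties.** When several equally long common substrings exist,
  the span whose supporting edges in the top tag carry the larger summed
  weight wins, then lexicographic order — determinism without arbitrary
  positional preferences.
* **Consensus requires two parents.** A spectrum with exactly one tag
  above the cutoff yields no consensus tag; passing the lone tag through
  would forfeit the correctness guarantee that motivates consensus.
* **Edge-weight evaluation** uses the closed form erfc(ε/(Δ/2)/√2),
  identical to the normal-CDF formulation.
* **Two-residue-per-protein rule** counts distinct peptide sequences, not
  spectra, per protein.
* **FDR** is 2D/(T+D), the concatenated target-decoy convention.
* **"Six surrounding full scans"** is read symmetrically: three before
  and three after the MS/MS scan, fewer at run boundaries; the nearest
  peak in each ±0.05 Th window is matched, and errors are measured on the
  neutral-mass scale.

## Synthetic data: what it emulates, and what it does not

The generator produces tryptic-like peptides (uniform residues, K/R
C-terminus, lengths 7–20), y/b ladders with per-ion inclusion probability
0.7, Gaussian fragment mass error with σ = 0.0025 Da (= Δ/4, so nearly
all relative errors fall inside ±0.01 Da, matching the error distribution
high-resolution analyzers produce), 8 uniform-m/z noise peaks per spectrum
drawn from the lower quartile of signal intensities, MS1 isotopic
envelopes from exact elemental compositions, and an optional systematic
calibration offset. Every fragment is book-kept to its (peptide, ion
type, index) identity.

It does **not** model collision-energy-dependent intensity patterns,
a-ions or neutral losses, co-isolated precursors, or residue-composition
bias in real proteomes. Passing tests on this generator therefore
demonstrate the graph/search/scoring machinery and its calibration
behavior, not real-spectrum performance figures; the accuracy values the
benchmark prints on synthetic runs (≈ 80% top-tag at the defaults) are
properties of the noise model.

Default problem sizes in the test suite — 500 peptides for the zero-error
recovery property, 1,000 noisy spectra for the consensus guarantee, 200
random graphs for the path-search oracle — were chosen as the smallest
sets that exercise the properties convincingly while keeping the full
suite around a minute on one core.

## Numerical notes

* Ion lists are strictly ascending; deisotoped masses within 0.005 Da are
  merged keeping the higher abundance, because spectrum-graph vertices
  must be distinct.
* Deisotoping is greedy from the most intense unassigned peak, candidate
  charges 1..parent charge, isotope spacing 1.003355/z, partners within
  0.01 Th, envelope shape checked against an averagine prediction within
  a factor of 3. Singly-charged lone peaks are kept unless
  `require_partner` is set. This preprocessing is a pragmatic stand-in
  validated by synthetic-recovery tests, not a contribution of the
  package.
* Path enumeration deduplicates reversals by enumerating ordered vertex
  pairs once and canonicalizing; output order is score-independent and
  stable (length descending, then lexicographic).
* Residual masses within 10⁻⁹ Da of zero are snapped to zero; paths whose
  residual masses are negative beyond the accumulated tolerance are
  dropped as inconsistent.

## Known limitations

* **End-residue ambiguity is inherent.** Exact compositional identities
  among residue multisets (beyond Q = G+A and N = 2·G, e.g.
  J+H+S = R+H₂O+Y) can make a false terminal edge carry zero error even
  on perfect data. Because edge weights are positive, the extended path
  always outscores the true one, so a small fraction of top tags on
  *error-free complete ladders* (≈ 3% of random tryptic peptides) end in
  a wrong terminal residue — the same end-substitution class that
  dominates the error histogram on noisy data. Consensus tags trim most
  of these; treat terminal tag residues as soft evidence when matching
  tags to a database.
* The last residue of a peptide is never read (no ion at P), and +1-rich
  data with sparse ladders sequences poorly — both intrinsic to the
  graph construction.
* Scores are sums of edge weights, comparable across spectra only loosely;
  they are not calibrated probabilities.
* The FT1/FT2 reader implements one fixed dialect (S/Z header lines,
  six- or seven-column peak lines, the seventh column ignored); vendor
  RAW, mzML and MGF conversion is upstream of this package.
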