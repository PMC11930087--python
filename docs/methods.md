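# Methods

This note documents the models behind `porlab`'s two analysis tracks, the
synthetic-data generators that drive them, the numerical choices of each
stage, and what the tests do and do not establish about real data.

## Track A: 77 K fluorescence spectral kinetics

### Spectral model

Spectra live on the instrument grid (600–790 nm, 0.5 nm step, 381 points).
Emission bands are modeled as symmetric Gaussians in wavelength with a
default sigma of 6 nm.  No lineshape is implied by the measurements
themselves; a symmetric Gaussian is the simplest shape consistent with the
narrow peaks seen at 77 K, and the width is configurable per band.  All
analyses operate on spectra normalized to a maximum of exactly 1, matching
the preprocessing applied to the measured spectra.

Emission centers are drawn from a documented lookup keyed by
(pigment, dinucleotide, lipid).  Measured anchor points: ternary
Pchlide:NADPH complexes at ~648 nm (lipid-free and with PG), ~655 nm on
OPT membranes (50/35/15 mol% MGDG/DGDG/PG) and ~652 nm on low-MGDG
membranes; Pchlide:NADP⁺ at ~638 nm (PG) and ~647 nm (OPT); Chlide
complexes at ~687 nm (NADPH) and ~684 nm (NADP⁺) lipid-free.  Three groups
of entries are stand-ins that measurements do not pin down and are
explicitly overridable: free pigment in buffer at 77 K (632 nm Pchlide,
676 nm Chlide), the lipid-free Pchlide:NADP⁺ complex (641 nm, middle of the
observed 8 nm spread), and the lipid-supplemented Chlide complexes
(red-shifted by a few nm from their lipid-free values).

### Titration generator

A dark spectrum at NADPH concentration *c* mixes

* a **free-pigment band** of constant amplitude 1 (the pigment pool in the
  frozen matrix, approximately constant across the titration), and
* a **complex band** of amplitude `vmax_d · f(c)` with the binding isotherm
  `f(c) = c / (K_M^D + c)`.

After 20 s of illumination, only a **convertible pool** of amplitude
`vmax_l` (default 0.3; the enzyme-complexed pigment that can turn over
during illumination) photoconverts; free pigment in the frozen matrix does
not.  The product band receives amplitude
`conv_max · vmax_l · c/(K_M^L + c)` at the product-complex center, and the
same amount is debited proportionally from the substrate bands, so total
band amplitude is conserved exactly (conversion moves amplitude, never
creates it).  `conv_max` defaults to 0.95 so a substrate peak always
survives, as in the measured illuminated spectra.

Two modeling consequences are worth recording:

* **Why the convertible pool is finite.**  If the converted fraction
  `conv_max·c/(K_M^L+c)` were applied to the *total* substrate amplitude,
  the observable F Chlide/F Pchlide would be proportional to φ/(1−φ),
  which is algebraically again a hyperbola in *c* but with half-saturation
  `K_M^L/(1−conv_max)` — twenty times the planted constant at
  conv_max = 0.95.  The planted parameter would then be unrecoverable from
  the spectra by construction.  With a finite convertible pool the
  substrate window peak stays dominated by the unconverted pigment and the
  ratio half-saturates at ≈ K_M^L.  This is also the physically sensible
  model: only pigment complexed with the photoenzyme converts.
* **Residual observable bias.**  Band overlap and the slow growth of the
  complex band leave a small systematic offset between the fitted and the
  planted constants: with the default amplitudes the noiseless fits land at
  −0.4 % (K_M^D) and +4.5 % (K_M^L) for the OPT condition, −9.8 % / +0.2 %
  for the lipid-free condition.  This mirrors the caveat attached to the
  measured constants: they are observables of the spectra, not binding
  constants, and the generator preserves that distinction while keeping
  recovery comfortably inside the 20 % acceptance band.

Defaults for a titration: K_M^D = 50 μM, K_M^L = 5 μM (representative of
the measured mid-range and of the K_M^L < K_M^D ordering), duplicate
replicates per condition, replicate noise = 1 % of the peak intensity
(i.i.d. Gaussian per grid point), and a 13-point 2-fold serial dilution
ladder from 62.5 nM to 200 μM — the measured concentration range sampled
the way a titration bench protocol would.

Product centers couple to substrate centers as 637→681, 648→683,
655→687 nm; other centers use the mean red shift (+34 nm).

### Ratio observables and fitting

Dark ratio: intensity at 648 nm over 635 nm without lipids, 658/635 with
OPT lipids (nearest-grid lookup; exact on the 0.5 nm grid).  Light ratio:
windowed peak maxima, 674–695 nm (product) over 632–655 nm (substrate).
Ties in a windowed argmax break to the lowest wavelength; sub-grid
parabolic refinement exists but is off by default so maxima are reported at
the 0.5 nm collection resolution.  Replicates are normalized individually,
averaged point-wise, and the between-replicate SD is retained.  If a fully
converted spectrum leaves no measurable substrate signal (substrate peak
below 10⁻⁴ of the product peak) the light ratio is flagged `inf` rather
than returned as a meaningless number.

The fit `y = vmax·c/(K_M+c) + a` uses unweighted least squares
(`scipy.optimize.curve_fit`), started from a = min y, vmax = range,
K_M = concentration at half range, with a 7-point log-spaced K_M
multi-start fallback; the best residual sum of squares wins.  Standard
errors come from the Jacobian-based covariance.  A fit is flagged
unconverged when it fails, lands on a non-positive K_M, or leaves K_M
unresolved (SE more than 10× the estimate, as for a constant series) —
never silently returned.  The baseline term is essential: inactive samples
have nonzero ratios, so a two-parameter hyperbola through the origin cannot
represent the data.  A literal product-denominator variant
`vmax·c/(K_M·c)+a` is retained behind a `literal_form` flag for
comparison; it is constant in *c* and cannot describe a saturation curve,
which is why the hyperbolic reading is the default.

### Oligomerization index and lipid optimum

Index: `log10(F658/F631)` for NADPH samples, `log10(F647/F631)` for NADP⁺
(the NADP⁺:OPT complex emits at 647 nm).  The 631 nm denominator follows
the index definition used for the lipid analyses; the K_M ratios use the
635 nm denominator of the titration protocol.  Both wavelengths are
configurable since different figures of merit in this literature use
631 vs 635 nm.

The lipid-titration generator gives the oligomer band a unimodal profile
in log-concentration (Gaussian in log10 c, 0.5-decade width) peaking at the
planted optimum — the membrane-dilution phenomenology: beyond the optimum,
subunit density on the membranes drops and the oligomer band decays — while
the free-pigment band starts to grow once the optimum is passed.  The
monotone variant (isoforms whose index keeps rising in the tested range)
saturates instead.  Classification: a series is `monotone_increasing` when
its maximum sits at the largest tested concentration and no interior point
exceeds the final point by more than 2× the replicate SD (a fixed tolerance
is needed because the measured classification was made by eye);
`flat` series resolve to the lowest concentration by the tie rule.

### Emission-maximum pairing

Samples with NADPH ≥ 1 μM (inclusive threshold — below it the product
maximum is unreliable) contribute one (substrate max, product max) pair;
NADP⁺ samples never enter (no product forms); orphan dark spectra are
skipped with a warning and counted.  Histograms use 1 nm bins aligned to
integer nm edges (maxima live on the 0.5 nm grid).  Conditional product
distributions select pairs within ±2.5 nm of a substrate class center
(637/648/655 nm) and report the subset and its modal product maximum; an
empty subset is an explicit empty result, not an exception.

## Track B: conformational-ensemble flexibility

### Alignment recipe

All metrics share one frame: each Cα model is rigid-body superposed
(Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`) onto the
reference over all residues shared by every member and the reference;
residues missing on either side are dropped from the shared set with a
logged count.  Region RMSDs are then measured in that frame *without*
region-local refitting, so they report genuine displacement rather than
fitting freedom.  A consequence to keep in mind: a localized rigid
displacement is partially absorbed by the global fit (translation plus
rotation leakage), so a planted 5 Å displacement of a 23-residue region in
a 400-residue model reads out as ≈ 4.4 Å.  Degenerate selections (< 3
atoms or collinear) are rejected.

RMSF is computed about the **ensemble mean** position after reference
alignment (the fluctuation definition); a deviation-from-reference variant
is available as `about="reference"` and is the larger of the two whenever
the ensemble mean departs from the reference.

### Dynamic (leader) clustering

Members are visited in rank order (rank = prediction confidence order; the
top-ranked prediction seeds the centroid list).  For each later member the
Cα RMSD over the four flexible regions **concatenated** is computed against
each current centroid, after globally superposing the member onto that
centroid; if the minimum exceeds the cutoff (3 Å default) the member
becomes a new centroid.  Final assignment is to the nearest centroid, which
guarantees the invariant that every member lies within the cutoff of its
centroid or is one.  Two readings were genuinely open and are resolved as
follows: (i) the threshold is compared against the *minimum* distance over
current centroids (the standard leader-algorithm convention; "exceeds the
threshold to every centroid" is the same condition); (ii) one RMSD over
the concatenated regions matches the single threshold comparison per
prediction, and a per-region variant (max over regions) is available
behind `mode="per_region_max"` — it is never coarser, since a max dominates
the pooled RMSD.  Clustering output depends on member order by design;
permuting non-top members may change the centroid list but never violates
the assignment invariant.

### Ensemble generator

The reference is a protein-like Cα trace: a helical solenoid (radius 9 Å,
1.5 Å rise, ~16 residues/turn) with a small smooth seeded perturbation;
consecutive-Cα spacing stays within [3.6, 4.0] Å and non-consecutive Cα
stay > 3 Å apart (both asserted at construction).  Members are built by
(i) rigidly translating each mobile region by its family's offset
(mimicking loop uncoiling/shifting without a physics engine), (ii) adding
per-axis Gaussian jitter inside the regions, and (iii) applying a random
global rotation and translation per member — downstream metrics must be
blind to the global placement, and an end-to-end invariance test enforces
this.  The default region set is the four documented flexible ranges, so
fixtures exercise the production defaults.  Isotropic jitter of σ per axis
gives an expected RMSF of σ√3, the ground truth used by the recovery tests.

### Alignment variability

Per mapped column (columns where the reference row has a residue, numbered
from a configurable start offset), `v = 100·(1 − n_mode/N)`.  Gaps are
excluded from both counts by default — the metric measures residue
disagreement among sequences that have a residue there — and an
`include_gaps` mode counts the gap as a 21st symbol, since the convention
is not fixed by the metric's definition.  Comparison is case-insensitive;
ambiguity codes count as ordinary symbols; modal ties cannot change *v*.
The bound v ≤ 100·(N−1)/N holds for all N ≥ 1.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations for a
desktop run: titrations use the 13-point ladder with duplicate replicates,
fit-recovery studies use 20 noise realizations per constant, RMSF recovery
uses 200 members × 400 residues, clustering studies 40 members, and the
permutation-invariance study 100 reorderings.  Every random draw flows
from an explicit seed through `numpy` seed sequences: identical seeds give
bit-identical datasets, and the CLI's outputs are byte-identical across
reruns — covered by dedicated determinism tests.

## What the synthetic data does and does not establish

The generators reproduce the *statistical structure* the analyses assume:
composition-dependent Gaussian bands on the instrument grid, isotherm-driven
band growth, conservation under photoconversion, unimodal-vs-monotone lipid
profiles, class-coupled substrate/product maxima, localized flexibility and
discrete conformational families.  Passing tests therefore establish that
the pipeline recovers known structure of this kind at the stated noise
levels.  They do not establish anything about effects the generators omit:
excitonic coupling and resonance energy transfer between fluorophore
populations (fluorescence intensity need not track concentration),
asymmetric or temperature-dependent lineshapes, instrument baseline and
scatter, correlated replicate error, physically realistic conformational
sampling, side-chain or backbone-dihedral behavior, or prediction
confidence (pLDDT).  Conclusions about real spectra and real prediction
ensembles inherit those caveats.

## Known limitations

* K_M estimates from ratio observables carry a small composition-dependent
  bias (quantified above); the package reports them as observables, and
  comparisons should be made within one composition.
* Region RMSD under a global fit underestimates large localized
  displacements (rotation leakage), most visibly for long levers.
* The leader clustering is order-dependent by construction; centroid lists
  from differently ordered ensembles are comparable only through the
  assignment invariant, not element-wise.
* The free-pigment emission centers and the lipid-supplemented Chlide
  centers are stand-in defaults; analyses sensitive to them should pass
  explicit overrides.
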