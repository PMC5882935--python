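# Methods

`oligoms` implements a de novo structural-determination procedure for
underivatised glucose oligosaccharides based on multi-stage tandem mass
spectrometry (MSⁿ) of sodium adducts in a low-energy ion trap. This note
records the model, its assumptions, the parameters that matter, and what the
synthetic data used for testing does and does not establish.

## The dissociation model

A glycan is a rooted tree of glucose residues; the root is the reducing sugar
(free anomeric carbon). All ions are singly charged sodium adducts at
unit resolution, so the mass calculus is nominal:

    [k-mer + Na]⁺ = k·162.0528 + 18.0106 + 22.9892  →  203, 365, 527, 689, 851 …

Under low-energy resonance-excitation CID of sodiated species, three channel
families have low barriers and dominate:

1. **Glycosidic cleavage at any bond**, giving Domon–Costello B/C ions
   (nonreducing side) and Y/Z ions (reducing side). A C-type or Y-type product
   is a genuine smaller sugar; crucially, a C-type product's new reducing
   anomer *is* the anomeric configuration of the cleaved bond (anomer
   inheritance), which is how interior bond anomers become measurable.
2. **Dehydration (−18) at the reducing ring only.** Its rate depends on the
   cis/trans relation of O1/O2: the α (cis) reducing anomer dehydrates much
   faster than β. The −18 : (non-dehydration) ratio therefore reads the
   reducing anomer.
3. **Retro-aldol cross-ring cleavage (−60 ⁰'²A, −90 ⁰'³A, −120 ⁰'⁴A) at the
   reducing ring only**, gated by which acceptor carbons are substituted:

   | reducing linkage(s) | −18 | −60 | −90 | −120 |
   |---|---|---|---|---|
   | 1→2 | minor | | | |
   | 1→3 | ✓ | | ✓ | |
   | 1→4 | ✓ | ✓ | | |
   | 1→6 | ✓ (weak) | ✓ | ✓ | ✓ |
   | (1→6,1→4) | ✓ | ✓ | | |
   | (1→6,1→3) | ✓ | | ✓ | |
   | (1→4,1→3) | ✓ | | | |
   | (1→6,1→2) | | ✓ | | |
   | (1→4,1→2) | | ✓ | | |
   | (1→3,1→2) | | | ✓ | |

   The MS2 loss pattern therefore constrains the reducing-sugar linkage(s).
   The table is not injective: {−18,−60} is shared by linear 1→4 and branched
   (1→6,1→4); {−18,−90} by linear 1→3 and branched (1→6,1→3); {−60} by the
   two 1→2-containing pairs. The first two collisions are settled one CID
   stage deeper: a disaccharide-region ion (m/z 365; 347 on a cross-ring
   route) in the CID of a loss ion proves the chain extends two residues
   above the reducing sugar (linear); absence in every such spectrum proves
   the branch.

Cross-ring ions are modelled as M − (60/90/120) with every residue retained —
the lost neutral is bare ring atoms. This reproduces every decision ion the
procedure uses; the alternative (a substituent departing with the ring
fragment) is chemically conceivable for some linkages but inconsistent with
the loss-pattern table above, and the two readings coincide in m/z for the
linear 1→3 case. A complementary sodiated ring piece (X₀, at loss + 23) is
emitted for branched reducing sugars.

Secondary dissociation within one CID stage is closed (resonance excitation
addresses only the isolated precursor), so consecutive losses arise only
across explicit MSⁿ stages — and loss-state species do not lose again.

## The anomer-resolved disaccharide database

The reducing anomers of a disaccharide coexist in solution but mutarotation is
slow enough that they are separable before measurement, so each reference
fingerprint has a *resolved* reducing anomer. A glucose disaccharide slot is
(bond anomer, linkage position, reducing anomer): 2 × {2,3,4,6} × 2 = 16
slots (1→1 is outside the scheme). Identification reads three ratios from a
fingerprint: the loss-ladder support (→ linkage), the −18 ratio (→ reducing
anomer), and the glycosidic share plus B:C partition (→ bond anomer; the B/C
split is the dehydration-like proton transfer at the glycosidic oxygen, so it
carries the same cis/trans sensitivity).

The shipped database is synthetic: each fingerprint is the zero-noise CID
spectrum of the corresponding disaccharide under the channel model below. A
lab can drop in measured spectra in the same MSP-like or JSON schema
(provenance `measured`). Fingerprints are stored base-peak-normalised; the
pre-normalisation base intensity travels in the `raw_base` metadata so that
mixtures of fingerprints can be recombined in true intensity proportions
(needed for mutarotation-composite matching and weighted subtraction).

**Y-type disaccharides are mutarotation mixtures.** A Y ion keeps the original
reducing sugar, whose anomer is a solution mixture, so its spectrum is the
raw-proportion average of the two reducing-anomer fingerprints.
`match_mutarotated` ranks these 8 composites and decides only the
(bond anomer, position) pair — the software analogue of reporting
"α-(1→4)-α or α-(1→4)-β" and accepting the bond assignment.

## Channel-model parameters

All rates are relative; the spectrum is renormalised to its base peak and
thresholded at 0.01 (the spectrum threshold used throughout). Defaults:

| parameter | value | meaning |
|---|---|---|
| `c_ion`, `y_ion` | 0.8, 0.5 | C/Y rates per bond |
| `b_fraction_alpha/beta` | 0.55 / 0.12 | B:C (and Z:Y) partition per bond anomer |
| `glycosidic_alpha/beta` | 1.0 / 0.45 | overall bond-cleavage factor per anomer |
| `dehydration_cis/trans` | 2.2 / 0.25 | −18 rate per reducing anomer |
| `dehydration_16_scale` | 0.4 | 1→6-only reducing sugar: weak −18 |
| `minor_dehydration_cis/trans` | 0.65 / 0.04 | 1→2 class (different mechanism) |
| `cross_60/90/120` | 0.8 / 0.7 / 0.5 | retro-aldol rates |
| `branch_bias` | 24 | reducing-branch cleavage asymmetry (~96/4) |
| `noise_sigma` | 0 | per-peak lognormal sigma (0.15 in noisy tests) |
| `chemical_noise_peaks/level` | 4 / 0.05 | random low-level peaks when noisy |

No quantitative branching ratios are published for these channels; the
defaults were fixed once, at design time, to satisfy the *ordinal* constraints
the mechanism imposes (cis ≫ trans; α > β glycosidic; 1→6 dehydration weak;
1→2 dehydration smallest) together with two global requirements the method
needs to function: all 16 fingerprints mutually distinguishable with a cosine
margin ≥ 0.05 (achieved: 0.0597), and the branched partial-assignment
phenomenology (below). Two entries deserve flags:

* the 1→2 anomer contrast is the loosest stand-in — cosine matching needs the
  −18 peak to carry weight, so the "minor" channel sits at ≈0.38 relative for
  the cis entry (still far below the base-peak dehydration of 1→3/1→4);
* `branch_bias = 24` rather than a milder 90/10 split: the weighted-subtraction
  residual of the starved branch must fall below the near-zero cutoff (0.05)
  for the branched trisaccharide to yield the documented partial assignment at
  zero noise, and at 90/10 it does not. The bias acts only at the
  reducing-sugar branch point; an interior branch point is symmetric, which
  type-III tetrasaccharide detection requires. Setting `branch_bias = 1.0`
  reproduces the comparable-populations regime in which both branch anomers
  are readable.

## The decision procedure

`decisive_ion_plan(n)` names every potentially decisive precursor path for
n = 2…5 (all four loss-ion routes are listed; routes absent for the actual
linkage return no spectrum and are skipped). The elucidator then:

1. reads the MS2 loss pattern → reducing-linkage candidates;
2. settles linear vs branched (trisaccharides) or walks the four-way
   tetrasaccharide classification (disaccharide-region ions in MS2 ×
   trisaccharide-region ions in loss-ion CID; on the −18 route only the C₃
   ion at 527 is decisive, because a Y₃-type ion also sits at 509 there);
3. matches the nonreducing disaccharide (loss ion → 365 → fingerprint),
   taking the bond assignment and, via anomer inheritance, the next bond's
   anomer toward the reducing end; repeats inward (tetrasaccharide: the
   loss-ion's Y₃ analogue → 365; pentasaccharide: the Y₄ and Y₃ routes, where
   isolation co-selects isobaric C-type species and the already-identified
   nonreducing fingerprint is stripped by weighted subtraction first);
4. crosschecks via the mixed 365 spectrum: subtract the identified
   component's fingerprint with the weight that nulls a reference-unique ion
   (chosen automatically as the minimum mixed:reference bin ratio, which
   reproduces the designated ⁰'³A choice for a 1→6 reference over a 1→4
   partner), then match the residual;
5. audits: every anomer decided by more than one route is checked for
   agreement; disagreement downgrades the assignment to unspecified with a
   caveat. The reducing-end anomer is always reported unspecified.

Branched trisaccharides: the mixed 365 spectrum is matched against
mutarotation composites. With the default bias the residual after subtracting
the dominant branch is near zero, so only the dominant branch's bond anomer is
assigned — the report carries the linkages of both branches, one anomer, and
an explicit caveat. If no composite dominates (comparable populations), the
top candidate is accepted only when the subtraction residual decisively names
the other branch.

Branched tetrasaccharides are classified (types II–IV) with linkage-set
candidates reported, but full bond-by-bond assignment is not attempted — the
printed decision scheme covers classification only, and extrapolating beyond
it is flagged rather than silently done.

## Numerical and robustness choices

* Matching currency: nominal (integer) bins, tolerance ±0.5 u — unit
  resolution data. Similarity: cosine on normalised bins; only rankings and
  margins (default 0.05) drive decisions, never absolute scores.
* Subtraction clips negative residuals to zero, forces the zero ion to zero,
  and renormalises unless the residual is near zero everywhere (max < 0.05 of
  the mixed base peak) — the "no second component" outcome.
* Ion presence = binned intensity ≥ 0.01 after normalisation, with two
  noise-hardening exceptions: topology-deciding ion votes are read at 0.06
  (just above the chemical-noise ceiling; genuine C/B diagnostic fragments are
  never that weak under the channel model), and when the MS2 loss pattern
  matches no table row, observed losses weaker than 0.08 are discarded one at
  a time and the read retried, recording a caveat.
* When no single disaccharide route clears the similarity margin but every
  route ranks the same fingerprint first, that consensus is accepted with a
  caveat — multiple independent routes agreeing is the method's own
  reliability argument.
* Degenerate inputs: empty or all-zero spectra are rejected at normalisation;
  unreachable plan paths yield empty spectra tagged `unreachable`; a missing
  decisive spectrum produces a partial report naming the path that would
  settle each undetermined item.

## What the synthetic data shows — and does not

The simulator emulates: the reducing-side-only loss channels with
linkage-gated ladders, anomer-dependent channel ratios, anomer inheritance in
C-type products, isobaric co-isolation (daughter spectra are rate-weighted
mixtures), per-peak multiplicative lognormal noise and low-level chemical
noise, and deterministic seeding (same seed → identical tree; different seeds
move intensities, never peak positions).

It does **not** emulate: real branching-ratio magnitudes (unpublished — the
ordinal structure is honest, the numbers are stand-ins), collision-energy
dependence, desodiation competition, isotope envelopes, profile-mode peak
shapes, retention-time behaviour, or the alternative 1→2 dissociation
mechanism beyond "dehydration is minor". Passing round-trip tests therefore
demonstrates that the *logic* of the procedure — plans, pattern tables,
matching, subtraction, inheritance, audit — is sound and noise-tolerant under
a mechanism-faithful instrument model; it does not certify performance on
real spectra, which depends on a measured fingerprint database.

Problem sizes used in the test suite and acceptance script: the full
trisaccharide panel (48 structures: 36 linear over linkages {3,4,6} × both
anomer pairs, 12 branched 1→2-free), five noisy replicates each (240
elucidations, ≈1 s total); complementarity over every bond of all ≤5-residue
linear panels (426 bond pairs); the four worked compounds at zero noise.
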