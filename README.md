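# oligoms

De novo structural determination of **underivatised glucose oligosaccharides**
from multi-stage tandem mass spectra (MSⁿ) of sodium adducts.

Identifying a small oligosaccharide completely — linkage positions, anomeric
configurations (α/β), and branch locations — is hard because isomers are
legion and their single-stage mass spectra are nearly identical. For sodiated
species under low-energy ion-trap CID, however, dehydration and cross-ring
cleavage happen essentially only at the **reducing ring**, while glycosidic
bonds cleave anywhere. That asymmetry makes a small set of MSⁿ spectra
structurally decisive, and `oligoms` implements the whole decision procedure
for glycomics researchers and mass-spectrometry software developers:

* **fragment m/z calculus** — sodiated B/C/Y/Z, [M+Na−H₂O]⁺ and retro-aldol
  ⁰'²A/⁰'³A/⁰'⁴A ions on the nominal ladder m/z = 162k + 41 − {0,18,60,90,120};
* **rule engine** — the loss-pattern table that maps observed −18/−60/−90/−120
  losses to reducing-sugar linkage candidates, the linear-vs-branched test,
  the four-way tetrasaccharide classification, and the decisive-ion
  acquisition plans (which MSⁿ spectra to record, and why);
* **anomer-resolved disaccharide database** — 16 fingerprint slots
  (bond anomer × position {2,3,4,6} × reducing anomer), cosine matching,
  mutarotation-composite matching, and weighted spectral subtraction for
  co-isolated isobaric mixtures;
* **instrument emulator** — a channel model producing MSⁿ spectral trees for
  any known structure, so the procedure is testable end to end;
* **elucidator** — orchestrates plans, matches, inheritance of anomers from
  C-type fragments, subtraction crosschecks, and a consistency audit, and
  emits a structure with per-bond provenance.

The scientific background and every modelling choice are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate the spectral tree of panose, build the synthetic fingerprint
database, and run the elucidator:

```bash
oligoms make-db -o db.msp
oligoms simulate "α-Glc-(1→6)-α-Glc-(1→4)-Glc" -o panose.json --seed 1
oligoms elucidate --tree panose.json --db db.msp --n 3 --text
```

prints

```
structure: α-Glc-(1→6)-α-Glc-(1→4)-Glc
topology: linear
  bond 1-2: α(1→4)
    decided by: MS2 loss pattern of the precursor
    decided by: reducing anomer inherited from the 527→509→365 match
    decided by: subtraction crosscheck on 527→365 (weight 0.62)
    crosscheck: 2 independent anomer readings agree
  bond 2-3: α(1→6)
    decided by: DB match of 527→509→365
    crosscheck: no anomer crosscheck
```

and exits 0 (a partial assignment exits 3). Reading the report: the MS2
spectrum of the sodiated trisaccharide (m/z 527) shows −18 (509) and −60
(467), which restricts the reducing-sugar linkage to linear 1→4 or branched
(1→6,1→4); the disaccharide ion 365 in the CID of 509 proves the chain is
linear; the MS4 spectrum 527→509→365 fingerprints the nonreducing
disaccharide as α-Glc-(1→6)-α-Glc — whose reducing anomer, inherited from the
cleaved bond, simultaneously fixes bond 1-2 as α; and subtracting that
fingerprint from the mixed 527→365 spectrum (weight 0.62, chosen to null a
reference-unique ion) leaves a residual matching an α-1→4 disaccharide,
crosschecking the first bond. Residues are numbered from the reducing end.

The same pipeline in Python:

```python
from oligoms import (build_db, synth_fingerprints, parse_structure,
                     simulate_tree, TreeProvider, elucidate)

db = build_db(synth_fingerprints())
tree = simulate_tree(parse_structure("α-Glc-(1→4)-[α-Glc-(1→6)]-Glc"))  # isopanose
report = elucidate(TreeProvider(tree), 3, db)
print(report.structure_string)   # Glc-(1→4)-[α-Glc-(1→6)]-Glc
print(report.is_partial)         # True — the starved branch's anomer is unreadable
```

The branched case deliberately returns a *partial* structure: at the default
branch-cleavage bias almost no disaccharide survives from the 1→4 branch, so
its anomer is reported unspecified with an explicit caveat — exactly the
honest outcome the method produces on such molecules.

The shipped database is synthetic (generated from the channel model); measured
fingerprint spectra can be dropped into the same MSP-like or JSON schema with
provenance `measured`.

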