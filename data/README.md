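# data/

Drop-in location for deposited inputs that are not redistributed with the
package.

* `5LCB.pdb` — the deposited baseplate ensemble (PDB format, 10 models).
  Needed only by the two deposited-coordinate acceptance checks in
  `tests/test_acceptance.py` (shortest Mg–Mg distances; ensemble RMSD for
  residues 6–48 + pigment).  When the file is absent the test helper
  attempts a download from the PDB and otherwise fails with an
  explanatory message; everything else in the test suite runs on
  synthetic fixtures generated at test time.
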