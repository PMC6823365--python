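# Deposited structures

This directory holds plain-text PDB coordinate files for the deposited
entries used by the acceptance targets and the criterion-8 tests:

- `4wis.pdb`
- `6oy3.pdb`
- `6qma.pdb`

They are not distributed with the repository.  On a machine with network
access run `python scripts/fetch_structures.py` from the repository root to
download them from the RCSB.
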