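# Golden crystallographic fixtures (optional)

The golden comparison of deposited TCR-free/TCR-bound peptide/HLA-A3
structures needs the PDB coordinate files `7l1b.pdb`, `8vcl.pdb` and
`9asg.pdb` placed in this directory (download them from the PDB, e.g.
`https://files.rcsb.org/download/7L1B.pdb`). They are not redistributed
with the package; when absent, the corresponding test is skipped.
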