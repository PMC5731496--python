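# Reference structures

Place the real PDB entries here to enable the endpoint-RMSD structural
checks in the test suite:

    1CLL.pdb  1CTR.pdb   (calmodulin, open/closed)
    1AKE.pdb  4AKE.pdb   (adenylate kinase, closed/open)
    1SS8.pdb  1SX4.pdb   (GroEL)

e.g. `wget https://files.rcsb.org/download/1CLL.pdb`.  These files are not
redistributed with the package.
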