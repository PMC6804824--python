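# Deposited sequence panel (user-supplied)

The reproduction checks in `tests/test_acceptance.py` compare this package's
output against numbers published for the NCBI-deposited lily monoTPS panel.
Those sequences and supplementary tables are third-party data and are not
redistributed here. To run the checks, place in this directory:

- `cdnas.fasta` — the 32 deposited monoTPS cDNAs (accessions MH203230,
  MH203231, MH203233, MH203236, MH203239, MH203242, MH203251, MH203254-58,
  MH203261, MH203263, MH203265, MH203268, MH203273-75, MH203279, MH203280,
  MH203282-84, MH203286-88, MH203295, MH203296, MH203298, MH203303,
  MH203304), with the LTPS-1 reference MH203231 as the first record;
- `gdna.fasta` — the genomic locus MH618207;
- `emissions.csv` / `sites.csv` — cultivar x compound emissions and
  cultivar x site incidence matrices (CSV, first column = cultivar id)
  built from the published supplementary tables.
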