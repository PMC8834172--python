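Protein FASTA files from Ensembl go here; run scripts/fetch_ensembl_sequences.py (network required) to download SCN1A.fasta, scn1laa.fasta and scn1lab.fasta.
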