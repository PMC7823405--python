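# Known 3' sRNA-seq adapter library: one entry per line, "name<TAB>sequence".
# Lines starting with '#' are comments. Users are encouraged to enrich this
# file with the adapters of their own sequencing kits.
#
# Entries named "synthetic_*" are synthetic example adapters (not from any
# sequencing kit) illustrating library enrichment and exercising the
# cross-matching machinery.
illumina_truseq_small_rna	TGGAATTCTCGGGTGCCAAGG
illumina_small_rna_v1.5	ATCTCGTATGCCGTCTTCTGCTTG
illumina_truseq_universal	AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
ion_torrent_p1	ATCACCGACTGCCCATAGAGAGG
solid_small_rna	CGCCTTGGCCGTACAGCAG
qiagen_qiaseq_mirna	AACTGTAGGCACCATCAAT
bgi_mgi_small_rna	AAGTCGGAGGCCAAGCGGTCTTAGGAAGACAA
roche_454_a	CTGAGACTGCCAAGGCACACAGGGGATAGG
nextera_transposase	CTGTCTCTTATACACATCT
synthetic_01	CAAAGGGGTACGCGAGCAGCG
synthetic_02	CGTTATTCCGTCTGCAAAAGC
synthetic_03	AAGCAATAGGTAGAGTAGTCC
synthetic_04	GAACGGGGTTATTGGCGGTCT
synthetic_05	ATCGATCAGTAATATCGCGAC
synthetic_06	CTTGCAGATTAAGACAACAGA
synthetic_07	GCTGACCCCGAACGGTGTCCG
synthetic_08	CAACGGGGTTGATGGAGGACA
synthetic_09	AAACCTTTGCCTCTTCACTTG
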