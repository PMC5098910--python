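>synthetic_mouse_gcna SYNTHETIC stand-in transcript emulating the cloned mouse Gcna testis cDNA: acidic disordered ORF with 25 tandem GE(P/M/S)E(S/T)EAK repeats, SIMs and an NLS-like patch; not the biological sequence
GCGGCCGCTTCCTGAACATGGATTCAGGACGTGGATCATCACCTACAGCTCAAAAACTTT
CACCTAATGGATCACAATCAAATGGATCAACACTTCAAGCTCCTAAATCACCTGGACGTA
CACAAAATTCAGGATCAAAACGTCCTGCTGAAACAAAAAAACGTAAACTTTCATCAGGAA
ATCAAGGATCACCTACAACAGGAAATTCAGCTCCTCAATCACAAGGATCAACACTTAAAA
ATTCACCTGTTCGTGGAGGATCAAATACACAAGGAGCTCAATCACCTAATAAAGGATCAA
CACTTGGAAATTCACAAGGAGAACCTGAATCAGAAGCTAAAGGAGAAATGGAAACAGAAG
CTAAAGGAGAATCAGAATCAGAAGCTAAAGGAGAACCTGAAACAGAAGCTAAAGGAGAAA
TGGAATCAGAAGCTAAAGGAGAATCAGAAACAGAAGCTAAAGGAGAACCTGAATCAGAAG
CTAAAGGAGAAATGGAAACAGAAGCTAAAGGAGAATCAGAATCAGAAGCTAAAGGAGAAC
CTGAAACAGAAGCTAAAGGAGAAATGGAATCAGAAGCTAAAGGAGAATCAGAAACAGAAG
CTAAAGGAGAACCTGAATCAGAAGCTAAAGGAGAAATGGAAACAGAAGCTAAAGGAGAAT
CAGAATCAGAAGCTAAAGGAGAACCTGAAACAGAAGCTAAAGGAGAAATGGAATCAGAAG
CTAAAGGAGAATCAGAAACAGAAGCTAAAGGAGAACCTGAATCAGAAGCTAAAGGAGAAA
TGGAAACAGAAGCTAAAGGAGAATCAGAATCAGAAGCTAAAGGAGAACCTGAAACAGAAG
CTAAAGGAGAAATGGAATCAGAAGCTAAAGGAGAATCAGAAACAGAAGCTAAAGGAGAAC
CTGAATCAGAAGCTAAATCAGGATCAACAACATCATCAACAGCTGTTGTTATTGTTGCTA
CAGGATCACCTCAACGTTCAAATTCAGGAACATCATCAACAGGACCTATTGTTCTTACAT
CATCAACATCACCTGCTAAATCACCTGGAAAACAAAATGGATCAACATCACAAAATACAG
CTCAAGGACGTTCACCTGGAACATCACAAACAGGATCAGCTAAAAATCAAGATTCATCAC
CTGCTAATCAAGGACTTCGTGGATCAAATGCTCAAGATTCACCTAAACAAGGAGAAACAT
CAAATGGACAAAATTCAGCTCAAAATACACAAGGATCACCTGGACTTGATAATTCACAAG
GATCAAATTATCAAGATAAATAAGACTCCTCGAGTTTAACCCGCT
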