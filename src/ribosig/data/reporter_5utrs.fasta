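>ARF6wt
AGAACUGGGAGGAGGAGUUGGAGGCCGGAGGGAGCCCGCGCUCGGGGCGGCGGCUGGAGGCAGCGCACCG
AGUUCCCGCGAGGAUCCAUGACCUGACGGGGCCCCGGAGCCGCGCUGCCUCUCGGGUGUCCUGGGUCGGU
GGGGAGCCCAGUGCUCGCAGGCCGGCGGGCGGGCCGGAGGGCUGCAGUCUCCCUCGCGGUGAGAGGAAGG
CGGAGGAGCGGGAACCGCGGCGGCGCUCGCGCGGCGCCUGCGGGGGGAAGGGCAGUUCCGGGCCGGGCCG
CGCCUCAGCAGGGCGGCGGCUCCCAGCGCAGUCUCAGGGCCCGGGUGGCGGCGGCGACUGGAGAAAUCAA
GUUGUGCGGUCGGUGAUGCCCGAGUGAGCGGGGGGCCUGGGCCUCUGCCCUUAGGAGGCAACUCCCACGC
AGGCCGCAAAGGCGCUCUCGCGGCCGAGAGGCUUCGUUUCGGUUUCGCGGCGGCGGCGGCGUUGUUGGCU
GAGGGGACCCGGGACACCUGAAUGCCCCCGGCCCCGGCUCCUCCGACGCGCCAUG
>ARF6mut
CCAUGGuUGGGAcGuGcAcUgGcAGcCgGcAGaGAGCCCGCcCaCcGcuacGCGGCUuacccgucCcgAg
CcAcUaggCcCGAGGAUCCAUGACCUGACGGGGCCCCGGAGCCGCGCUGCCUCUCGGGUGUCCUGGGUCG
GUGGGGAGCCCAGUGCUCGCAGGCCGGCGGGCGGGCCGGAGGGCUGCAGUCUCCCUCGCGGUGAGAGGAA
GGCGGAGGAGCGGGAACCGCGGCucuagaCGCGCGGCGCCUGCGGGGGGAAGGGCAGUUCCGGGCCGGGC
CGCGCCUCAGCAGGGCGGCGGCUCCCAGCGCAGUCUCAGGGCCCGGGUGGCGGCGGCGACUGGAGAAAUC
AAGUUGUGCGGUCGGUGAUGCCCGAGUGAGCGuauacagUcGaCaUaUuagCUUAGGAGGCAACUCCCAC
GCAGGCCGCAAAGGCGCUCUCGCGGCCGAGAGGCUUCGUUUCGGUUUCGCGGCGGCGGCGGCGUUGUUGG
CUGAGGGGACCCGGGACACCUGAAUGCCCCCGGCCCCGGCUCCUCCGACGCGCCAUG
>CyclinD1
CCAUGGGCUUAACAACAGUAACGUCACACGGACUACAGGGGAGUUUUGUUGAAGUUGCAAAGUCCUGGAG
CCUCCAGAGGGCUGUCGGCGCAGUAGCAGCGAGCAGCAGAGUCCGCACGCUCCGGCGAGGGGCAGAAGAG
CGCGAGGGAGCGCGGGGCAGCAGAAGCGAGAGCCGAGCGCGGACCCAGCCAGGACCCACAGCCCUCCCCA
GCUGCCCAGGAAGAGCCCCAGCCAUG
>ROCK1
GCUGGUUCCCCUUCCGAGCGUCCGCGCCCCGCAUGCGCAGUCUGCCCCGGCGGUCUCCGUUUGUUUGAAC
AGGAAGGCGGACAUAUUAGUCCCUCUCAGCCCCCCUCGCCCCACCCCCCAGGCAUUCGCCGCCGCGACUC
GCCCUUUCCCCGGCUGGGACCGCAGCCCCUCCCAGAAGCUCCCCCAUCAGCAGCCGCCGGGACCCAACUA
UCGUCUUCCUCUUCGCCCGCUCUCCAGCCUUUCCUCUGCUAAGUCUCCAUCGGGCAUCGACCUCGCCCUG
CCCCACCGGACACCGUAGCAGCAGCCCCAGCAGCGACGGGACAAAAUGGGAGAGUGAGGCUGUCCUGCGU
GGACCAGCUCGUGGCCGAGACUGAUCGGUGCGUCGGGCCGGGCCGAGUAGAGCCGGGGACGCGGGGCUAG
ACCGUCUACAGCGCCUCUGAGCGGAGCGGGCCCGGCCCGUGGCCCGAGCGGCGGCCGCAGCUGGCACAGC
UCCUCACCCGCCCUUUGCUUUCGCCUUUCCUCUUCUCCCUCCCUUGUUGCCCGGAGGGAGUCUCCACCCU
GCUUCUCUUUCUCUACCCGCUCCUGCCCAUCUCGGGACGGGGACCCCUCCAUGGCGACGGCGGCCGGGGC
CCGCUAGACUGAAGCACCUCGCCGGAGCGACGAGGCUGGUGGCGACGGCGCUGUCGGCUGUCGUGAGGGG
CUGCCGGGUGGGAUGCGACUUUGGGCGUCCGAGCGGCUGUGGGUCGCUGUUGCCCCCGGCCCGGGGUCUG
GAGAGCGGAGGUCCCCUCAGUGAGGGGAAGACGGGGGAACCGGGCGCACCUGGUGACCCUGAGGUUCCGG
CUCCUCCGCCCCGCGGCUGCGAACCCACCGCGGAGGAAGUUGGUUGAAAUUGCUUUCCGCUGCUGGUGCU
GGUAAGAGGGCAUUGUCACAGCAGCAGCAACACCCAUG
>PFN2
CGCUGCGGUAAGGAGCAGCCGCCACAGGCACAGCCGCUUCGCAGCCUCCCGCCGCUGGUUUGUCAGCCCC
GCGGCUGCGGGCGGCCGGGCGGCCGAGCGCGCUCUGAGGUUCGUCCCUCAUCGCUGAACCCGCGUCCUCC
CGCCGCAGCUCCUCGGGGAGGGGGGCGGUCGGUGCCUGCGCAGAGCCGCCUCCUCCCCGCCCCCGCCCCG
CCUCCCCCCGCGCCGCCGCCGCCCGCUACCGCCGCCGCCGCCGCUGCGCCUGCUGCUCCUCGCCGUCCGC
GCUGCAGUGCGAAGGGCUCGAGCCAUG
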