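# Published confusion matrix of the decision-tree UPDRS scorer (131 recordings).
# Rows: true UPDRS 0-4; columns: predicted UPDRS 0-4.
75  4  0  0  0
 4 18  0  0  0
 1  3 15  3  0
 0  0  2  4  0
 0  0  0  2  0
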