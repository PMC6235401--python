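2034ebc2fedeb6ab6735a61ce447a2ddcb83416c6f908aa4e78fbc0787147931  fig2_ory.nwk
eeec3398ab1dfd3bfc6945b0329d3915fa2f56e33097effca404d6414aee667e  fig2_ory.tsv
3fd7d6f2cfb6cfa837beaa8bacf277e4fc1bdfad626ea593dd3cbbe029d06ec5  montium_partial.nwk
44c0dc202c75ada8663aeba97237eab7a8d4abd8aa32a79dfa465fcbe62e43d8  montium_partial.tsv
c002b2dcbe99f4f7c3969c3ebb27bb7f48206401fb121a636e60595f1374d2d2  montium_partial_labels.tsv
ef9fffb84be0b8b872a4c4293b61f04bfce10e60e50339c9c71743f375df1977  table1_counts.tsv
28b2689f3677a929d1ffc880248fb3c20f14310284d30c282a81561858e3648e  fig1_pairs.tsv
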