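# Four-level Ramachandran region grid, version 1
# 36 rows = phi bins ascending from -180 in 10-degree steps;
# 36 columns = psi bins ascending from -180.
# F most favoured / A additionally allowed / G generously allowed / D disallowed
AAGGDDDGGAAAAAAAAAGGDDGGAAAAAAAAAAAA
FAGGDDDGGAAAAAAAAAGGDDGGAAAAFFFFFFFF
FAGGDDDGGAAFFFFFFAGGDDGGAAAAFFFFFFFF
FAGGDDDGGAAFFFFFFAGGDDGGAAAAFFFFFFFF
FAGGDDDGGAAFFFFFFAGGDDGGAAAAFFFFFFFF
FAGGDDDGGAAFFFFFFAGGGGGGAAAAFFFFFFFF
FAGGDDDGGAAFFFFFFAGGGGGGAAAAFFFFFFFF
FAGGDDDGGAAFFFFFFAAAAAAAAAAAFFFFFFFF
FAGGDDDGGAAFFFFFFAAAAAAAAAAAFFFFFFFF
AAGGDDDGGAAFFFFFFAAAAAAAAAAAFFFFFFFF
AAGGDDDGGAAFFFFFFAAAAAAAAAAAFFFFFFFF
AAGGDDDGGAAFFFFFFAAAAAAAAAAAFFFFFFFF
AAGGDDDGGAAFFFFFFAAAAAAAAAAAFFFFFFFF
AAGGDDDGGAAFFFFFFAAAAAAAAAAAAAAAAAAA
GGGGDDDGGAAAAAAAAAGGGGGGGGGGGGGGGGGG
GGGGDDDGGGGGGGGGGGGGGGGGGGGGGGGGGGGG
DDDDDDDGGGGGGGGGGGGGDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDGGGGGGGGGGGGGDDDDDDD
DDDDDDDDDDDDDDDDGGGGGGGGGGGGGDDDDDDD
GGGGDDDDDDDDDDDDGGAAAAAAAAAGGDDDGGGG
GGGGDDDDDDDDDDDDGGAAFFFFFAAGGDDDGGGG
AAGGDDDDDDDDDDDDGGAAFFFFFAAGGDDDGGAA
AAGGDDDDDDDDDDDDGGAAFFFFFAAGGDDDGGAA
AAGGDDDDDDDDDDDDGGAAAAAAAAAGGDDDGGAA
AAGGDDDDDDDDDDDDGGGGGGGGGGGGGDDDGGAA
GGGGDDDDDDDDDDDDGGGGGGGGGGGGGDDDGGGG
GGGGDDDDDDDDDDDDDDDDDDDDDDDDDDDDGGGG
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
GGGGDDDGGGGGGGGGGGGGDDGGGGGGGGGGGGGG
GGGGDDDGGGGGGGGGGGGGDDGGGGGGGGGGGGGG
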