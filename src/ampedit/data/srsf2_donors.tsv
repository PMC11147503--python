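donor_id	donor_string
SRSF2_silent_ssODN	t*g*gacggccgcgagctgcgggtgcaaatggcgcgctacggccgcccTccAgaTtcacaccacagccgccggggaccgccaccccgcag*g*t
SRSF2_P95H_ssODN	t*g*gacggccgcgagctgcgggtgcaaatggcgcgctacggccgccATccggactcacaccacagccgccggggaccgccaccccgcag*g*t
SRSF2_long_ssODN	TtcacgacaagcgcgacgctgaggacgctatggaTgccatggacggggccgtgctggacggccgcgagctgcgggtgcaaatggcgcgctacggccgccATccggactcacaccacagccgccggggaccgccaccccgcaggtacgggggcggtggctacggacgccggagccgcaggtaaacggggctgaggggaccg
SRSF2_P95H_silent_ssODN	t*g*gacggccgcgagctgcgggtgcaaatggcgcgctacggccgccATccAgaTtcacaccacagccgccggggaccgccaccccgcag*g*t
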