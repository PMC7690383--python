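chr2	207076106	207078770	GH02J206211
chr2	206945799	206952525	GH02J206081
chr7	155074428	155074660	GH07J155282
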