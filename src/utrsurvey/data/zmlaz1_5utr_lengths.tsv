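# Cloned 5' UTR lengths (bp) of the seven analyzed ZmLAZ1 family members.
# ZmLAZ1-3 has no 5' UTR and ZmLAZ1-6 (suspected pseudogene) is excluded.
gene	utr5_len
ZmLAZ1-1	1391
ZmLAZ1-2	1237
ZmLAZ1-7	493
ZmLAZ1-8	376
ZmLAZ1-9	355
ZmLAZ1-4	162
ZmLAZ1-5	149
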