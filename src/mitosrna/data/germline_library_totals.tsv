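sample	total_reads	mt_reads	total_sequences	mt_sequences
PGC	39792571	366447	567704	4859
SPG	39531404	258125	831190	6393
SPZ	28519791	346020	324746	5496
OCY	50561193	281005	457580	3702
ZYGO	49555453	338956	454901	3399
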