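population	latitude	n_autosomes	informative_reads	del_reads
Maine	45.5	322	301	171
Pennsylvania	40.0	900	1400	743
NorthCarolina	35.5	92	67	32
SouthCarolina	33.0	96	255	107
Georgia	30.9	102	246	101
Florida	25.5	174	225	76
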