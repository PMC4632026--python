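Frames	Tracks
Frame	X1	Y1
1	169.0	123.0
2	170.5	123.5
3	172.0	124.0
4	173.5	124.5
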