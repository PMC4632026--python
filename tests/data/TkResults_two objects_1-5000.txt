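Frames	Tracks
Frame	X1	Y1	X2	Y2
1	50.0	60.0	200.0	210.0
2	51.0	60.0	-	-
3	52.0	60.0	202.0	212.0
4	53.0	60.0	203.0	213.0
5	54.0	60.0	204.0	214.0
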