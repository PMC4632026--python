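Frames	Tracks
Frame	X1	Y1
4995	160.0	120.0
4996	161.5	120.5
4997	163.0	121.0
4998	164.5	121.5
4999	166.0	122.0
5000	167.5	122.5
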