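line_id	disease	teer_increase_pct
H4	healthy	52.1
H9	healthy	17.5
H12	healthy	9
H13	healthy	6.8
UC1	UC	30
UC2	UC	100
UC3	UC	62
UC13	UC	187.5
CD2	CD	37
CD3	CD	18
CD10	CD	49.45
CD11	CD	55.5
CD20	CD	47.3
CD24	CD	15.3
CD30	CD	377.5
CD21	CD	211.4
CD32	CD	52.9
CD42	CD	3.3
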