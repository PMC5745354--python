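word,polarity
hope,1
hopeful,1
love,1
happy,1
grateful,1
gratitude,1
thankful,1
great,1
good,1
awesome,1
stellar,1
wonderful,1
amazing,1
relieved,1
blessed,1
proud,1
support,1
survivor,1
fear,-1
scared,-1
afraid,-1
sad,-1
worry,-1
worried,-1
bad,-1
terrible,-1
awful,-1
ugh,-1
heartbreaking,-1
dying,-1
pain,-1
painful,-1
angry,-1
devastating,-1
cry,-1
lost,-1
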