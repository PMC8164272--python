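((((Human:0.007,Chimp:0.007):0.02,Macaque:0.035):0.06,(Mouse:0.08,Rat:0.085):0.18):0.1,((Dog:0.1,Cow:0.12):0.05,(Chicken:0.35,ZebraFinch:0.36):0.2):0.05,(Frog:0.7,Zebrafish:0.9):0.3);
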