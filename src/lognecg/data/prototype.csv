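component,mu,sigma,t0,D
P,-2.0,0.1,-0.24,3
Q,-3.0,0.4,-0.08,-50
R,-3.0,0.25,-0.045,80
S,-3.5,0.4,0.015,-10
Tp,-1.0,0.4,0.15,150
Tm,-1.0,0.23,0.22,-120
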