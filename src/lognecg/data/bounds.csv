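component,mu_lo,mu_hi,sigma_lo,sigma_hi,t0_lo,t0_hi,D_lo,D_hi
P,-2.4,-1.6,0.08,0.12,-0.288,-0.192,0,3.6
Q,-3.6,-2.4,0.32,0.48,-0.096,-0.064,-60,0
R,-3.6,-2.4,0.2,0.3,-0.054,-0.036,0,96
S,-4.2,-2.8,0.32,0.48,0.012,0.018,-12,0
Tp,-1.2,-0.8,0.32,0.48,0.12,0.18,0,204
Tm,-1.2,-0.8,0.184,0.276,0.176,0.264,-144,0
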