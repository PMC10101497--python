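# Cycle-start state paired with reference_params.yaml (synthetic;
# estimated jointly with the parameters).
RP_LH: 37.151895
LH: 20.442344
RP_FSH: 64.863605
FSH: 6.044082
RcF: 0.7819
GrF: 20.384546
DomF: 260.596482
Sc1: 18.015379
Sc2: 2.104125
Lut1: 4.275336
Lut2: 10.849625
Lut3: 5.828889
Lut4: 6.167822
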