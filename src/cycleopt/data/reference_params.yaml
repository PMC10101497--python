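# Synthetic reference parameter set for the cycleopt menstrual-cycle model.
# Produced by the package's staged calibration against the designed
# synthetic 28-day hormone table (synth.designed_cycle_table); yields a stable
# ~28.0-day limit cycle. Units: see cycleopt.params.
V0_LH: 303.8817245635
V1_LH: 6355.7316935288
Km_LH: 230.3903081334
Ki_LH_P: 30.222252177
k_LH: 10.3109210616
c_LH_P: 0.2960026435
c_LH_E: 0.0551971195
alpha_LH: 14.0
V_FSH: 216.375444602
Ki_FSH_Inh: 339.1246088506
tau: 2.0
k_FSH: 28.4655356221
c_FSH_P: 0.0001506812
c_FSH_E: 0.0176296055
alpha_FSH: 8.21
v: 2.5
w: 10.0
q: 4.0
b: 0.0009268714
c1: 0.099660531
c2: 0.0328082679
c3: 0.0555573458
c4: 0.0004470246
d1: 0.838043841
d2: 0.8387630552
k1: 0.8436144859
k2: 0.8280219339
k3: 0.8377241828
k4: 0.8586621431
alpha: 1.1004016459
gamma: 1.6785341719
e0: 0.144613621
e1: 0.5657634093
e2: 0.1171731424
e3: 0.3764315893
p0: 0.2413652047
p1: 6.7381e-06
p2: 0.0384938366
h0: 0.0016779324
h1: 0.0044802818
h2: 5.17703e-05
h3: 0.0360354224
b1: 1.0
b2: 1.0
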