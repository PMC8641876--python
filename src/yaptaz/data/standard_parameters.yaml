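# Standard parameter set of the Hippo-YAP/TAZ circuit model.
# Calibrated so that the basal YAP/TAZ production rate kYTup0 = 0.007 lies in
# the monostable homeostatic window of the one-parameter bifurcation diagram,
# flanked by the degeneration switch (SN1 ~ 0.0035, SN2 ~ 0.0055) and the
# tumorigenesis switch (SN4 ~ 0.0105, SN3 ~ 0.0155).
# Units: concentrations and time are arbitrary units (a.u.); rates a.u./time
# or 1/time; J thresholds a.u.; n dimensionless.
kL1: 0.00675
kL2: 0.096
kL3: 0.05
kYTup0: 0.007
kYTup1: 0.00486
kYTup2: 0.0609
kYTup3: 0.0395
kYTup4: 0.001
kYTup5: 0.00615
kYTp1: 0.05
kS1: 0.005
kS2: 0.045
kS3: 0.05
kN1: 0.005
kN2: 0.045
kN3: 0.05
JL: 1.461
JYTup1: 0.5
JYTup2: 0.55
JYTup3: 0.02
JYTup4: 0.1
JS: 0.336
JN: 1.382
n: 4.0
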