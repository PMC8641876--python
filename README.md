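# yaptaz

Deterministic and stochastic analysis of the Hippo-YAP/TAZ regulatory
circuit: how one negative and two positive feedback loops hold a tissue in
homeostasis, and how the same wiring can trap it in a degenerative or a
tumorigenic state.

The package is aimed at systems biologists studying multistable gene
circuits: it provides the ODE model, equilibrium and saddle-node
bifurcation analysis, phase-plane tools, a threshold sensitivity scan, and
tau-leap stochastic population simulation — all from Python, with a thin
CLI for batch runs.

## The model

Five species: LATS1/2 kinase `L`, active (unphosphorylated, nuclear)
YAP/TAZ `YT_up`, inactive (phosphorylated) YAP/TAZ `YT_p`, SIRT1 `S`, and
NOTCH `N`.  Transcriptional activation uses Hill functions
H(x) = xⁿ/(xⁿ + Jⁿ); (de)phosphorylation uses Michaelis–Menten kinetics;
basal production is constant and degradation first-order:

    dL/dt     = kL1 + kL2·H(YT_up; JL) − kL3·L
    dYT_up/dt = kYTup0 + kYTup1·H(S; JYTup1) + kYTup2·H(N; JYTup2)
                − kYTup3·YT_up·L/(YT_up + JYTup3)
                + kYTup4·YT_p/(YT_p + JYTup4) − kYTup5·YT_up
    dYT_p/dt  = kYTup3·YT_up·L/(YT_up + JYTup3)
                − kYTup4·YT_p/(YT_p + JYTup4) − kYTp1·YT_p
    dS/dt     = kS1 + kS2·H(YT_up; JS) − kS3·S
    dN/dt     = kN1 + kN2·H(YT_up; JN) − kN3·N

`YT_up → LATS ⊣ YT_up` is the homeostatic negative feedback;
`YT_up ↔ SIRT1` and `YT_up ↔ NOTCH` are positive loops that create,
respectively, a lower (degeneration) and an upper (tumorigenesis) bistable
switch.  Because `S`, `N` and `YT_p` relax to algebraic quasi-steady
states, the system reduces to two ODEs in `(L, YT_up)` used for all
phase-plane and bifurcation work.

Sweeping the basal production rate `kYTup0` yields four saddle-node points:
SN1 < SN2 bound the degeneration switch, SN4 < SN3 the tumorigenesis
switch, and the standard value `kYTup0 = 0.007` sits in the monostable
homeostatic window between SN2 and SN4.  When the negative feedback is
weak the two switches overlap (SN4 < SN2) and all three tissue states
coexist (tristability).

## Worked example

```bash
python examples/02_bifurcation_diagram.py
```

prints (standard parameter set):

```
saddle-node thresholds (kYTup0 axis):
  SN1 = 0.00349
  SN2 = 0.00549
  SN3 = 0.01550
  SN4 = 0.01049
...
regimes:
  kYTup0=0.002   -> mono_degenerative
  kYTup0=0.0045  -> bistable_HD
  kYTup0=0.007   -> mono_homeostatic
  kYTup0=0.013   -> bistable_HT
  kYTup0=0.02    -> mono_tumorigenic
```

Reading: below SN1 = 0.0035 only the low-YAP/TAZ degenerative state exists;
between SN1 and SN2 it coexists with homeostasis (hysteresis: a tissue that
degenerates at SN1 only recovers above SN2); 0.007 is safely monostable;
past SN3 = 0.0155 the tissue is locked tumorigenic until the rate falls
below SN4 = 0.0105.

The stochastic counterpart (`examples/04_stochastic_population.py`,
60 cells, Ω = 100, 720 time units) shows the population consequence:

```
  kYTup0  degenerative  homeostatic  tumorigenic
   0.004          0.70         0.30         0.00
   0.005          0.15         0.85         0.00
   0.007          0.00         1.00         0.00
   0.012          0.00         0.85         0.15
   0.014          0.00         0.42         0.58
```

Molecular noise lets individual cells jump the switch well before the
deterministic threshold: the degenerative fraction grows as `kYTup0`
falls, the tumorigenic fraction as it rises.

The other examples cover deterministic time courses (`01`), the ±15%
threshold sensitivity scan with the J_N irreversibility case (`03`), and
nullcline/vector-field analysis (`05`).  The same stages are scriptable via
the `yaptaz` CLI (`simulate`, `bifurcation`, `nullclines`, `sensitivity`,
`stochastic`, `fixtures`).

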