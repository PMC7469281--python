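# TNF-alpha / macrophage-crosstalk signaling model (MDA-MB-231 context).
# Inputs: Macrophage (tumor-associated macrophage secretome present),
# TNF (TNF-alpha available; 0 models Etanercept neutralization).
# Crosstalk: macrophage cytokines drive JAK-STAT and PI3K-AKT, both of
# which sustain IKK/NFKB independently of TNF receptor engagement.
targets, factors
Macrophage, Macrophage
TNF, TNF
MacrophageCytokines, Macrophage
TNFR, TNF
JAK, MacrophageCytokines
STAT3, JAK
PI3K, MacrophageCytokines | TNFR
AKT, PI3K
IKK, TNFR | STAT3 | AKT
NFKB, IKK
Proliferation, NFKB & (STAT3 | AKT | TNFR)
Survival, NFKB
Apoptosis, !NFKB
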