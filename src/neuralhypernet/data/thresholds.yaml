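# Risk-range map for vertex/antivertex discretization.
#
# For every analysis variable, "0" is the range of the antivertex descriptor
# (observed, not a risk sign) and "1" the range of the vertex descriptor
# (observed risk sign).  Range fields: equals, min, max, min_exclusive,
# max_exclusive (bounds inclusive unless the *_exclusive flag is set).
# Values covered by neither range are treated as uninformative (see
# preprocess.discretize).  "Final diagnosis" is mapped only for the
# Q-analysis view of the complex, never as a classifier feature.

Age:
  "0": {max: 64}
  "1": {min: 65}
N_F_Pred:
  "0": {equals: 0}
  "1": {min: 1}
N_F_Risk:
  "0": {equals: 0}
  "1": {min: 1}
Previous DVT:
  "0": {equals: 0}
  "1": {equals: 1}
Palpitations:
  "0": {equals: 0}
  "1": {equals: 1}
Cough:
  "0": {equals: 0}
  "1": {equals: 1}
dDimer:
  "0": {max: 230}
  "1": {min: 230, min_exclusive: true}
FC:
  "0": {min: 50, max: 99}
  "1": {min: 100}
WBC:
  "0": {min: 2000, max: 10000}
  "1": {min: 10000}
Cancer at diagnosis:
  "0": {equals: 0}
  "1": {equals: 1}
Shockindex:
  "0": {min: 0.0, max: 0.89}
  "1": {min: 0.9}
Cancer:
  "0": {equals: 0}
  "1": {equals: 1}
RVD:
  "0": {equals: 0}
  "1": {equals: 1}
Dyspnea:
  "0": {equals: 0}
  "1": {equals: 1}
Chest pain:
  "0": {equals: 0}
  "1": {equals: 1}
PCO2:
  "0": {min: 35, max: 45}
  "1": {min: 45, min_exclusive: true}
PO2:
  "0": {max: 60}
  "1": {min: 60, min_exclusive: true}
PH:
  "0": {min: 7.3, max: 7.42}
  "1": {min: 7.42, min_exclusive: true}
Hemoptysis:
  "0": {equals: 0}
  "1": {equals: 1}
Final diagnosis:
  "0": {equals: 0}
  "1": {equals: 1}
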