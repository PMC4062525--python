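genes:
- X1
- X2
- X3
- X4
- X5
- X6
- X7
- X8
- X9
- X10
- X11
- X12
- X13
- X14
p: 0.001
q: 0.99
functions:
  X1:
  - inputs:
    - X1
    table: '01'
    prob: 0.856
  - inputs:
    - X1
    table: '01'
    prob: 0.144
  X2:
  - inputs:
    - X2
    table: '01'
    prob: 0.2768
  - inputs:
    - X2
    table: '01'
    prob: 0.7232
  X3:
  - inputs:
    - X3
    table: '01'
    prob: 0.6759
  - inputs:
    - X3
    table: '01'
    prob: 0.3241
  X4:
  - inputs:
    - X4
    table: '01'
    prob: 1.0
  X5:
  - inputs:
    - X5
    table: '01'
    prob: 1.0
  X6:
  - inputs:
    - X6
    table: '01'
    prob: 0.0263
  - inputs:
    - X6
    table: '01'
    prob: 0.4983
  - inputs:
    - X6
    table: '01'
    prob: 0.4754
  X7:
  - inputs:
    - X7
    table: '01'
    prob: 1.0
  X8:
  - inputs:
    - X8
    table: '01'
    prob: 0.0857
  - inputs:
    - X8
    table: '01'
    prob: 0.9143
  X9:
  - inputs:
    - X9
    table: '01'
    prob: 1.0
  X10:
  - inputs:
    - X10
    table: '01'
    prob: 1.0
  X11:
  - inputs:
    - X11
    table: '01'
    prob: 0.8508
  - inputs:
    - X11
    table: '01'
    prob: 0.1492
  X12:
  - inputs:
    - X12
    table: '01'
    prob: 1.0
  X13:
  - inputs:
    - X13
    table: '01'
    prob: 0.8697
  - inputs:
    - X13
    table: '01'
    prob: 0.1303
  X14:
  - inputs:
    - X14
    table: '01'
    prob: 0.6004
  - inputs:
    - X14
    table: '01'
    prob: 0.3996
topology_incomplete: true
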