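genes:
- p53
- Mdm2
p: 0.01
q: 0.9
functions:
  p53:
  - inputs:
    - p53
    - Mdm2
    table: '1100'
    prob: 0.5
  - inputs:
    - p53
    - Mdm2
    table: '1101'
    prob: 0.4
  - inputs:
    - p53
    - Mdm2
    table: '1011'
    prob: 0.09
  - inputs:
    - p53
    - Mdm2
    table: '0011'
    prob: 0.01
  Mdm2:
  - inputs:
    - p53
    - Mdm2
    table: '0011'
    prob: 0.5
  - inputs:
    - p53
    - Mdm2
    table: '0010'
    prob: 0.4
  - inputs:
    - p53
    - Mdm2
    table: '0100'
    prob: 0.09
  - inputs:
    - p53
    - Mdm2
    table: '1100'
    prob: 0.01
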