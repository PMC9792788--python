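C11: 0.7
C12: 0.6
C21: 0.5
C22: 0.7
C31: 0.7
C32: 0.5
C41: 0.0
C42: 0.0
C43: 0.9
C44: 1.0
C45: 1.0
C46: 0.9
F1: 0.3
R11: 0.0
R12: 1.7
R13: 3.0
R21: 1.7
R22: 2.5
R31: 1.4
R32: 1.5
R33: 1.0
R34: 1.4
R41: 1.5
R42: 1.0
R43: 1.6
R44: 0.0
R45: 0.0
T1: 0.0
T2: 0.0
T3: 0.0
alpha: 0.7
beta: 0.4
theta: 0.6
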