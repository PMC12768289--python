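site,Se,Be,Cu,Mn,As,Pb,Cd,Co,Cr,Ni,V,Hg
A1,0.23±0.001,0.79±0.002,1.39±0.001,53.58±0.005,3.34±0.002,21.9±0.001,0.16±0.002,3.71±0.008,2.84±0.006,10.2±0.007,2.86±0.005,0.19±0.004
A2,0.15±0.005,0.3±0.007,20.75±0.002,120.35±0.004,2±0.009,78.35±0.003,1.36±0.007,4.68±0.004,12.28±0.006,75.68±0.009,24.42±0.005,0.8±0.002
A3,0.04±0.006,0.12±0.002,8.77±0.002,78.08±0.009,0.51±0.008,1.11±0.005,0.84±0.006,2.76±0.002,3.99±0.001,0.2±0.001,7.22±0.002,0.06±0.003
A4,0.22±0.001,0.31±0.004,38.89±0.001,192.2±0.006,1.4±0.007,6.51±0.002,0.15±0.003,6.42±0.006,3.09±0.003,29.28±0.003,6.17±0.005,0.57±0.001
B1,0.19±0.001,0.42±0.001,38.6±0.005,187.4±0.007,3.16±0.002,19.38±0.004,0.09±0.002,8.84±0.003,16.67±0.001,19.73±0.005,21.74±0.007,0.08±0.004
B2,0.09±0.002,0.18±0.004,38.29±0.005,200.47±0.003,0.08±0.002,7.11±0.003,1.05±0.003,5.39±0.001,20.53±0.001,15.54±0.003,2.78±0.003,0.29±0.001
B3,0.06±0.002,0.14±0.002,3.89±0.002,88.86±0.002,0.27±0.001,1.2±0.002,0.96±0.002,9.39±0.001,8.32±0.003,12.17±0.001,0.8±0.003,0.96±0.002
B4,0.05±0.001,0.05±0.001,13.2±0.005,75.61±0.002,0.11±0.001,1.32±0.001,0.32±0.005,2.72±0.002,0.26±0.002,12.4±0.002,13.73±0.005,0.25±0.005
C,0.04±0.004,0.12±0.005,4.96±0.002,64.29±0.001,0.51±0.002,1.11±0.002,0.84±0.002,1.22±0.003,1.63±0.001,0.2±0.001,10.09±0.003,0.13±0.003
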