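site,As,Se,Pb,Be,Cd,Co,Cr,Cu,Mn,Ni,V,Hg
A1,1.633±0.008,0.273±0.003,0.935±0.005,0.011±0.004,0.705±0.009,0.31±0.008,0.139±0.004,0.197±0.002,113.57±0.006,1.237±0.009,1.509±0.006,0.762±0.006
A2,0.995±0.005,0.172±0.008,1.911±0.005,0.029±0.009,0.546±0.007,0.099±0.003,0.055±0.004,0.08±0.004,20.535±0.005,0.419±0.005,1.458±0.004,0.322±0.005
A3,2.49±0.006,0.129±0.009,0.826±0.006,0.005±0.005,0.811±0.008,0.055±0.008,0.083±0.005,0.208±0.005,27.54±0.007,0.456±0.008,1.05±0.004,0.088±0.004
A4,1.073±0.006,0.244±0.006,6.693±0.005,0.007±0.005,2.197±0.008,0.2±0.005,1.624±0.006,1.81±0.007,81.77±0.005,0.981±0.006,0.49±0.005,0.324±0.006
B1,5.657±0.005,0.229±0.006,0.439±0.005,0.003±0.008,0.026±0.006,0.529±0.006,0.542±0.005,1.98±0.006,24.977±0.006,10.66±0.009,5.225±0.008,0.025±0.008
B2,1.136±0.003,0.389±0.007,0.447±0.005,0.006±0.009,0.039±0.007,0.161±0.006,0.372±0.005,0.388±0.008,103.2±0.007,1.154±0.006,0.12±0.006,0.59±0.005
B3,0.744±0.009,0.044±0.007,0.697±0.005,0.045±0.009,0.917±0.006,0.254±0.004,0.049±0.006,2.258±0.006,409.94±0.006,0.851±0.006,0.651±0.006,0.904±0.006
B4,2.29±0.006,0.087±0.006,0.304±0.007,0.013±0.008,0.039±0.007,0.083±0.009,0.015±0.007,2.688±0.004,22.48±0.007,0.542±0.009,2.351±0.006,1.002±0.004
C,3.419±0.008,0.215±0.008,2.808±0.006,0.276±0.006,2.22±0.006,0.135±0.008,0.162±0.005,0.738±0.009,113.47±0.009,1.174±0.006,2.551±0.004,0.293±0.008
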