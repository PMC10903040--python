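property,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
molecular weight,89.09,121.16,133.1,147.13,165.19,75.07,155.16,131.17,146.19,131.17,149.21,132.12,115.13,146.15,174.2,105.09,119.12,117.15,204.23,181.19
mass,71.04,103.01,115.03,129.04,147.07,57.02,137.06,113.08,128.09,113.08,131.04,114.04,97.05,128.06,156.1,87.03,101.05,99.07,186.08,163.06
bulkiness,11.5,13.46,11.68,13.57,19.8,3.4,13.69,21.4,15.71,21.4,16.25,12.82,17.43,14.45,14.28,9.47,15.77,21.57,21.67,18.03
hydrophobicity,1.8,2.5,-3.5,-3.5,2.8,-0.4,-3.2,4.5,-3.9,3.8,1.9,-3.5,-1.6,-3.5,-4.5,-0.8,-0.7,4.2,-0.9,-1.3
hydrophilicity,-0.5,-1.0,3.0,3.0,-2.5,0.0,-0.5,-1.8,3.0,-1.8,-1.3,0.2,0.0,0.2,3.0,0.3,-0.4,-1.5,-3.4,-2.3
melting point,297.0,178.0,270.0,249.0,284.0,290.0,277.0,284.0,224.0,337.0,283.0,236.0,222.0,185.0,238.0,228.0,253.0,293.0,282.0,344.0
transfer free energy,0.3,0.9,-0.6,-0.7,0.5,0.3,-0.1,0.7,-1.8,0.5,0.4,-0.5,-0.3,-0.7,-1.4,-0.1,-0.2,0.6,0.3,-0.4
solvation free energy,0.67,0.38,-1.2,-0.76,2.3,0.0,0.64,1.9,-0.57,1.9,2.4,-0.6,1.2,-0.22,-2.1,0.01,0.52,1.5,2.6,1.6
buriability,0.38,0.45,0.15,0.18,0.5,0.36,0.17,0.6,0.03,0.45,0.4,0.12,0.18,0.07,0.01,0.22,0.23,0.54,0.27,0.15
volume,88.6,108.5,111.1,138.4,189.9,60.1,153.2,166.7,168.6,166.7,162.9,114.1,112.7,143.8,173.4,89.0,116.1,140.0,227.8,193.6
polarity,8.1,5.5,13.0,12.3,5.2,9.0,10.4,5.2,11.3,4.9,5.7,11.6,8.0,10.5,10.5,9.2,8.6,5.9,5.4,6.2
relative mutability,100.0,20.0,106.0,102.0,41.0,49.0,66.0,96.0,56.0,40.0,94.0,134.0,56.0,93.0,65.0,120.0,97.0,74.0,18.0,41.0
isoelectric point,6.0,5.07,2.77,3.22,5.48,5.97,7.59,6.02,9.74,5.98,5.74,5.41,6.3,5.65,10.76,5.68,5.6,5.96,5.89,5.66
amino acid distribution,8.25,1.37,5.45,6.75,3.86,7.07,2.27,5.96,5.84,9.66,2.42,4.06,4.7,3.93,5.53,6.56,5.34,6.87,1.08,2.92
chromatographic index,0.5,-6.8,-8.2,-16.9,13.2,0.0,-3.5,13.9,0.1,8.8,4.8,0.8,6.1,-4.8,0.8,1.2,2.7,2.7,14.9,6.1
residue volume,52.6,68.3,68.4,84.7,113.9,36.3,91.9,102.0,105.1,102.0,97.7,75.7,73.6,89.7,109.1,54.9,71.2,85.1,135.4,116.2
compressibility,-25.5,-32.8,-33.1,-36.2,-29.4,-27.0,-31.0,-31.8,-28.7,-31.7,-31.5,-23.8,-23.7,-26.9,-26.7,-24.5,-24.9,-30.7,-30.4,-28.9
hydration number,1.5,1.0,6.0,7.0,0.0,1.0,4.0,1.0,4.5,1.0,1.0,2.0,3.0,2.0,3.0,2.0,2.0,1.0,2.0,3.0
shape,0.52,0.62,0.76,0.68,0.7,0.0,0.7,1.02,0.68,0.98,0.78,0.76,0.36,0.68,0.68,0.53,0.7,0.76,0.7,0.7
stability,1.29,1.16,0.72,0.93,1.23,0.51,1.07,1.25,0.81,1.3,1.23,0.77,0.62,0.91,0.83,0.78,0.87,1.12,1.22,1.05
power to be at the N-terminal,0.7,1.1,1.5,0.9,0.6,1.6,1.0,0.5,0.9,0.5,0.6,1.6,1.9,0.8,1.0,1.6,1.3,0.5,0.9,1.0
power to be at the C-terminal,1.1,0.9,0.7,1.2,0.9,1.6,1.2,0.8,1.3,1.0,1.2,1.0,0.6,1.3,1.1,0.9,0.8,0.8,1.0,1.1
unfolding entropy change,4.2,7.5,6.0,7.8,10.0,3.8,8.5,9.5,9.8,9.0,9.2,6.5,5.5,8.2,10.5,5.0,6.2,8.0,11.5,10.2
unfolding enthalpy change,1.0,2.1,1.6,2.1,2.9,0.8,2.4,2.7,2.8,2.6,2.6,1.7,1.4,2.2,2.9,1.2,1.6,2.2,3.4,3.0
unfolding Gibbs free energy change,0.1,1.5,-0.4,-0.5,2.0,0.0,0.4,1.8,-0.6,1.7,1.5,-0.3,-0.2,-0.3,-0.1,-0.1,0.1,1.4,2.1,1.3
middle of alpha helix,1.5,0.8,0.9,1.2,1.0,0.4,1.0,1.1,1.1,1.3,1.3,0.7,0.2,1.2,1.0,0.7,0.7,0.9,1.0,0.9
alpha-helical tendency,1.42,0.7,1.01,1.51,1.13,0.57,1.0,1.08,1.16,1.21,1.45,0.67,0.57,1.11,0.98,0.77,0.83,1.06,1.08,0.69
beta-helical tendency,0.83,1.19,0.54,0.37,1.38,0.75,0.87,1.6,0.74,1.3,1.05,0.89,0.55,1.1,0.93,0.75,1.19,1.7,1.37,1.47
turn tendency,0.66,1.19,1.46,0.74,0.6,1.56,0.95,0.47,1.01,0.59,0.6,1.56,1.52,0.98,0.95,1.43,0.96,0.5,0.96,1.14
coil tendency,0.82,1.07,1.24,0.75,0.8,1.42,0.95,0.78,1.01,0.66,0.61,1.33,1.36,0.81,0.9,1.34,1.08,0.83,0.9,1.07
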