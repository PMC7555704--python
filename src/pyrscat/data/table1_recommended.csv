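# Recommended integral electron scattering cross sections for pyridine.
# Units: 10^-20 m^2.  Energy in eV.
# elastic: R-matrix (below 10 eV) / IAM-SCAR (above), the recommended set.
# attachment: shape resonances from the R-matrix calculation.
# electronic, ionization: IAM-SCAR ratio split of the total inelastic CS;
# vibrational: closure remainder of the reference TCS.
# rotational: dipole-Born calculation (2.2 D permanent dipole).
# Cells printed as "<0.1" in the source compilation are upper bounds; the loader
# decodes them to 0.05 (interval midpoint) and flags them. Blank cells are absent
# grid points (no data), not zeros.
E_eV,elastic,attachment,electronic,vibrational,ionization,rotational
0.11,423,,,,,1374
0.135,340,,,,,1145
0.16,284.1,,,,,984.4
0.185,244.1,,,,,864.9
0.21,214.1,,,,,772.5
0.235,190.8,,,,,698.8
0.26,172.3,,,,,638.6
0.285,157.2,,,,,588.5
0.31,144.8,,,,,546
0.335,134.3,,,,,509.5
0.36,125.3,,,,,477.8
0.385,117.6,,,,,450.1
0.41,110.9,,,,,425.6
0.435,105.1,,,,,403.7
0.46,99.89,,,,,384.1
0.485,95.27,,,,,366.4
0.51,91.14,,,,,350.3
0.535,87.42,,,,,335.7
0.56,84.05,,,,,322.3
0.585,80.99,,,,,310
0.61,78.18,,,,,298.7
0.635,75.61,,,,,288.2
0.66,73.23,,,,,278.4
0.685,71.06,,,,,269.3
0.71,69.23,<0.1,,,,260.9
0.735,68.64,0.1459,,,,252.9
0.76,67.39,18.25,,,,245.5
0.785,66.19,29.47,,,,238.5
0.81,65.01,7.442,,,,232
0.835,63.87,3.107,,,,225.8
0.86,62.77,1.479,,,,219.9
0.885,61.7,0.6735,,,,214.4
0.91,60.67,0.2315,,,,209.1
0.935,59.66,<0.1,,,,204.1
0.96,58.61,,,,,199.4
0.985,57.72,,,,,194.9
1,57.21,,,,,192.2
1.01,56.88,0.1512,,,,190.6
1.03,56.02,0.6431,,,,186.4
1.06,55.2,1.899,,,,182.5
1.08,54.4,6.533,,,,178.8
1.11,53.65,36.67,,,,175.2
1.13,52.93,9.549,,,,171.7
1.16,52.25,1.578,,,,168.4
1.18,51.59,0.184,,,,165.3
1.2,51.09,<0.1,,,,163.4
1.5,45.51,,,,,133.9
1.7,43.42,,,,,119.8
2,41.37,,,<0.1,,103.6
2.3,40.23,,,1.73,,91.51
2.6,39.64,,,3.26,,82.04
2.8,39.44,,,4.71,,76.8
3,39.33,,,2.05,,72.22
3.2,39.31,,,<0.1,,68.18
3.5,39.34,,<0.1,,,62.95
3.7,39.4,,2.47,,,59.91
4,39.51,,7.53,,,55.89
4.2,39.6,,12.32,,,53.51
4.4,39.73,,14.27,,,51.33
4.6,39.9,,16.33,,,49.34
4.8,40.18,,14.03,,,47.5
5,40.77,,11.25,,,45.81
5.2,42.28,,5.26,,,44.23
5.5,48.05,,1.99,,,42.08
5.8,44.2,,8.13,,,40.13
6,42.52,,9.65,,,38.94
6.5,41.8,,13.83,,,36.26
7,42.21,,17.40,,,33.94
7.5,41.79,,15.01,,,31.91
8,45.49,,11.82,,,30.13
8.5,47.75,,14.18,,,28.55
9,47.94,,12.21,,,27.13
9.5,51.54,,8.65,,,25.85
10,49.32,,12.27,,<0.1,24.7
12,45.19,,12.43,,0.18,20.99
15,40.6,,14.83,,1.329,17.21
20,42.28,,7.548,,4.012,13.32
30,35.56,,6.392,,8.778,9.277
40,31.64,,5.13,,10.97,7.179
50,28.84,,5.71,,11.81,5.884
70,24.92,,3.96,,12.27,4.36
90,22.4,,4.10,,12.59,3.485
100,21.42,,3.96,,12.26,3.173
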