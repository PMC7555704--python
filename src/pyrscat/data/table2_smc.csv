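# Integral elastic electron scattering cross sections for pyridine, 0.1-20 eV,
# calculated with the Schwinger multichannel (SMC) method with pseudopotentials
# at the static-exchange-polarization level.
# Units: 10^-20 m^2.  Energy in eV.
# The spike at 0.9 eV (81.96 between 32.47 and 34.43) is retained verbatim from
# the source table; interpolation across 0.8-1.0 eV is linear-linear.
E_eV,elastic
0.1,172.4
0.2,97.4
0.3,65.32
0.4,50.62
0.5,42.81
0.6,37.78
0.7,34.31
0.8,32.47
0.9,81.96
1,34.43
1.1,30.87
1.2,30.44
1.3,44.29
1.33,64.7
1.4,34.02
1.5,29.95
1.6,29.33
1.7,29.17
1.8,29.14
1.9,29.2
2,29.31
2.1,29.49
2.2,29.72
2.3,29.98
2.4,30.29
2.5,30.62
2.6,30.97
2.7,31.34
2.8,31.71
2.9,32.08
3,32.46
3.1,32.83
3.2,33.19
3.3,33.54
3.4,33.89
3.5,34.19
3.6,34.39
3.7,34.64
3.8,34.92
3.9,35.2
4,35.74
4.1,35.58
4.2,35.86
4.3,36.14
4.4,36.62
4.5,36.73
4.6,37.05
4.7,37.58
4.8,37.96
4.9,38.38
5,38.87
5.1,39.47
5.2,40.2
5.3,41.04
5.4,42.3
5.5,43.94
5.6,45.72
5.7,47.19
5.8,47.82
5.9,47.98
6,47.16
6.1,46.48
6.2,45.63
6.3,45.94
6.4,45.94
6.5,45.76
6.6,47.07
6.7,47.49
6.8,48.26
6.9,49.14
7,49.62
7.5,49.71
8,48.35
9,53.61
9.5,53.28
10,54.85
11,56.67
12,52.58
15,43.31
16,46.12
18,39.85
20,36.35
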