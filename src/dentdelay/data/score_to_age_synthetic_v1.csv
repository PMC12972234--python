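# SYNTHETIC stand-in reference table (not the published Demirjian values).
# Generated by dentdelay.tables.write_synthetic_fixtures; logistic maturation model v1.
sex,total_score,age_years
female,4.109,0.0
female,4.249,0.1
female,4.394,0.2
female,4.543,0.3
female,4.698,0.4
female,4.857,0.5
female,5.021,0.6
female,5.191,0.7
female,5.366,0.8
female,5.546,0.9
female,5.732,1.0
female,5.925,1.1
female,6.123,1.2
female,6.327,1.3
female,6.538,1.4
female,6.755,1.5
female,6.978,1.6
female,7.209,1.7
female,7.447,1.8
female,7.692,1.9
female,7.944,2.0
female,8.204,2.1
female,8.471,2.2
female,8.746,2.3
female,9.03,2.4
female,9.321,2.5
female,9.622,2.6
female,9.93,2.7
female,10.248,2.8
female,10.574,2.9
female,10.91,3.0
female,11.255,3.1
female,11.609,3.2
female,11.973,3.3
female,12.347,3.4
female,12.731,3.5
female,13.124,3.6
female,13.529,3.7
female,13.943,3.8
female,14.369,3.9
female,14.805,4.0
female,15.252,4.1
female,15.71,4.2
female,16.179,4.3
female,16.659,4.4
female,17.15,4.5
female,17.654,4.6
female,18.168,4.7
female,18.694,4.8
female,19.232,4.9
female,19.782,5.0
female,20.343,5.1
female,20.916,5.2
female,21.501,5.3
female,22.097,5.4
female,22.706,5.5
female,23.326,5.6
female,23.958,5.7
female,24.601,5.8
female,25.256,5.9
female,25.923,6.0
female,26.6,6.1
female,27.289,6.2
female,27.989,6.3
female,28.7,6.4
female,29.421,6.5
female,30.153,6.6
female,30.896,6.7
female,31.648,6.8
female,32.41,6.9
female,33.181,7.0
female,33.962,7.1
female,34.751,7.2
female,35.549,7.3
female,36.355,7.4
female,37.168,7.5
female,37.989,7.6
female,38.817,7.7
female,39.652,7.8
female,40.492,7.9
female,41.338,8.0
female,42.189,8.1
female,43.045,8.2
female,43.905,8.3
female,44.769,8.4
female,45.636,8.5
female,46.506,8.6
female,47.377,8.7
female,48.251,8.8
female,49.125,8.9
female,50.0,9.0
female,50.875,9.1
female,51.749,9.2
female,52.623,9.3
female,53.494,9.4
female,54.364,9.5
female,55.231,9.6
female,56.095,9.7
female,56.955,9.8
female,57.811,9.9
female,58.662,10.0
female,59.508,10.1
female,60.348,10.2
female,61.183,10.3
female,62.011,10.4
female,62.832,10.5
female,63.645,10.6
female,64.451,10.7
female,65.249,10.8
female,66.038,10.9
female,66.819,11.0
female,67.59,11.1
female,68.352,11.2
female,69.104,11.3
female,69.847,11.4
female,70.579,11.5
female,71.3,11.6
female,72.011,11.7
female,72.711,11.8
female,73.4,11.9
female,74.077,12.0
female,74.744,12.1
female,75.399,12.2
female,76.042,12.3
female,76.674,12.4
female,77.294,12.5
female,77.903,12.6
female,78.499,12.7
female,79.084,12.8
female,79.657,12.9
female,80.218,13.0
female,80.768,13.1
female,81.306,13.2
female,81.832,13.3
female,82.346,13.4
female,82.85,13.5
female,83.341,13.6
female,83.821,13.7
female,84.29,13.8
female,84.748,13.9
female,85.195,14.0
female,85.631,14.1
female,86.057,14.2
female,86.471,14.3
female,86.876,14.4
female,87.269,14.5
female,87.653,14.6
female,88.027,14.7
female,88.391,14.8
female,88.745,14.9
female,89.09,15.0
female,89.426,15.1
female,89.752,15.2
female,90.07,15.3
female,90.378,15.4
female,90.679,15.5
female,90.97,15.6
female,91.254,15.7
female,91.529,15.8
female,91.796,15.9
female,92.056,16.0
female,92.308,16.1
female,92.553,16.2
female,92.791,16.3
female,93.022,16.4
female,93.245,16.5
female,93.462,16.6
female,93.673,16.7
female,93.877,16.8
female,94.075,16.9
female,94.268,17.0
female,100.0,18.0
male,4.039,0.0
male,4.169,0.1
male,4.302,0.2
male,4.44,0.3
male,4.583,0.4
male,4.729,0.5
male,4.88,0.6
male,5.035,0.7
male,5.196,0.8
male,5.361,0.9
male,5.53,1.0
male,5.705,1.1
male,5.886,1.2
male,6.071,1.3
male,6.262,1.4
male,6.459,1.5
male,6.661,1.6
male,6.869,1.7
male,7.083,1.8
male,7.303,1.9
male,7.53,2.0
male,7.763,2.1
male,8.003,2.2
male,8.249,2.3
male,8.502,2.4
male,8.762,2.5
male,9.03,2.6
male,9.305,2.7
male,9.587,2.8
male,9.877,2.9
male,10.174,3.0
male,10.48,3.1
male,10.794,3.2
male,11.115,3.3
male,11.446,3.4
male,11.784,3.5
male,12.132,3.6
male,12.488,3.7
male,12.853,3.8
male,13.227,3.9
male,13.611,4.0
male,14.003,4.1
male,14.406,4.2
male,14.817,4.3
male,15.239,4.4
male,15.67,4.5
male,16.111,4.6
male,16.562,4.7
male,17.023,4.8
male,17.494,4.9
male,17.976,5.0
male,18.467,5.1
male,18.969,5.2
male,19.482,5.3
male,20.005,5.4
male,20.538,5.5
male,21.082,5.6
male,21.636,5.7
male,22.201,5.8
male,22.776,5.9
male,23.362,6.0
male,23.958,6.1
male,24.564,6.2
male,25.181,6.3
male,25.807,6.4
male,26.444,6.5
male,27.091,6.6
male,27.748,6.7
male,28.414,6.8
male,29.09,6.9
male,29.776,7.0
male,30.47,7.1
male,31.174,7.2
male,31.886,7.3
male,32.607,7.4
male,33.337,7.5
male,34.074,7.6
male,34.819,7.7
male,35.572,7.8
male,36.332,7.9
male,37.098,8.0
male,37.872,8.1
male,38.651,8.2
male,39.437,8.3
male,40.227,8.4
male,41.023,8.5
male,41.824,8.6
male,42.629,8.7
male,43.438,8.8
male,44.251,8.9
male,45.066,9.0
male,45.884,9.1
male,46.705,9.2
male,47.527,9.3
male,48.351,9.4
male,49.175,9.5
male,50.0,9.6
male,50.825,9.7
male,51.649,9.8
male,52.473,9.9
male,53.295,10.0
male,54.116,10.1
male,54.934,10.2
male,55.749,10.3
male,56.562,10.4
male,57.371,10.5
male,58.176,10.6
male,58.977,10.7
male,59.773,10.8
male,60.563,10.9
male,61.349,11.0
male,62.128,11.1
male,62.902,11.2
male,63.668,11.3
male,64.428,11.4
male,65.181,11.5
male,65.926,11.6
male,66.663,11.7
male,67.393,11.8
male,68.114,11.9
male,68.826,12.0
male,69.53,12.1
male,70.224,12.2
male,70.91,12.3
male,71.586,12.4
male,72.252,12.5
male,72.909,12.6
male,73.556,12.7
male,74.193,12.8
male,74.819,12.9
male,75.436,13.0
male,76.042,13.1
male,76.638,13.2
male,77.224,13.3
male,77.799,13.4
male,78.364,13.5
male,78.918,13.6
male,79.462,13.7
male,79.995,13.8
male,80.518,13.9
male,81.031,14.0
male,81.533,14.1
male,82.024,14.2
male,82.506,14.3
male,82.977,14.4
male,83.438,14.5
male,83.889,14.6
male,84.33,14.7
male,84.761,14.8
male,85.183,14.9
male,85.594,15.0
male,85.997,15.1
male,86.389,15.2
male,86.773,15.3
male,87.147,15.4
male,87.512,15.5
male,87.868,15.6
male,88.216,15.7
male,88.554,15.8
male,88.885,15.9
male,89.206,16.0
male,89.52,16.1
male,89.826,16.2
male,90.123,16.3
male,90.413,16.4
male,90.695,16.5
male,90.97,16.6
male,91.238,16.7
male,91.498,16.8
male,91.751,16.9
male,91.997,17.0
male,100.0,18.5
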