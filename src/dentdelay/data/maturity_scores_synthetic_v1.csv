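# SYNTHETIC stand-in reference table (not the published Demirjian values).
# Generated by dentdelay.tables.write_synthetic_fixtures; logistic maturation model v1.
sex,tooth_position,stage,score
female,1,A,0.47
female,1,B,1.3
female,1,C,2.48
female,1,D,4.13
female,1,E,6.14
female,1,F,8.26
female,1,G,10.15
female,1,H,11.8
female,2,A,0.51
female,2,B,1.4
female,2,C,2.67
female,2,D,4.44
female,2,E,6.6
female,2,F,8.89
female,2,G,10.92
female,2,H,12.7
female,3,A,0.46
female,3,B,1.26
female,3,C,2.42
female,3,D,4.02
female,3,E,5.98
female,3,F,8.05
female,3,G,9.89
female,3,H,11.5
female,4,A,0.56
female,4,B,1.53
female,4,C,2.92
female,4,D,4.87
female,4,E,7.23
female,4,F,9.73
female,4,G,11.95
female,4,H,13.9
female,5,A,0.56
female,5,B,1.55
female,5,C,2.96
female,5,D,4.93
female,5,E,7.33
female,5,F,9.87
female,5,G,12.13
female,5,H,14.1
female,6,A,0.7
female,6,B,1.94
female,6,C,3.7
female,6,D,6.16
female,6,E,9.15
female,6,F,12.32
female,6,G,15.14
female,6,H,17.6
female,7,A,0.74
female,7,B,2.02
female,7,C,3.86
female,7,D,6.44
female,7,E,9.57
female,7,F,12.88
female,7,G,15.82
female,7,H,18.4
male,1,A,0.49
male,1,B,1.34
male,1,C,2.56
male,1,D,4.27
male,1,E,6.34
male,1,F,8.54
male,1,G,10.49
male,1,H,12.2
male,2,A,0.52
male,2,B,1.42
male,2,C,2.71
male,2,D,4.51
male,2,E,6.71
male,2,F,9.03
male,2,G,11.09
male,2,H,12.9
male,3,A,0.48
male,3,B,1.31
male,3,C,2.5
male,3,D,4.17
male,3,E,6.19
male,3,F,8.33
male,3,G,10.23
male,3,H,11.9
male,4,A,0.54
male,4,B,1.5
male,4,C,2.86
male,4,D,4.76
male,4,E,7.07
male,4,F,9.52
male,4,G,11.7
male,4,H,13.6
male,5,A,0.55
male,5,B,1.52
male,5,C,2.9
male,5,D,4.83
male,5,E,7.18
male,5,F,9.66
male,5,G,11.87
male,5,H,13.8
male,6,A,0.69
male,6,B,1.9
male,6,C,3.63
male,6,D,6.05
male,6,E,9.0
male,6,F,12.11
male,6,G,14.88
male,6,H,17.3
male,7,A,0.73
male,7,B,2.01
male,7,C,3.84
male,7,D,6.41
male,7,E,9.52
male,7,F,12.81
male,7,G,15.74
male,7,H,18.3
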