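id,class_label,age,psa,dheas,coefficient,psa_rule,dheas_rule,ratio_rule
A0001,PCa,58,6.00,1144.79,44.5,BPH/HC,BPH/HC,PCa
A0003,PCa,78,43.00,191.792,49.3,PCa,PCa,PCa
A0004,PCa,66,8.00,591.168,38.7,PCa,PCa,PCa
A0005,PCa,68,9.50,638.852,49.8,PCa,PCa,PCa
A0006,PCa,76,7.30,385.659,42.2,BPH/HC,PCa,PCa
A0007,PCa,82,78.00,2106.52,42.7,PCa,BPH/HC,PCa
A0008,PCa,74,5.29,1490.21,51.1,BPH/HC,BPH/HC,PCa
A0010,PCa,70,400.00,234.102,52.9,PCa,PCa,PCa
A0011,PCa,80,11.00,247.311,47.6,PCa,PCa,PCa
A0012,PCa,69,10.00,430.209,49.3,PCa,PCa,PCa
A0014,PCa,70,12.00,903.685,40.9,PCa,BPH/HC,PCa
A0015,PCa,78,4.90,294.322,50.2,BPH/HC,PCa,PCa
A0017,PCa,72,12.00,1286.50,52.0,PCa,BPH/HC,PCa
A0018,PCa,69,,1423.28,5.0,,BPH/HC,HC
A0020,PCa,61,5.52,553.783,8.0,BPH/HC,PCa,HC
A0021,PCa,75,5.50,519.083,43.1,BPH/HC,PCa,PCa
A0022,PCa,65,21.00,1209.71,47.1,PCa,BPH/HC,PCa
A0023,PCa,56,6.29,977.112,47.6,BPH/HC,BPH/HC,PCa
A0024,PCa,57,12.00,1142.33,51.6,PCa,BPH/HC,PCa
A0025,PCa,72,8.70,168.51,44.9,PCa,PCa,PCa
C0001,BPH,57,5.20,1443.20,22.6,BPH/HC,BPH/HC,BPH
C0002,BPH,64,17.00,947.786,19.6,PCa,BPH/HC,BPH
C0003,BPH,65,7.27,1158.89,21.6,BPH/HC,BPH/HC,BPH
C0004,BPH,75,9.12,317.604,26.8,PCa,PCa,BPH
C0005,BPH,64,11.00,1550.66,22.8,PCa,BPH/HC,BPH
C0007,BPH,62,5.45,1590.28,44.3,BPH/HC,BPH/HC,PCa
C0008,BPH,66,4.68,684.52,48.9,BPH/HC,PCa,PCa
C0009,BPH,61,5.40,955.398,23.5,BPH/HC,BPH/HC,BPH
C0010,BPH,63,2.50,1508.79,18.7,BPH/HC,BPH/HC,BPH
C0012,BPH,59,5.80,2363.96,47.4,BPH/HC,BPH/HC,PCa
C0014,BPH,60,6.00,2216.43,50.3,BPH/HC,BPH/HC,PCa
C0016,BPH,54,5.50,1622.97,23.5,BPH/HC,BPH/HC,BPH
C0017,BPH,58,6.60,584.228,18.9,BPH/HC,PCa,BPH
C0018,BPH,58,12.94,600.57,18.9,PCa,PCa,BPH
C0019,BPH,52,10.33,1552.22,20.3,PCa,BPH/HC,BPH
C0020,BPH,50,3.54,899.207,23.9,BPH/HC,BPH/HC,BPH
C0021,BPH,69,6.00,901.446,26.4,BPH/HC,BPH/HC,BPH
C0022,BPH,63,6.00,1300.37,21.4,BPH/HC,BPH/HC,BPH
C0023,BPH,52,5.44,1844.59,21.9,BPH/HC,BPH/HC,BPH
C0024,BPH,62,8.94,911.52,24.4,PCa,BPH/HC,BPH
HC0001,HC,79,1.11,907.043,5.3,,BPH/HC,HC
HC0002,HC,54,0.5,1672.22,5.3,,BPH/HC,HC
HC0003,HC,72,1.12,538.336,4.5,,PCa,HC
HC0004,HC,84,,298.8,6.4,,PCa,HC
HC0005,HC,64,0.45,1512.15,49.5,,BPH/HC,PCa
HC0006,HC,54,1.66,531.844,47.4,,PCa,PCa
HC0007,HC,60,1.91,1853.55,6.0,,BPH/HC,HC
HC0008,HC,50,0.24,1848.17,5.7,,BPH/HC,HC
HC0009,HC,83,1.23,1680.05,48.6,,BPH/HC,PCa
HC0010,HC,54,0.33,2534.77,5.8,,BPH/HC,HC
HC0011,HC,66,1.13,960.77,6.2,,BPH/HC,HC
HC0012,HC,57,1.2,1440.51,5.6,,BPH/HC,HC
HC0013,HC,73,0.5,1167.40,5.4,,BPH/HC,HC
HC0014,HC,78,2.53,673.551,49.7,,PCa,PCa
HC0015,HC,70,0.43,602.138,6.1,,PCa,HC
HC0016,HC,65,0.43,1438.50,5.6,,BPH/HC,HC
HC0017,HC,59,0.24,844.584,5.8,,PCa,HC
HC0018,HC,65,1.94,1678.04,4.6,,BPH/HC,HC
HC0019,HC,58,1.85,1440.07,6.3,,BPH/HC,HC
HC0020,HC,67,2.81,1377.38,47.6,,BPH/HC,PCa
HC0021,HC,55,3.16,1419.92,4.3,,BPH/HC,HC
HC0022,HC,66,1.79,530.501,4.5,,PCa,HC
HC0023,HC,72,1.99,541.246,5.1,,PCa,HC
HC0024,HC,71,1.21,534.53,48.7,,PCa,PCa
HC0025,HC,68,1.1,627.21,6.1,,PCa,HC
HC0026,HC,82,0.71,1408.50,6.1,,BPH/HC,HC
HC0027,HC,60,0.63,1988.76,6.1,,BPH/HC,HC
HC0028,HC,54,1.22,193.359,4.6,,PCa,HC
HC0029,HC,54,0.42,1037.78,6.0,,BPH/HC,HC
HC0030,HC,79,1.46,430.433,4.8,,PCa,HC
HC0031,HC,84,1.49,1128.00,4.7,,BPH/HC,HC
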