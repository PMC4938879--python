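# patient_id: dataset-1
# a0_bq: 7.4e9
# provenance: clinical whole-body-scintigraphy reference table, patient 1
time_h,organ,value_bq
0,liver,0
0,kidney,0
0,brain,0
0.5,liver,13.70
0.5,kidney,3.38
0.5,brain,0
2.5,liver,18.70
2.5,kidney,2.30
2.5,brain,0
24.5,liver,17.90
24.5,kidney,1.93
24.5,brain,0
119.5,liver,10.00
119.5,kidney,1.12
119.5,brain,0
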