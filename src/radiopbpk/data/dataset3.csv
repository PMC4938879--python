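# patient_id: dataset-3
# a0_bq: 7.4e9
# provenance: clinical whole-body-scintigraphy reference table, patient 3
time_h,organ,value_bq
0,liver,0
0,kidney,0
0,brain,0
0.5,liver,5.75
0.5,kidney,2.12
0.5,brain,0.15
2.5,liver,6.05
2.5,kidney,1.31
2.5,brain,0.20
20.5,liver,5.50
20.5,kidney,1.36
20.5,brain,0.02
71.5,liver,3.57
71.5,kidney,0.74
71.5,brain,0.0
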