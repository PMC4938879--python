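# patient_id: dataset-4
# a0_bq: 7.4e9
# provenance: clinical whole-body-scintigraphy reference table, patient 4
time_h,organ,value_bq
0,liver,0
0,kidney,0
0,brain,0
0.5,liver,7.5
0.5,kidney,2.28
0.5,brain,0
4.5,liver,7.79
4.5,kidney,1.92
4.5,brain,0
26.5,liver,7.2
26.5,kidney,1.81
26.5,brain,0
69.5,liver,5.2
69.5,kidney,1.22
69.5,brain,0
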