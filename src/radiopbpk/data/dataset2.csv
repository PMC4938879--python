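# patient_id: dataset-2
# a0_bq: 7.4e9
# provenance: clinical whole-body-scintigraphy reference table, patient 2
time_h,organ,value_bq
0,liver,0
0,kidney,0
0,brain,0
0.5,liver,2.41
0.5,kidney,3.60
0.5,brain,0.05
3.5,liver,1.38
3.5,kidney,1.73
3.5,brain,0.2
23.5,liver,0.98
23.5,kidney,1.50
23.5,brain,0.15
119.5,liver,0.33
119.5,kidney,0.27
119.5,brain,0.066
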