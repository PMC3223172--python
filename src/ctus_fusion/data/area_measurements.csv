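tumor_volume_mm3,ct_tumor_area_mm2,ct_fat_area_mm2,ct_percent_fat,hist_tumor_area_mm2,hist_fat_area_mm2,hist_percent_fat
9.5,2.4,41.0,94.4,7.4,48.4,86.7
13.5,16.9,33.3,66.4,10.5,53.0,83.5
45.4,14.9,29.0,66.1,16.4,35.5,68.4
74.9,33.3,17.4,34.3,26.3,43.3,62.2
113.4,45.8,43.0,48.4,31.7,29.6,48.3
114.1,38.7,20.1,34.2,30.1,32.0,51.5
120.2,46.7,28.0,37.5,37.8,29.6,43.9
147.6,39.3,13.7,25.9,37.8,37.8,50.0
193.2,52.7,35.3,40.1,40.1,32.6,44.8
225.1,72.8,23.8,24.6,52.0,30.4,36.9
253.9,62.0,33.1,34.8,49.3,40.2,44.9
309.4,72.4,26.7,26.9,69.7,26.5,27.5
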