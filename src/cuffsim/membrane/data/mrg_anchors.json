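{
 "version": 1,
 "description": "Myelinated-axon geometry anchors per fiber diameter (um); published values for nine diameters.",
 "fiber_diameter_um": [
  5.7,
  7.3,
  8.7,
  10.0,
  11.5,
  12.8,
  14.0,
  15.0,
  16.0
 ],
 "internodal_length_um": [
  500,
  750,
  1000,
  1150,
  1250,
  1350,
  1400,
  1450,
  1500
 ],
 "node_diameter_um": [
  1.9,
  2.4,
  2.8,
  3.3,
  3.7,
  4.2,
  4.7,
  5.0,
  5.5
 ],
 "axon_diameter_um": [
  3.4,
  4.6,
  5.8,
  6.9,
  8.1,
  8.8,
  9.2,
  9.5,
  9.7
 ],
 "flut_length_um": [
  35,
  38,
  40,
  46,
  50,
  54,
  56,
  58,
  60
 ],
 "n_lamellae": [
  80,
  100,
  110,
  120,
  130,
  135,
  140,
  145,
  150
 ]
}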