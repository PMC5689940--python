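{
 "format": "planedose-beam-model",
 "version": 1,
 "provenance": "Published Versa HD best-fit parameters; geometry values are package defaults (assumptions), fully overridable.",
 "energy_mode": "6FFF",
 "source": {
  "gaussians": [
   [
    0.022,
    3.3579,
    3.304
   ],
   [
    0.0465,
    0.6471,
    0.6049
   ]
  ],
  "source_plane_z": 6.0
 },
 "oar": {
  "coeffs": [
   0.55049,
   -0.0021479,
   -0.0034245,
   0.00025978,
   -6.0768e-06
  ]
 },
 "kernel": {
  "components": [
   [
    0.8709,
    0.2241
   ],
   [
    0.0178,
    1.4376
   ],
   [
    0.0032,
    8.4279
   ]
  ]
 },
 "leaf_end": {
  "alpha": 0.7,
  "beta": 0.24,
  "soft_range": 1.0
 },
 "mlc": {
  "bulk": 0.01,
  "interleaf": 0.01,
  "tongue_and_groove": 0.01,
  "tg_width_iso": 0.026,
  "leaf_width_iso": 0.5
 },
 "geometry": {
  "sad": 100.0,
  "z_mlc": 33.0,
  "z_jaw": 43.0
 }
}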