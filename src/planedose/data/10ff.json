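{
 "format": "planedose-beam-model",
 "version": 1,
 "provenance": "Published Versa HD best-fit parameters; geometry values are package defaults (assumptions), fully overridable. Kernel reused from the same-energy FFF fit.",
 "energy_mode": "10FF",
 "source": {
  "gaussians": [
   [
    0.0648,
    3.7172,
    2.7917
   ],
   [
    0.0449,
    0.9223,
    0.7526
   ]
  ],
  "source_plane_z": 12.5
 },
 "oar": null,
 "kernel": {
  "components": [
   [
    1.0385,
    0.2421
   ],
   [
    0.0298,
    1.3446
   ],
   [
    0.0033,
    8.3493
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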