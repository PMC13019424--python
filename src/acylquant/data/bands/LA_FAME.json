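{
 "species": "LA",
 "ester_form": "FAME",
 "bands": [
  {
   "center": 1740.0,
   "fwhm": 18.0,
   "amplitude": 1.0,
   "shape": 0.3
  },
  {
   "center": 1658.0,
   "fwhm": 16.0,
   "amplitude": 1.7,
   "shape": 0.3
  },
  {
   "center": 1265.0,
   "fwhm": 18.0,
   "amplitude": 1.55,
   "shape": 0.3
  },
  {
   "center": 1455.0,
   "fwhm": 16.0,
   "amplitude": 0.7,
   "shape": 0.4
  },
  {
   "center": 1439.0,
   "fwhm": 22.0,
   "amplitude": 1.9,
   "shape": 0.4
  },
  {
   "center": 1301.0,
   "fwhm": 18.0,
   "amplitude": 1.05,
   "shape": 0.2
  },
  {
   "center": 1196.0,
   "fwhm": 20.0,
   "amplitude": 0.5,
   "shape": 0.3
  },
  {
   "center": 1120.0,
   "fwhm": 14.0,
   "amplitude": 0.8,
   "shape": 0.3
  },
  {
   "center": 1080.0,
   "fwhm": 16.0,
   "amplitude": 1.3,
   "shape": 0.3
  },
  {
   "center": 1063.0,
   "fwhm": 14.0,
   "amplitude": 0.75,
   "shape": 0.3
  },
  {
   "center": 905.0,
   "fwhm": 12.0,
   "amplitude": 0.55,
   "shape": 0.3
  },
  {
   "center": 760.0,
   "fwhm": 20.0,
   "amplitude": 0.25,
   "shape": 0.3
  },
  {
   "center": 718.0,
   "fwhm": 18.0,
   "amplitude": 0.5,
   "shape": 0.3
  },
  {
   "center": 880.0,
   "fwhm": 16.0,
   "amplitude": 0.7,
   "shape": 0.3
  },
  {
   "center": 852.0,
   "fwhm": 16.0,
   "amplitude": 0.9,
   "shape": 0.3
  }
 ]
}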