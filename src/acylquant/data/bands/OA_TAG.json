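{
 "species": "OA",
 "ester_form": "TAG",
 "bands": [
  {
   "center": 1744.0,
   "fwhm": 23.4,
   "amplitude": 1.0,
   "shape": 0.3
  },
  {
   "center": 1651.0,
   "fwhm": 16.0,
   "amplitude": 1.08,
   "shape": 0.3
  },
  {
   "center": 1265.0,
   "fwhm": 18.0,
   "amplitude": 0.55,
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
   "amplitude": 2.352,
   "shape": 0.4
  },
  {
   "center": 1301.0,
   "fwhm": 18.0,
   "amplitude": 1.25,
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
   "amplitude": 0.9,
   "shape": 0.3
  },
  {
   "center": 1080.0,
   "fwhm": 16.0,
   "amplitude": 1.25,
   "shape": 0.3
  },
  {
   "center": 1063.0,
   "fwhm": 14.0,
   "amplitude": 0.8,
   "shape": 0.3
  },
  {
   "center": 920.0,
   "fwhm": 12.0,
   "amplitude": 0.55,
   "shape": 0.3
  },
  {
   "center": 760.0,
   "fwhm": 20.0,
   "amplitude": 0.28,
   "shape": 0.3
  },
  {
   "center": 718.0,
   "fwhm": 18.0,
   "amplitude": 0.35,
   "shape": 0.3
  },
  {
   "center": 865.0,
   "fwhm": 18.0,
   "amplitude": 0.75,
   "shape": 0.3
  },
  {
   "center": 845.0,
   "fwhm": 18.0,
   "amplitude": 0.55,
   "shape": 0.3
  }
 ]
}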