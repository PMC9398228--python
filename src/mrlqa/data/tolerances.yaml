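# Default QA tolerance tables for the daily image-quality (PIQT) tests and
# the 3D geometric-distortion test.  Operators are applied exactly as
# written: ">"/"<" strict, intervals closed.
piqt:
  snr:
    MS-MESE: {echo1: "> 59", echo2: "> 44"}
    MS-FFE: {echo1: "> 48"}
    2D-MESE: {echo1: "> 45", echo2: "> 39", echo3: "> 30"}
  uniformity_percent:
    MS-MESE: {echo1: "< 47", echo2: "< 48"}
    MS-FFE: {echo1: "< 47"}
    2D-MESE: {echo1: "< 10", echo2: "< 10", echo3: "< 10"}
  linearity_percent:
    MS-MESE: {echo1: "< 0.5"}
  slice_fwhm_mm:
    MS-MESE: {echo1: "4.65-5.15", echo2: "4.45-4.95"}
    MS-FFE: {echo1: "4.75-5.25"}
  slice_integral_mm:
    MS-MESE: {echo1: "4.85-5.35", echo2: "4.65-5.15"}
    MS-FFE: {echo1: "4.90-5.40"}
  pixel_horizontal_mm:
    MS-MESE: {echo1: "< 1.3", echo2: "< 1.3"}
  pixel_vertical_mm:
    MS-MESE: {echo1: "< 1.5", echo2: "< 1.5"}
distortion:
  max_distortion_mm:
    dsv20cm: "<= 1.0"
    dsv30cm: "<= 2.0"
    dsv40cm: "<= 4.0"
    dsv50cm: "<= 20.0"
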