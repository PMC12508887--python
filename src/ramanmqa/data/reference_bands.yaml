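# Reference band table used by the cell-phantom generator.
#
# Every metabolite's "bands" are its library positions; "filler" bands are
# fixed non-library background bands placed in quiet spectral regions (>= 25
# cm^-1 from every library center) so simulated spectra overlap realistically
# without corrupting any quantified integration window.
#
# Deliberate omissions at the modeled 3 cm^-1 resolution:
#   - nucleic_acid_po2 (1078) is spectrally degenerate with cholesterol (1083)
#     inside a +-8 cm^-1 window, so the default nucleus signature carries
#     deoxyribose only and the PO2- band is listed but unused by the default
#     phantom composition.
#   - palmitoleic_acid's 1656 band sits 2 cm^-1 from the squalene 1666 +- 8
#     window edge; the generator renders palmitoleic acid from its 1263 and
#     3009 bands only.
#
# band_shape gives the default pseudo-Voigt width (sigma, cm^-1) and
# Gaussian/Lorentzian mixing (eta); individual bands may override both.
band_shape:
  sigma: 2.5
  eta: 0.1
metabolites:
  deoxyribose:
    bands:
      - {center: 1423, amplitude: 1.0}
    filler:
      - {center: 780, amplitude: 0.4}
      - {center: 1180, amplitude: 0.25}
      - {center: 2930, amplitude: 0.2}
  nucleic_acid_po2:
    bands:
      - {center: 1078, amplitude: 1.0}
    filler:
      - {center: 812, amplitude: 0.3}
      - {center: 1485, amplitude: 0.25}
  triglyceride:
    bands:
      - {center: 1746, amplitude: 1.0}
    filler:
      - {center: 1170, amplitude: 0.3}
      - {center: 2850, amplitude: 0.45}
      - {center: 2880, amplitude: 0.3}
  palmitoleic_acid:
    bands:
      - {center: 1263, amplitude: 0.9}
      - {center: 3009, amplitude: 0.6}
    filler:
      - {center: 2855, amplitude: 0.5}
      - {center: 1455, amplitude: 0.3}
  cholesterol:
    bands:
      - {center: 1083, amplitude: 1.0}
    filler:
      - {center: 700, amplitude: 0.4}
      - {center: 2868, amplitude: 0.35}
  phenylalanine:
    bands:
      - {center: 1006, amplitude: 1.0}
    filler:
      - {center: 622, amplitude: 0.3}
      - {center: 1032, amplitude: 0.4}
      - {center: 1585, amplitude: 0.2}
  lanosterol:
    bands:
      - {center: 930, amplitude: 0.7}
      - {center: 943, amplitude: 0.8}
      - {center: 1643, amplitude: 1.0}
    filler:
      - {center: 2870, amplitude: 0.3}
  squalene:
    bands:
      - {center: 1379, amplitude: 0.9}
      - {center: 1666, amplitude: 1.0}
    filler:
      - {center: 1200, amplitude: 0.2}
      - {center: 2965, amplitude: 0.3}
  glycogen:
    bands:
      - {center: 484, amplitude: 1.0}
    filler:
      - {center: 860, amplitude: 0.35}
      - {center: 1460, amplitude: 0.3}
      - {center: 2910, amplitude: 0.25}
  nadh:
    bands:
      - {center: 1114, amplitude: 1.0}
    filler:
      - {center: 760, amplitude: 0.3}
      - {center: 1690, amplitude: 0.2}
  glucose:
    bands:
      - {center: 1127, amplitude: 1.0}
    filler:
      - {center: 840, amplitude: 0.3}
      - {center: 1365, amplitude: 0.25}
      - {center: 2885, amplitude: 0.3}
  tryptophan:
    bands:
      - {center: 1557, amplitude: 1.0}
    filler:
      - {center: 758, amplitude: 0.35}
      - {center: 880, amplitude: 0.25}
  threonine:
    bands:
      - {center: 1341, amplitude: 1.0}
    filler:
      - {center: 560, amplitude: 0.2}
      - {center: 872, amplitude: 0.2}
      - {center: 2940, amplitude: 0.25}
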