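# Pure-component band libraries for the synthetic pet-food adulteration study.
# Peak positions follow the assigned FT-IR bands of each component; widths and
# amplitudes are structural choices (broad N-H/O-H envelopes, sharp triazine
# ring modes) — absolute absorbances are not calibrated to any instrument.

matrix:
  # pet-food matrix: protein amide A/I/II + lipid C-H stretches
  - {center: 3288, fwhm: 220, amplitude: 0.55, shape: gaussian}   # amide A (N-H/O-H)
  - {center: 2921, fwhm: 35,  amplitude: 0.45, shape: gaussian}   # lipid CH2 asym
  - {center: 2852, fwhm: 30,  amplitude: 0.28, shape: gaussian}   # lipid CH2 sym
  - {center: 1643, fwhm: 60,  amplitude: 0.90, shape: gaussian}   # amide I
  - {center: 1538, fwhm: 55,  amplitude: 0.60, shape: gaussian}   # amide II

melamine:
  # broad -NH2 stretching envelope 3000-3500
  - {center: 3420, fwhm: 160, amplitude: 0.50, shape: gaussian}
  - {center: 3130, fwhm: 180, amplitude: 0.45, shape: gaussian}
  # triazine ring / C=N
  - {center: 1643, fwhm: 45,  amplitude: 0.80, shape: gaussian}
  # C-N stretching region 1433-1533
  - {center: 1530, fwhm: 40,  amplitude: 0.65, shape: gaussian}
  - {center: 1450, fwhm: 35,  amplitude: 0.70, shape: gaussian}
  # sharp ring modes (exclusive, no matrix overlap)
  - {center: 1022, fwhm: 18,  amplitude: 0.55, shape: lorentzian}
  - {center: 810,  fwhm: 14,  amplitude: 0.60, shape: lorentzian}

cyanuric_acid:
  # free and H-bonded N-H stretches
  - {center: 3440, fwhm: 120, amplitude: 0.35, shape: gaussian}
  - {center: 3210, fwhm: 140, amplitude: 0.45, shape: gaussian}
  # amido N-H region 2807-2907
  - {center: 2860, fwhm: 90,  amplitude: 0.30, shape: gaussian}
  # carbonyl stretches (strong, sharp)
  - {center: 1777, fwhm: 22,  amplitude: 0.70, shape: lorentzian}
  - {center: 1752, fwhm: 20,  amplitude: 0.90, shape: lorentzian}
  # in-plane s-triazine ring stretches
  - {center: 1464, fwhm: 18,  amplitude: 0.55, shape: gaussian}
  - {center: 1418, fwhm: 16,  amplitude: 0.60, shape: gaussian}
  - {center: 1400, fwhm: 16,  amplitude: 0.50, shape: gaussian}
  # out-of-plane ring bending
  - {center: 778,  fwhm: 12,  amplitude: 0.55, shape: lorentzian}
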