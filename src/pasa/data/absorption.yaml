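# Parametric (Gaussian-mixture) NIR-II absorption curves for the three
# biomacromolecules tracked by the pipeline. Each curve is
#   mu(lambda) = offset + sum_k amplitude_k * exp(-(lambda - center_k)^2 / (2 width_k^2))
# and is normalized to unit maximum on the 1200-1700 nm grid before use.
# The shapes are coarse approximations of published NIR-II spectra: water
# peaks near 1450 nm, lipid rises steeply toward its 1720-1730 nm band (with
# a secondary 1210 nm bump), and collagen shows broad absorption with local
# maxima near 1350 nm and 1590 nm. They serve as internally consistent
# ground truth for the synthetic generator, not as literature-exact tables.
collagen:
  offset: 0.02
  components:
    - {center: 1350.0, width: 70.0, amplitude: 0.5}
    - {center: 1400.0, width: 200.0, amplitude: 0.3}
    - {center: 1590.0, width: 32.0, amplitude: 1.0}
water:
  offset: 0.01
  components:
    - {center: 1450.0, width: 42.0, amplitude: 1.0}
    - {center: 1790.0, width: 110.0, amplitude: 0.25}
lipid:
  offset: 0.01
  components:
    - {center: 1210.0, width: 30.0, amplitude: 0.35}
    - {center: 1720.0, width: 55.0, amplitude: 1.6}
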