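# Instrument presets for the scan configurations used in multi-scale cochlea
# imaging.  Lab micro-CT entries (mu-CT*) carry full source/detector distances
# and every derived quantity (M, dx_eff, z_eff, F) follows from them.
# Synchrotron entries whose published source distances are in ambiguous units
# store the published effective pixel size and Fresnel number directly and are
# marked verified: false; their derived geometry is not reconstructable from
# this file alone.
#
# dx_um is the physical detector pitch at the detector plane, after any
# optical (lens) magnification of the scintillator image.

instruments:
  # --- synchrotron configurations -----------------------------------------
  SR-CB3:            # nano-imaging cone beam, waveguide/KB optics, 4 defocus planes
    energy_keV: 17.1
    dx_um: 10.0
    binning: 3
    beam_type: cone
    n_distances: 4
    phase_method: ctf_multi_cg
    dx_eff_um: 0.05
    fresnel: 4.2e-3
    verified: false
  SR-CB1:            # waveguide cone beam
    energy_keV: 8.0
    dx_um: 6.5
    binning: 1
    beam_type: cone
    phase_method: ctf_single
    dx_eff_um: 0.125
    fresnel: 3.6e-3
    verified: false
  SR-PB:             # parallel undulator beam, 10x lens -> 0.65 um pixels
    energy_keV: 13.8
    dx_um: 0.65
    binning: 1
    beam_type: parallel
    phase_method: ctf_single
    dx_eff_um: 0.65
    fresnel: 1.8e-3
    verified: false
  SR-CB2:            # enlarged KB beam, improvised cone stage, PCA flats
    energy_keV: 13.8
    dx_um: 3.25
    binning: 1
    beam_type: cone
    phase_method: ctf_single
    dx_eff_um: 3.05
    fresnel: 0.3240
    verified: false
  SR-PB2:            # wiggler white beam, effective peak energy 50 keV
    energy_keV: 50.0
    dx_um: 3.25
    binning: 1
    beam_type: parallel
    phase_method: gpm
    dx_eff_um: 3.58
    fresnel: 0.5169
    verified: false

  # --- laboratory micro-CT configurations (fully derivable) ---------------
  muCT2-overview:      # whole-head scan, fixed-target tube, effective 80 keV
    energy_keV: 80.0
    dx_um: 127.0
    binning: 1
    beam_type: cone
    z01_mm: 64.96
    z02_mm: 312.93
    phase_method: null
  muCT2-ROI:
    energy_keV: 80.0
    dx_um: 127.0
    binning: 1
    beam_type: cone
    z01_mm: 64.96
    z02_mm: 632.94
    phase_method: null
  muCT2-nanofocus:     # nanofocus source, CCD, 2x2 binning
    energy_keV: 53.0
    dx_um: 9.0
    binning: 2
    beam_type: cone
    z01_mm: 3.17
    z02_mm: 128.37
    phase_method: null
  muCT1-overview:      # liquid-metal jet, Ga K-alpha 9.25 keV, direct contrast
    energy_keV: 9.25
    dx_um: 75.0
    binning: 1
    beam_type: cone
    z01_mm: 100.0
    z02_mm: 1804.0
    phase_method: bac
  muCT1-temporal-bone:
    energy_keV: 9.25
    dx_um: 75.0
    binning: 1
    beam_type: cone
    z01_mm: 230.0
    z02_mm: 1054.0
    phase_method: bac
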