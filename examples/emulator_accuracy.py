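"""Grade the EIA-component emulator circuits against the reference spectra.

Assembles, for each age group, the recurrent ladder built from standard
(E24/E96) resistors and the packaged 13-branch Valsa CPE networks, and
compares its spectrum with the Cole reconstruction: component-wise relative
errors plus the MAE/RMSE/R2/NSE/WIA/LCE panel.  Sub-2 % worst-case errors
mean the solderable circuit is a faithful stand-in for the fractional-order
model.
"""

from dentimp import (
    DEFAULT_GRID,
    emulated_impedance,
    fit_metrics,
    phase_error_stats,
    reconstruct_reference,
    reference_emulated_model,
    relative_error_stats,
)

for group in ("young", "old"):
    ref = reconstruct_reference(group)
    test = emulated_impedance(reference_emulated_model(group), DEFAULT_GRID)
    re_err = relative_error_stats(ref, test, "re")
    im_err = relative_error_stats(ref, test, "neg_imag")
    mag_err = relative_error_stats(ref, test, "magnitude")
    ph_err = phase_error_stats(ref, test)
    panel = fit_metrics(ref, test)
    print(f"\n{group} group, EIA-component circuit vs Cole reconstruction")
    print(f"  |Re(Z)| rel. error  max {re_err.max:.3f} %  mean {re_err.mean:.3f} %")
    print(f"  |-Im(Z)| rel. error max {im_err.max:.3f} %  mean {im_err.mean:.3f} %")
    print(f"  |Z| rel. error      max {mag_err.max:.3f} %   phase max {ph_err.max:.3f} deg")
    print(f"  MAE_R {panel.real.mae:.3f} ohm  RMSE_R {panel.real.rmse:.3f} ohm  "
          f"R2_R {panel.real.r2:.5f}  NSE_R {panel.real.nse:.5f}")
    print(f"  MAE_X {panel.imag.mae:.3f} ohm  RMSE_X {panel.imag.rmse:.3f} ohm  "
          f"WIA_X {panel.imag.wia:.5f}  LCE_X {panel.imag.lce:.5f}")
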