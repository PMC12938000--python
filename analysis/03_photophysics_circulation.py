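"""Photophysics and circulation metrics on synthetic spectra and decay
traces.

Reproduces the arithmetic behind the probe-characterisation numbers: the
Stokes shifts of the ICG-like (796 -> 854 nm) and long-Stokes-shift AIE
probe (731 -> 1081 nm) spectra, the SBR fold change between the two
imaging windows, the hemolysis formula, and a simulation study of the
mono-exponential circulation fit (t1/2 = 45 h recovered under 5%
multiplicative noise).
"""

import json
from pathlib import Path

import numpy as np

from nir2a import metrics as am

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def gaussian_spectrum(peak_nm, lo, hi, width=35.0):
    w = np.linspace(lo, hi, 600)
    return am.SpectrumRecord(w, np.exp(-(w - peak_nm) ** 2 /
                                       (2 * width ** 2)))


def main():
    RESULTS.mkdir(exist_ok=True)
    icg = am.stokes_shift(gaussian_spectrum(796, 600, 1000),
                          gaussian_spectrum(854, 650, 1100))
    tcp = am.stokes_shift(gaussian_spectrum(731, 550, 950),
                          gaussian_spectrum(1081, 850, 1400))
    fold = am.fold_change(3.32, 1.26)

    rng = np.random.default_rng(SEED)
    t = np.linspace(0, 120, 9)
    hits, estimates = 0, []
    for _ in range(100):
        v = am.mono_exponential(t, 1.0, 45.0) * \
            (1 + 0.05 * rng.standard_normal(t.size))
        fit = am.fit_halflife(am.DecaySeries(t, np.abs(v)))
        estimates.append(fit.halflife_h)
        hits += abs(fit.halflife_h - 45.0) / 45.0 <= 0.10

    out = {
        "stokes_shift_icg_nm": float(icg),
        "stokes_shift_tcp_nm": float(tcp),
        "sbr_fold_change_tcp_over_icg": round(fold, 2),
        "hemolysis_example_pct": am.hemolysis_percent(0.30, 0.10, 0.90),
        "halflife_recovery_within_10pct": hits,
        "halflife_median_estimate_h": float(np.median(estimates)),
    }
    (RESULTS / "photophysics.json").write_text(json.dumps(out, indent=1))
    print(f"Stokes shift: ICG-like {float(icg):.0f} nm, "
          f"AIE probe {float(tcp):.0f} nm")
    print(f"vessel SBR fold change (3.32 / 1.26): {fold:.2f}")
    print(f"half-life recovery: {hits}/100 replicates within 10% "
          f"(median estimate {np.median(estimates):.1f} h)")
    print(f"-> {RESULTS / 'photophysics.json'}")


if __name__ == "__main__":
    main()
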