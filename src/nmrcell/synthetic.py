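"""Synthetic calibration series for fit-recovery studies.

Generates noisy (x, y) tables from a linear model — the in-silico
counterpart of the NaCl-susceptibility titration (slope 0.2 ppm/M,
intercept −9.01 ppm, five concentrations 0–2 M) and the cobalt(II)
resin-doping series (+117 Hz undoped to −80 Hz at 5 mM). Every series is
seeded and carries a provenance header so fixture CSVs are reproducible
byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .susceptometry import LinearCalibration

__all__ = ["generate_synthetic_series", "SALT_XS_M", "DOPING_XS_MM",
           "salt_model", "doping_model"]

#: NaCl concentrations of the titration, mol/L.
SALT_XS_M = (0.0, 0.5, 1.0, 1.5, 2.0)

#: Cobalt(II) doping levels of the resin series, mM.
DOPING_XS_MM = (0.0, 2.0, 5.0)


def salt_model() -> LinearCalibration:
    """χ(D2O) vs [NaCl]: 0.2 ppm/M, intercept −9.01 ppm."""
    from .constants import CHI_D2O_PPM, NACL_SLOPE_PPM_PER_M
    return LinearCalibration(slope=NACL_SLOPE_PPM_PER_M, intercept=CHI_D2O_PPM)


def doping_model() -> LinearCalibration:
    """Interface shift (Hz) vs cobalt(II) doping (mM), through the
    measured endpoints (0 mM, +117 Hz) and (5 mM, −80 Hz)."""
    slope = (-80.0 - 117.0) / 5.0
    return LinearCalibration(slope=slope, intercept=117.0)


def generate_synthetic_series(model: LinearCalibration, xs, noise_sd: float,
                              seed: int, path: str | Path | None = None,
                              x_name: str = "x", y_name: str = "y") -> pd.DataFrame:
    """Noisy series y = model(x) + N(0, noise_sd), reproducible by seed.

    When ``path`` is given, writes a CSV whose '#' header records the
    model, seed and noise level.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    xs = np.asarray(xs, dtype=np.float64)
    rng = np.random.default_rng(seed)
    ys = model.predict(xs) + rng.normal(0.0, noise_sd, size=xs.shape)
    frame = pd.DataFrame({x_name: xs, y_name: ys})
    if path is not None:
        path = Path(path)
        header = (f"# synthetic linear series: slope={model.slope!r} "
                  f"intercept={model.intercept!r}\n"
                  f"# noise_sd={noise_sd!r} seed={seed}\n")
        with open(path, "w", newline="") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False, float_format="%.10g",
                         lineterminator="\n")
    return frame
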