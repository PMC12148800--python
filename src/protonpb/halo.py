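"""Nuclear-halo parameterization for the double-Gaussian lateral kernel.

Protons undergoing nonelastic nuclear interactions deposit a broad,
low-amplitude lateral dose component (the "nuclear halo") that a single
Gaussian cannot capture.  The engine models it as a second, wider Gaussian
carrying a fraction u_n of the local dose, with width sigma_n, both functions
of the beam range R80 and the water-equivalent depth z_w.

The default parameterization packaged here is a smooth empirical form with
the features reported for scanned proton beams: the halo fraction grows with
beam range (more material for nuclear interactions) and builds up with depth,
reaching roughly 10-20 % near the Bragg peak for high energies; the halo
width grows with depth to roughly 5 % of the range.  The model is pluggable:
any pair of callables (r80_mm, zw_mm) -> value satisfying 0 <= u_n < 1 and
sigma_n > 0 can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

HaloFn = Callable[[np.ndarray | float, np.ndarray | float], np.ndarray | float]


@dataclass
class HaloModel:
    """Halo fraction u_n(R80, z_w) and halo sigma sigma_n(R80, z_w).

    Default constants (see module docstring):

    * ``u_amp``, ``u_range_mm``: the asymptotic halo fraction at full depth is
      ``u_amp * (1 - exp(-R80 / u_range_mm))`` — about 0.03 at R80 = 40 mm
      rising to about 0.18 at R80 = 335 mm.
    * ``u_depth_exp``: depth build-up shape, u_n proportional to
      (z_w / R80) ** u_depth_exp (non-decreasing up to R80, flat beyond).
    * ``sn_base_mm``, ``sn_amp``, ``sn_depth_exp``: halo width
      ``sn_base_mm + sn_amp * R80 * (z_w / R80) ** sn_depth_exp``.
    """

    u_amp: float = 0.29
    u_range_mm: float = 350.0
    u_depth_exp: float = 0.6
    sn_base_mm: float = 2.0
    sn_amp: float = 0.045
    sn_depth_exp: float = 0.8
    u_n_fn: HaloFn | None = None
    sigma_n_fn: HaloFn | None = None

    def u_n(self, r80_mm, zw_mm):
        """Nuclear halo fraction; 0 <= u_n < 1."""
        if self.u_n_fn is not None:
            return self.u_n_fn(r80_mm, zw_mm)
        r80 = np.asarray(r80_mm, dtype=np.float64)
        t = np.clip(np.asarray(zw_mm, dtype=np.float64) / r80, 0.0, 1.0)
        u = self.u_amp * (1.0 - np.exp(-r80 / self.u_range_mm)) * t**self.u_depth_exp
        return u if u.ndim else float(u)

    def sigma_n(self, r80_mm, zw_mm):
        """Nuclear halo sigma in mm; > 0 and finite."""
        if self.sigma_n_fn is not None:
            return self.sigma_n_fn(r80_mm, zw_mm)
        r80 = np.asarray(r80_mm, dtype=np.float64)
        t = np.clip(np.asarray(zw_mm, dtype=np.float64) / r80, 0.0, 1.0)
        s = self.sn_base_mm + self.sn_amp * r80 * t**self.sn_depth_exp
        return s if s.ndim else float(s)
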