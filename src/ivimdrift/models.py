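"""Closed-form IVIM signal representations.

b-values are passed in s/mm² and converted internally (×1e-3) to ms/µm² so
that b·D is dimensionless with D in µm²/ms; the flow-encoding factor c is
in s/mm so that c²·v_d² is dimensionless with v_d in mm/s.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "B_TO_MS_PER_UM2",
    "BLOOD_DIFFUSIVITY",
    "signal_monoexp",
    "signal_diffusive",
    "signal_ballistic",
]

B_TO_MS_PER_UM2 = 1e-3

#: Fixed intrinsic diffusion coefficient of blood (µm²/ms) for the ballistic fit.
BLOOD_DIFFUSIVITY = 1.75


def signal_monoexp(b, A, D):
    """Monoexponential representation S(b) = A·exp(-b·D)."""
    return A * np.exp(-np.asarray(b) * B_TO_MS_PER_UM2 * D)


def signal_diffusive(b, S0, f, D, Dstar):
    """Biexponential diffusive-regime representation
    S(b) = S0·((1-f)·exp(-b·D) + f·exp(-b·D*))."""
    bb = np.asarray(b) * B_TO_MS_PER_UM2
    return S0 * ((1.0 - f) * np.exp(-bb * D) + f * np.exp(-bb * Dstar))


def signal_ballistic(b, c, S0, f, D, v_d, D_b=BLOOD_DIFFUSIVITY):
    """Ballistic-regime representation
    S(b, c) = S0·((1-f)·exp(-b·D) + f·exp(-b·D_b)·exp(-c²·v_d²))."""
    bb = np.asarray(b) * B_TO_MS_PER_UM2
    c = np.asarray(c, dtype=float)
    return S0 * (
        (1.0 - f) * np.exp(-bb * D)
        + f * np.exp(-bb * D_b) * np.exp(-(c ** 2) * (v_d ** 2))
    )
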