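"""Cone-isolating (silent-substitution) stimulus computation.

A display modulation isolates one cone class when the change in the other
two classes' excitations is zero. Given the monitor's R, G, B spectral
power distributions and the L, M, S cone spectral sensitivities, the 3x3
primary-to-cone matrix E (rows = cone classes, columns = primaries at unit
drive)

    E[i, j] = sum_lambda  fundamental_i(lambda) * SPD_j(lambda) * dlambda

maps RGB drives to cone excitations, and the RGB direction producing a
desired cone-contrast direction w around a background b solves

    E . dRGB = w * (E . b)     (elementwise product on the right),

scaled to the largest amplitude that stays inside the display gamut.

Cone fundamentals are built from the Govardovsky A1 visual-pigment
absorbance template (alpha + beta band) at peak wavelengths 558 (L),
530 (M), 420 (S) nm, corrected for photopigment self-screening with axial
absorbance D = 0.15 (sensitivity proportional to 1 - 10^(-D a(lambda)))
and optionally for lens absorption. The template family and the lens
density spectrum are pluggable; the built-in lens curve is a smooth
synthetic short-wavelength-attenuating template (see
:func:`synthetic_lens_density`), not a measured standard. No macular
pigment correction is applied (receptive fields in the emulated paradigm
sit outside the macular pigment's central field).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

DEFAULT_GRID = np.arange(380.0, 781.0, 1.0)  # nm
DEFAULT_PEAKS = (558.0, 530.0, 420.0)        # L, M, S lambda_max
AXES = ("L+M", "L-M", "S")


def govardovsky_a1_template(wavelength: np.ndarray, lambda_max: float) -> np.ndarray:
    """Peak-normalized A1 visual-pigment absorbance template.

    Alpha band: S(x) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)
    with x = lambda_max / lambda; beta band: Gaussian whose position and
    width scale with lambda_max.
    """
    lam = np.asarray(wavelength, dtype=float)
    x = lambda_max / lam
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x))
                   + np.exp(C * (c - x)) + D)
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - lam_beta) / b_beta) ** 2))
    t = alpha + beta
    return t / t.max()


def synthetic_lens_density(wavelength: np.ndarray) -> np.ndarray:
    """Smooth synthetic lens optical-density curve (not a measured standard).

    Captures the qualitative behaviour of the young primate lens — strong
    short-wavelength attenuation falling off rapidly above ~450 nm — with a
    single exponential in wavelength. Swap in a measured density spectrum
    via the ``lens_density`` hook of :func:`cone_fundamentals` for
    colorimetric work.
    """
    lam = np.asarray(wavelength, dtype=float)
    return 1.2 * np.exp(-(lam - 380.0) / 45.0)


@dataclass
class ConeFundamentals:
    wavelength: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    axial_absorbance: float
    lens_applied: bool

    def as_matrix(self) -> np.ndarray:
        return np.vstack([self.L, self.M, self.S])


def cone_fundamentals(lambda_max: tuple = DEFAULT_PEAKS,
                      axial_absorbance: float = 0.15,
                      lens_on: bool = True,
                      wavelength: np.ndarray = DEFAULT_GRID,
                      template: Callable = govardovsky_a1_template,
                      lens_density: Callable = synthetic_lens_density
                      ) -> ConeFundamentals:
    """L, M, S spectral sensitivities with self-screening and lens correction.

    Self-screening broadens the absorbance template: sensitivity is
    proportional to 1 - 10^(-D a(lambda)) with axial absorbance D. Curves
    are peak-normalized after all corrections.
    """
    lam = np.asarray(wavelength, dtype=float)
    if not all(380.0 <= p <= 650.0 for p in lambda_max):
        raise ValueError("lambda_max values must lie within 380-650 nm")
    lens_t = 10.0 ** (-lens_density(lam)) if lens_on else np.ones_like(lam)
    curves = []
    for peak in lambda_max:
        a = template(lam, peak)
        if axial_absorbance > 0:
            sens = 1.0 - 10.0 ** (-axial_absorbance * a)
        else:
            sens = a.copy()
        sens = sens * lens_t
        curves.append(sens / sens.max())
    L, M, S = curves
    return ConeFundamentals(lam, L, M, S, axial_absorbance, lens_on)


@dataclass
class PrimaryToConeMatrix:
    matrix: np.ndarray            # 3x3: rows L, M, S; columns R, G, B
    condition_number: float

    @property
    def singular(self) -> bool:
        return not np.isfinite(self.condition_number) or self.condition_number > 1e12


def read_spd(path) -> pd.DataFrame:
    """Read spd.csv with columns wavelength_nm, R, G, B."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "R", "G", "B"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def primary_to_cone(spd: pd.DataFrame, fundamentals: ConeFundamentals
                    ) -> PrimaryToConeMatrix:
    """Integrate each primary's SPD against each cone fundamental.

    The SPD is linearly resampled onto the fundamentals' grid; trapezoidal
    integration on a 1 nm grid.
    """
    lam = fundamentals.wavelength
    spd_lam = spd["wavelength_nm"].to_numpy(dtype=float)
    if spd_lam.max() < lam.min() or spd_lam.min() > lam.max():
        raise ValueError("SPD and fundamentals wavelength ranges do not overlap")
    F = fundamentals.as_matrix()
    E = np.empty((3, 3))
    for j, ch in enumerate(("R", "G", "B")):
        power = np.interp(lam, spd_lam, spd[ch].to_numpy(dtype=float),
                          left=0.0, right=0.0)
        E[:, j] = np.trapezoid(F * power, lam, axis=1)
    cond = float(np.linalg.cond(E))
    return PrimaryToConeMatrix(matrix=E, condition_number=cond)


#: Weber cone-contrast directions for the three isolating axes.
AXIS_DIRECTIONS = {
    "L+M": np.array([1.0, 1.0, 0.0]),
    "L-M": np.array([1.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class IsolatingModulation:
    axis: str
    delta_rgb: np.ndarray          # RGB modulation at maximum in-gamut amplitude
    cone_contrasts: np.ndarray     # achieved Weber contrasts (L, M, S)
    condition_number: float


def isolating_modulation(p2c: PrimaryToConeMatrix, axis: str,
                         background: np.ndarray | tuple = (0.5, 0.5, 0.5)
                         ) -> IsolatingModulation:
    """RGB modulation isolating one DKL axis around a background drive.

    Solves E dRGB = w * E b for the Weber direction w of the axis, then
    scales dRGB to the largest amplitude keeping b +/- dRGB inside the
    [0, 1] gamut. The silenced cones' achieved contrast is zero to
    numerical precision by construction.
    """
    if axis not in AXIS_DIRECTIONS:
        raise ValueError(f"axis must be one of {AXES}")
    E = p2c.matrix
    if p2c.singular:
        raise np.linalg.LinAlgError(
            f"primary-to-cone matrix is singular (cond={p2c.condition_number:.3g})")
    b = np.asarray(background, dtype=float)
    if np.any(b <= 0) or np.any(b >= 1):
        raise ValueError("background drive must lie strictly inside (0, 1)")
    e_bg = E @ b
    target = AXIS_DIRECTIONS[axis] * e_bg
    d = np.linalg.solve(E, target)
    # max s with 0 <= b +/- s*d <= 1
    with np.errstate(divide="ignore"):
        limits = np.concatenate([
            np.where(d != 0, (1.0 - b) / np.abs(d), np.inf),
            np.where(d != 0, b / np.abs(d), np.inf),
        ])
    s = float(limits.min())
    if not np.isfinite(s) or s <= 0:
        raise ValueError("zero gamut headroom around the background")
    delta = s * d
    contrasts = (E @ delta) / e_bg
    return IsolatingModulation(axis=axis, delta_rgb=delta,
                               cone_contrasts=contrasts,
                               condition_number=p2c.condition_number)


def gaussian_primary_monitor(centers=(610.0, 530.0, 450.0), width: float = 25.0,
                             wavelength: np.ndarray = DEFAULT_GRID,
                             peak_power: float = 1.0) -> pd.DataFrame:
    """Synthetic monitor with Gaussian R, G, B primaries (test fixture)."""
    lam = np.asarray(wavelength, dtype=float)
    data = {"wavelength_nm": lam}
    for ch, c in zip(("R", "G", "B"), centers):
        data[ch] = peak_power * np.exp(-0.5 * ((lam - c) / width) ** 2)
    return pd.DataFrame(data)
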