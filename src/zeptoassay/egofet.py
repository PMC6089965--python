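"""p-type electrolyte-gated FET transduction.

The sensing gate of the immunoassay couples to the transistor channel
through the electrolyte, and affinity binding changes only the gate work
function: a work-function change Δϕ (eV) appears one-to-one as a threshold
voltage shift ΔV_T (V).  A saturation square-law describes the transfer
characteristic, which makes the normalized current response to a threshold
shift available in closed form.

Sign convention: measured V_G and I_D are negative for the p-type device;
this module stores drain currents as magnitudes and gate voltages as the
measured (negative) values, and reports binding responses as positive
fractional current decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeviceParams",
    "TransferCurve",
    "GateState",
    "drain_current",
    "extract_threshold",
    "transconductance",
    "response",
    "vt_shift_to_response",
    "response_to_vt_shift",
    "workfunction_to_vt_shift",
    "ThresholdFitError",
    "SaturationError",
]

#: Default gate-voltage grid of the measurement protocol: -0.1 to -0.7 V
#: in steps of -0.01 V at fixed V_D = -0.4 V.
DEFAULT_VG_GRID = np.round(np.arange(-0.10, -0.7001, -0.01), 10)
DEFAULT_VD = -0.4


class ThresholdFitError(RuntimeError):
    """Raised when a transfer curve does not support threshold extraction."""


class SaturationError(ValueError):
    """Raised when a requested response exceeds what the overdrive allows."""


@dataclass(frozen=True)
class DeviceParams:
    """Geometry and gain of the transistor.

    Attributes
    ----------
    width : float
        Channel width W in µm (perimeter of the interdigitated fingers).
    length : float
        Channel length L in µm.
    mobility_capacitance : float
        Lumped µC_i product in A/V² per square.
    vt : float
        Threshold voltage in V; negative for the p-type enhancement device.
    """

    width: float = 1280.0
    length: float = 5.0
    mobility_capacitance: float = 1e-5
    vt: float = -0.3

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("width and length must be > 0")
        if self.mobility_capacitance <= 0:
            raise ValueError("mobility_capacitance must be > 0")


@dataclass(frozen=True)
class TransferCurve:
    """(V_G, |I_D|) samples at fixed drain voltage."""

    vg: np.ndarray
    id: np.ndarray
    vd: float = DEFAULT_VD

    def __post_init__(self) -> None:
        vg = np.asarray(self.vg, dtype=float)
        cur = np.asarray(self.id, dtype=float)
        if vg.shape != cur.shape or vg.ndim != 1:
            raise ValueError("vg and id must be 1-D arrays of equal length")
        d = np.diff(vg)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("vg grid must be strictly monotone")
        if np.any(cur < 0):
            raise ValueError("id stores current magnitudes and must be >= 0")
        object.__setattr__(self, "vg", vg)
        object.__setattr__(self, "id", cur)


@dataclass(frozen=True)
class GateState:
    """Cumulative gate work-function shift and the V_T shift it causes."""

    workfunction_shift: float  # eV, negative = lowered work function
    vt_shift: float  # V

    def __post_init__(self) -> None:
        if self.workfunction_shift * self.vt_shift < 0:
            raise ValueError("workfunction_shift and vt_shift must share a sign")


def overdrive(vg, vt: float):
    """Gate overdrive |V_G| - |V_T|, clipped at zero below threshold."""
    return np.clip(np.abs(vg) - abs(vt), 0.0, None)


def drain_current(vg, params: DeviceParams):
    """Saturation square-law drain current magnitude.

    I_D = (W / 2L) · µC_i · u² with u the overdrive; zero below threshold.
    Scalar or array ``vg``.
    """
    u = overdrive(vg, params.vt)
    scale = params.width / (2.0 * params.length) * params.mobility_capacitance
    out = scale * u**2
    return float(out) if np.isscalar(vg) else out


def transfer_curve(params: DeviceParams, vg=None, vd: float = DEFAULT_VD) -> TransferCurve:
    """Noiseless square-law transfer curve on a gate-voltage grid."""
    if vg is None:
        vg = DEFAULT_VG_GRID
    vg = np.asarray(vg, dtype=float)
    return TransferCurve(vg=vg, id=drain_current(vg, params), vd=vd)


def extract_threshold(curve: TransferCurve, min_points: int = 10) -> float:
    """Threshold voltage from a linear fit of sqrt(I_D) vs V_G.

    In saturation sqrt(I_D) is linear in V_G beyond threshold; the fit is
    restricted to the top 50% of the observed overdrive range (where the
    square law is cleanest) and the extrapolated root of the fit line is
    returned as V_T.  On noiseless square-law input this recovers the
    generating threshold to machine precision.

    Raises
    ------
    ThresholdFitError
        If fewer than ``min_points`` samples fall in the fit window, or the
        fitted slope has the wrong sign (non-monotone sqrt(I_D) region).
    """
    y = np.sqrt(curve.id)
    top = y >= 0.5 * y.max()
    usable = top & (curve.id > 0)
    if usable.sum() < min_points:
        raise ThresholdFitError(
            f"only {int(usable.sum())} points in the fit window, need {min_points}"
        )
    slope, intercept = np.polyfit(curve.vg[usable], y[usable], 1)
    if slope == 0:
        raise ThresholdFitError("flat sqrt(I_D) region, cannot extrapolate a root")
    # p-type: sqrt(I) grows towards more negative vg, slope < 0
    if slope > 0:
        raise ThresholdFitError("sqrt(I_D) increases with V_G: not a p-type branch")
    return float(-intercept / slope)


def transconductance(curve: TransferCurve) -> tuple[float, float]:
    """Locate the maximum-transconductance bias point.

    Central finite differences of I_D on the V_G grid; returns the grid
    voltage where |dI_D/dV_G| peaks and the magnitude of the derivative
    there.  Dose-response read-out is performed at this bias.
    """
    if len(curve.vg) < 3:
        raise ValueError("need at least 3 points for finite differences")
    gm = np.gradient(curve.id, curve.vg)
    i = int(np.argmax(np.abs(gm)))
    return float(curve.vg[i]), float(abs(gm[i]))


def response(i: float, i0: float) -> float:
    """Normalized current response ΔI/I₀ = (I₀ - I)/I₀ at fixed bias.

    Binding lowers |I_D|, so the response is reported as a positive
    fraction.  ``i > i0`` (a current increase) is physically unexpected:
    a warning is emitted and the signed (negative) value returned.
    """
    if i0 <= 0:
        raise ValueError("baseline current must be > 0")
    if i < 0:
        raise ValueError("current magnitudes must be >= 0")
    r = (i0 - i) / i0
    if r < 0:
        warnings.warn(
            f"negative response {r:.3g}: current increased above baseline",
            stacklevel=2,
        )
    return r


def vt_shift_to_response(dvt: float, overdrive_v: float) -> float:
    """Closed-form square-law response to a threshold shift.

    At fixed bias with baseline overdrive u, a shift ΔV_T towards more
    negative threshold reduces the overdrive to u - |ΔV_T|, hence
    ΔI/I₀ = 1 - (1 - |ΔV_T|/u)².  Strictly increasing in |ΔV_T|.
    """
    if overdrive_v <= 0:
        raise ValueError("overdrive must be > 0")
    if abs(dvt) >= overdrive_v:
        raise SaturationError(
            f"|dvt|={abs(dvt):.3g} V >= overdrive {overdrive_v:.3g} V: channel pinched off"
        )
    return 1.0 - (1.0 - abs(dvt) / overdrive_v) ** 2


def response_to_vt_shift(r: float, overdrive_v: float) -> float:
    """Inverse of :func:`vt_shift_to_response`: |ΔV_T| = u·(1 - sqrt(1 - r))."""
    if overdrive_v <= 0:
        raise ValueError("overdrive must be > 0")
    if not 0 <= r < 1:
        raise ValueError("response must lie in [0, 1)")
    return overdrive_v * (1.0 - np.sqrt(1.0 - r))


def workfunction_to_vt_shift(dphi_ev: float) -> float:
    """Gate work-function change (eV) to threshold-voltage shift (V).

    Unit-charge conversion: ΔV_T [V] = Δϕ [eV], sign preserved — lowering
    the gate work function moves V_T towards more negative values on the
    p-type device.
    """
    return float(dphi_ev)
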