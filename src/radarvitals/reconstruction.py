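"""From raw I/Q samples to calibrated relative displacement.

An ideal interferometric radar maps target motion onto a circle in the
I/Q plane: ``Z(t) = A exp(j φ(t))`` with ``φ(t) = 4π d(t) / λ``.
Antenna cross-talk and DC offsets translate the circle, quadrature gain
imbalance and rotation deform it into an ellipse.  Reconstruction
therefore proceeds in four steps:

1. fit an ellipse to the measured samples (direct algebraic least
   squares with the ellipse-specific constraint),
2. normalize the samples onto the unit circle with the inverse affine
   map,
3. take the four-quadrant argument and unwrap it,
4. scale phase to displacement, ``d(t) = (λ/2) φ(t) / (2π)``, anchored
   so that the first sample reads zero (the radar measures relative
   distance only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import DisplacementTrace, PhaseTrace, QuadratureRecord

__all__ = [
    "EllipseParams",
    "EllipseFitError",
    "fit_ellipse",
    "normalize_iq",
    "demodulate_phase",
    "phase_to_displacement",
    "reconstruct",
]


class EllipseFitError(ValueError):
    """Raised when the conic fit does not yield a valid ellipse."""


@dataclass
class EllipseParams:
    """Geometric parameters of a fitted I/Q ellipse.

    ``semi_axes`` is ordered (major, minor); ``rotation`` is the angle
    of the major axis, normalized to [0, π).  ``fit_residual`` is the
    RMS algebraic distance of the points under unit-norm conic
    coefficients.
    """

    center: complex
    semi_axes: tuple
    rotation: float
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        self.rotation = float(self.rotation) % np.pi


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit (numerically stable variant).

    Solves the conic ``a x² + b xy + c y² + d x + e y + f = 0`` under
    the constraint ``4ac - b² = 1``, which guarantees an ellipse and
    admits a non-iterative eigen-solution.  Requires at least six
    non-degenerate points; for a stable fit the points should span at
    least half the circle.
    """
    z = np.asarray(points, dtype=complex).ravel()
    if z.size < 6:
        raise ValueError("ellipse fit needs at least 6 points")
    x, y = z.real.copy(), z.imag.copy()
    # centre/scale for conditioning
    mx, my = x.mean(), y.mean()
    s = max(np.abs(x - mx).max(), np.abs(y - my).max())
    if s == 0:
        raise EllipseFitError("degenerate input: all points identical")
    xs, ys = (x - mx) / s, (y - my) / s

    D1 = np.column_stack([xs * xs, xs * ys, ys * ys])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    # premultiply by inv(C1) with C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(evals) & (cond > 0))[0]
    if ok.size == 0:
        raise EllipseFitError("direct fit did not produce an ellipse conic")
    a1 = np.real(evecs[:, ok[0]])
    coeffs = np.concatenate([a1, T @ a1])  # conic in scaled coordinates

    A, B, C, D, E, F = coeffs
    # undo the normalization: x = (X - mx)/s, y = (Y - my)/s
    A2, B2, C2 = A / s**2, B / s**2, C / s**2
    D2_ = -2 * A * mx / s**2 - B * my / s**2 + D / s
    E2 = -B * mx / s**2 - 2 * C * my / s**2 + E / s
    F2 = (
        A * mx**2 / s**2
        + B * mx * my / s**2
        + C * my**2 / s**2
        - D * mx / s
        - E * my / s
        + F
    )
    conic = np.array([A2, B2, C2, D2_, E2, F2])
    conic /= np.linalg.norm(conic)
    A, B, C, D, E, F = conic

    M0 = np.array([[A, B / 2.0], [B / 2.0, C]])
    try:
        center = np.linalg.solve(2.0 * M0, -np.array([D, E]))
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("singular conic matrix") from exc
    f0 = F - center @ M0 @ center
    lam, vec = np.linalg.eigh(M0)
    radii_sq = -f0 / lam
    if np.any(radii_sq <= 0):
        raise EllipseFitError("conic is not an ellipse")
    radii = np.sqrt(radii_sq)
    major = int(np.argmax(radii))
    rotation = float(np.arctan2(vec[1, major], vec[0, major])) % np.pi
    semi_axes = (float(radii[major]), float(radii[1 - major]))

    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    residual = float(np.sqrt(np.mean((design @ conic) ** 2)))
    return EllipseParams(
        center=complex(center[0], center[1]),
        semi_axes=semi_axes,
        rotation=rotation,
        fit_residual=residual,
    )


def normalize_iq(record: QuadratureRecord, ellipse: EllipseParams) -> QuadratureRecord:
    """Map samples lying on the fitted ellipse onto the unit circle.

    One invertible affine map: translate by ``-center``, rotate by
    ``-rotation``, scale each principal axis to 1, rotate back.  The
    map is recorded in the output's ``meta`` for provenance.
    """
    a, b = ellipse.semi_axes
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    rot = np.exp(-1j * ellipse.rotation)
    v = (record.iq - ellipse.center) * rot
    v = v.real / a + 1j * v.imag / b
    w = v * np.conj(rot)
    meta = dict(record.meta)
    meta["normalization"] = {
        "center": ellipse.center,
        "rotation": ellipse.rotation,
        "semi_axes": ellipse.semi_axes,
    }
    return QuadratureRecord(
        sample_rate=record.sample_rate,
        iq=w,
        wavelength=record.wavelength,
        meta=meta,
    )


def demodulate_phase(record: QuadratureRecord) -> PhaseTrace:
    """Four-quadrant arctangent demodulation with 2π unwrapping.

    The record should be normalized first (documented contract, not
    enforced): the argument of an off-centre ellipse is a distorted
    phase.  A zero-magnitude sample has an undefined argument and is
    reported by index.
    """
    mag = np.abs(record.iq)
    zeros = np.flatnonzero(mag == 0.0)
    if zeros.size:
        raise ValueError(f"zero-magnitude sample at index {int(zeros[0])}: argument undefined")
    phase = np.unwrap(np.angle(record.iq))
    return PhaseTrace(phase=phase, sample_rate=record.sample_rate)


def phase_to_displacement(phase: PhaseTrace, wavelength: float) -> DisplacementTrace:
    """Scale unwrapped phase to relative displacement in µm.

    ``d(t) = (λ/2) · φ(t) / (2π)``, reported relative to the first
    sample so that ``d(0) = 0``.  Increasing distance maps to
    increasing phase.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    d_m = (wavelength / 2.0) * (phase.phase - phase.phase[0]) / (2.0 * np.pi)
    return DisplacementTrace(
        displacement_um=d_m * 1e6,
        sample_rate=phase.sample_rate,
        wavelength_used=wavelength,
    )


def reconstruct(
    record: QuadratureRecord,
    refit_blocks: bool = False,
    block_s: float = 5.0,
    power_change_threshold: float = 0.2,
) -> DisplacementTrace:
    """Full reconstruction: fit → normalize → demodulate → displacement.

    With ``refit_blocks`` the ellipse parameters are re-estimated
    whenever the windowed mean modulus (a proxy for receive power)
    drifts by more than ``power_change_threshold`` relative to the block
    the current fit came from; off by default for reproducibility.
    """
    if not refit_blocks:
        ellipse = fit_ellipse(record.iq)
        norm = normalize_iq(record, ellipse)
        phase = demodulate_phase(norm)
        return phase_to_displacement(phase, record.wavelength)

    n_block = max(int(round(block_s * record.sample_rate)), 64)
    z = record.iq
    edges = list(range(0, z.size, n_block))
    normalized = np.empty_like(z)
    ellipse = fit_ellipse(z)
    ref_power = float(np.mean(np.abs(z[: edges[1]] if len(edges) > 1 else z)))
    fit_start = 0
    for i, start in enumerate(edges):
        stop = min(start + n_block, z.size)
        block = z[start:stop]
        power = float(np.mean(np.abs(block)))
        if abs(power - ref_power) > power_change_threshold * ref_power:
            # refit on data since the power step
            seg = z[start : min(start + 4 * n_block, z.size)]
            try:
                ellipse = fit_ellipse(seg)
                ref_power = power
                fit_start = start
            except EllipseFitError:
                pass  # keep the previous fit if the segment is degenerate
        sub = QuadratureRecord(
            sample_rate=record.sample_rate, iq=block, wavelength=record.wavelength
        )
        normalized[start:stop] = normalize_iq(sub, ellipse).iq
    whole = QuadratureRecord(
        sample_rate=record.sample_rate,
        iq=normalized,
        wavelength=record.wavelength,
        meta={"refit_blocks": True, "block_s": block_s, "last_fit_start": fit_start},
    )
    phase = demodulate_phase(whole)
    return phase_to_displacement(phase, record.wavelength)
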