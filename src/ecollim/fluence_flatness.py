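"""Sequential in-air fluence transport through the collimating chain and the
in-field flatness decision used as the optimization constraint.

The primary electron fluence is transported plane to plane along fan-line
coordinates theta = x / zeta (zeta the distance below the virtual source),
in which divergent projection is the identity.  At each collimating plane
the profile is clipped to the aperture; over each air gap it is convolved
with the Gaussian penumbra kernel of that gap.  The clip discontinuities are
blurred analytically (error-function terms), so the single-edge limit
reproduces the closed-form penumbra to machine precision; the smooth
remainder is convolved on the grid with an integrated-Gaussian kernel.

This is the Gaussian (first-moment) approximation to a full
scattering-moments transport; it is exact for a single edge by construction
and approximate for multiple collimation levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .beam_model import ElectronBeamModel, MachineGeometry, sigma_penumbra
from .trimmer_geometry import ApplicatorDesign

__all__ = ["FluenceProfile", "FlatnessReport", "transport_fluence",
           "evaluate_flatness", "diagonal_profile"]


@dataclass(frozen=True)
class FluenceProfile:
    """Relative in-air fluence vs off-axis position at one plane."""

    axis: str
    x: np.ndarray          # off-axis positions at the evaluation plane (cm)
    values: np.ndarray     # relative fluence, 1.0 on the central axis
    z_eval: float
    energy: float
    normalized: bool = True

    def at(self, x):
        return np.interp(x, self.x, self.values)


@dataclass(frozen=True)
class FlatnessReport:
    """The 2%-drop uniformity-edge rule on a major-axis profile."""

    profile: FluenceProfile
    uniformity_x: float
    value: float
    passed: bool
    margin: float          # threshold - (1 - value); >= 0 iff passed
    threshold: float = 0.02
    diagonal: dict = field(default_factory=dict, compare=False)


def _normal_cdf(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(u / np.sqrt(2.0)))


def _blur(theta: np.ndarray, f: np.ndarray, steps: list[tuple[float, float, int]],
          sigma_theta: float) -> np.ndarray:
    """Gaussian blur of f = smooth part + steps.

    ``steps`` lists (position, height, direction): direction +1 for a step
    that is ``height`` on the right of the position (0 left), -1 for the
    mirror.  Steps are convolved analytically; the smooth remainder uses a
    cell-integrated Gaussian kernel.
    """
    if sigma_theta <= 0:
        return f
    g = f.copy()
    for pos, height, direction in steps:
        # inclusive on the surviving side, matching the aperture clip
        g -= height * np.where(direction * (theta - pos) >= 0, 1.0, 0.0)
    h = theta[1] - theta[0]
    half = int(np.ceil(6.0 * sigma_theta / h)) + 1
    edges = (np.arange(-half, half + 1 + 1) - 0.5) * h
    kernel = np.diff(_normal_cdf(edges / sigma_theta))
    # edge-padded convolution (profile is constant far off axis)
    gp = np.pad(g, half + 1, mode="edge")
    out = np.convolve(gp, kernel, mode="same")[half + 1:-(half + 1)]
    for pos, height, direction in steps:
        out += height * _normal_cdf(direction * (theta - pos) / sigma_theta)
    return out


def transport_fluence(machine: MachineGeometry, beam: ElectronBeamModel,
                      design: ApplicatorDesign,
                      E: float, axis: str, z_eval: float | None = None,
                      grid_spacing: float = 0.05,
                      half_width: float | None = None) -> FluenceProfile:
    """Transport a uniform divergent fluence through jaws and trimmers.

    Returns the relative fluence profile at ``z_eval`` (default: isocenter),
    normalized to the central axis.  An empty aperture yields an all-zero,
    unnormalized profile (flagged, not an error).
    """
    if z_eval is None:
        z_eval = machine.z_isocenter
    zu, zm, zl = design.trimmer_z
    if z_eval < zl:
        raise ValueError("evaluation plane must lie at or below the last trimmer")
    zj = machine.z_jaw(axis)
    if E not in design.jaw_schedule:
        raise KeyError(f"energy {E} MeV not in the design's jaw schedule")
    planes = sorted([
        (zj, design.jaw_schedule[E][axis]["aperture"]),
        (zu, design.planes["upper"].aperture_half_width[axis]),
        (zm, design.planes["middle"].aperture_half_width[axis]),
        (zl, design.planes["lower"].aperture_half_width[axis]),
    ])
    if half_width is None:
        half_width = design.field_size / 2.0 + 10.0
    zeta_eval = machine.zeta(z_eval)
    # pad the domain so convolution boundaries stay far from the field
    margin = 6.0
    theta_max = (half_width + margin) / zeta_eval
    n = int(np.ceil(theta_max / (grid_spacing / zeta_eval)))
    theta = np.arange(-n, n + 1) * (grid_spacing / zeta_eval)
    f = np.ones_like(theta)

    for i, (z_plane, aperture) in enumerate(planes):
        edge = aperture / machine.zeta(z_plane)
        steps = []
        for sign in (+1.0, -1.0):
            pos = sign * edge
            val = float(np.interp(pos, theta, f))
            if val > 0:
                # fluence drops to zero outside the aperture
                steps.append((pos, val, -1 if sign > 0 else +1))
        f = np.where(np.abs(theta) <= edge, f, 0.0)
        z_next = planes[i + 1][0] if i + 1 < len(planes) else z_eval
        if z_next > z_plane:
            sig = sigma_penumbra(E, z_plane, z_next, machine, beam)
            f = _blur(theta, f, steps, sig / machine.zeta(z_next))
    x = theta * zeta_eval
    center = float(np.interp(0.0, theta, f))
    # an essentially closed aperture cannot be meaningfully normalized
    if center > 1e-6:
        return FluenceProfile(axis=axis, x=x, values=f / center, z_eval=z_eval,
                              energy=E, normalized=True)
    return FluenceProfile(axis=axis, x=x, values=f, z_eval=z_eval, energy=E,
                          normalized=False)
def evaluate_flatness(profile: FluenceProfile, field_size: float,
                      threshold: float = 0.02, edge_inset: float = 2.0,
                      diagonal: dict | None = None) -> FlatnessReport:
    """Apply the uniformity-edge rule: the relative fluence may drop at most
    ``threshold`` below the central axis at ``edge_inset`` cm inside the
    field edge on a major axis."""
    x_unif = field_size / 2.0 - edge_inset
    if x_unif <= 0:
        raise ValueError("field too small for the uniformity inset")
    if x_unif > profile.x.max():
        raise ValueError("profile grid does not cover the uniformity region")
    dx = np.diff(profile.x).min()
    if dx > 0.25:
        raise ValueError("profile grid too coarse to locate the uniformity edge")
    value = float(min(profile.at(x_unif), profile.at(-x_unif)))
    drop = 1.0 - value
    return FlatnessReport(profile=profile, uniformity_x=x_unif, value=value,
                          passed=bool(drop <= threshold),
                          margin=float(threshold - drop), threshold=threshold,
                          diagonal=diagonal or {})


def diagonal_profile(profile_inplane: FluenceProfile,
                     profile_crossplane: FluenceProfile) -> FluenceProfile:
    """Approximate diagonal profile as the product of the two major-axis
    profiles evaluated at r/sqrt(2) each (separable-aperture approximation)."""
    r = profile_inplane.x
    vals = profile_inplane.at(r / np.sqrt(2.0)) * profile_crossplane.at(r / np.sqrt(2.0))
    return FluenceProfile(axis="diagonal", x=r, values=vals,
                          z_eval=profile_inplane.z_eval,
                          energy=profile_inplane.energy,
                          normalized=profile_inplane.normalized
                          and profile_crossplane.normalized)
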