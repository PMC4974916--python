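"""Physical model of tag-to-tag radio propagation.

Received signal strength (RSSI, in dB) between two animal-borne dipole
tags a distance ``r`` apart is modelled as inverse-square spherical
spreading plus exponential absorption, with an additive correction for
the relative orientation of the two antennae::

    RSSI = kappa(h, z) + beta(h, z) * r - 20 log10(r) + gamma * delta(theta, phi)

``kappa`` (dB) is a received-power offset and ``beta`` (dB/m, <= 0) an
absorption coefficient, both specific to a habitat--height stratum
``(h, z)``.  ``delta`` is the pairwise dipole directivity in dB, derived
from the in-plane radiation pattern of an antenna tilted 45 degrees to
the horizontal; ``gamma`` scales it and equals 1 under the pure physical
model.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "HABITATS",
    "Height",
    "Stratum",
    "ALL_STRATA",
    "Orientation",
    "PropagationParams",
    "fold_angle",
    "in_plane_pattern",
    "directivity",
    "directivity_db",
    "mean_directivity_db",
    "expected_rssi",
    "power_ratio",
]

#: The five habitat classes of the calibration site (a New Caledonian
#: dry-forest mosaic).  Labels are short slugs; descriptive names live in
#: :mod:`proxcal.datasets`.
HABITATS: tuple[str, ...] = ("casuarina", "fig", "gallery", "paperbark", "shrubs")


class Height(str, Enum):
    """Tag height above ground: ground-foraging (0.1 m) or canopy (4 m)."""

    GROUND = "ground"
    ARBOREAL = "arboreal"

    @property
    def metres(self) -> float:
        return 0.1 if self is Height.GROUND else 4.0


@dataclass(frozen=True, order=True)
class Stratum:
    """One habitat--height combination; exactly 10 distinct strata exist."""

    habitat: str
    height: Height

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(
                f"unknown habitat {self.habitat!r}; expected one of {HABITATS}"
            )
        if not isinstance(self.height, Height):
            object.__setattr__(self, "height", Height(self.height))

    @property
    def label(self) -> str:
        return f"{self.habitat}:{self.height.value}"

    @classmethod
    def from_label(cls, label: str) -> "Stratum":
        habitat, _, height = label.partition(":")
        return cls(habitat, Height(height))


#: All 10 strata (5 habitats x 2 heights), in a fixed deterministic order.
ALL_STRATA: tuple[Stratum, ...] = tuple(
    Stratum(h, z) for h in HABITATS for z in (Height.GROUND, Height.ARBOREAL)
)


@dataclass(frozen=True)
class Orientation:
    """Relative in-plane orientation of a communicating tag pair.

    ``theta`` is the transmitter angle and ``phi`` the receiver angle
    about the line-of-sight bearing, both in degrees.  The derived angle
    ``alpha`` to the antenna axis satisfies cos(alpha) = sin(theta)/sqrt(2)
    for an antenna tilted 45 degrees to the horizontal.
    """

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and np.isfinite(self.phi)):
            raise ValueError("orientation angles must be finite")

    @property
    def alpha(self) -> float:
        """Angle (degrees) between the line of sight and the antenna axis."""
        return float(np.degrees(np.arccos(np.sin(np.radians(self.theta)) / np.sqrt(2.0))))


@dataclass(frozen=True)
class PropagationParams:
    """Path-loss parameters for one stratum.

    kappa : received-power offset (dB).
    beta  : absorption coefficient (dB per metre); must be <= 0 — radio
            power is never amplified by the medium.
    gamma : multiplier on the directivity term; 1 under the pure dipole
            model, left free when fitting to test the dipole assumption.
    """

    kappa: float
    beta: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.kappa):
            raise ValueError("kappa must be finite")
        if not (np.isfinite(self.beta) and self.beta <= 0):
            raise ValueError(f"beta must be finite and <= 0, got {self.beta}")
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValueError(f"gamma must be finite and >= 0, got {self.gamma}")


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def fold_angle(angle) -> np.ndarray | float:
    """Reduce an angle in degrees to the equivalent value in [0, 180].

    The directivity is periodic (period 360) and symmetric about 180, so
    any real angle maps to a canonical representative in [0, 180].
    """
    arr = _check_finite("angle", angle)
    folded = np.mod(arr, 360.0)
    folded = np.where(folded > 180.0, 360.0 - folded, folded)
    return float(folded) if np.isscalar(angle) or arr.ndim == 0 else folded


def in_plane_pattern(theta) -> np.ndarray | float:
    """In-plane radiation pattern I(theta) = (1 + cos^2 theta) / 2.

    This is the horizontal-plane section through the dipole "doughnut"
    for an antenna tilted 45 degrees to the horizontal.  Maximum power
    I(0) = 1 is radiated to the sides, twice the power I(90) = 1/2
    radiated to the front and back.  Returns a power fraction in [1/2, 1].
    """
    t = np.radians(_check_finite("theta", theta))
    out = 0.5 * (1.0 + np.cos(t) ** 2)
    return float(out) if out.ndim == 0 else out


def directivity(theta, phi) -> np.ndarray | float:
    """Pairwise directivity D(theta, phi) = (1 + cos^2 theta)(1 + sin^2 phi) / 4.

    The product of the transmitter's in-plane pattern and the receiver's
    pattern rotated by ``phi`` about the line-of-sight bearing.  Bounded
    in [1/4, 1]: maximum when the tags sit side by side (theta=0, phi=90),
    minimum when aligned parallel or antiparallel along the line of sight.
    """
    t = np.radians(_check_finite("theta", theta))
    p = np.radians(_check_finite("phi", phi))
    out = 0.25 * (1.0 + np.cos(t) ** 2) * (1.0 + np.sin(p) ** 2)
    return float(out) if out.ndim == 0 else out


def directivity_db(theta, phi) -> np.ndarray | float:
    """Directivity on the decibel scale, delta = 10 log10 D(theta, phi).

    Ranges over [10 log10(1/4), 0] ~= [-6.0206, 0] dB.
    """
    out = 10.0 * np.log10(directivity(theta, phi))
    return float(out) if np.ndim(out) == 0 else out


def mean_directivity_db() -> float:
    """Orientation-averaged directivity, 10 log10 E[D] = 10 log10(9/16).

    With theta and phi independently uniform, E[1 + cos^2 theta] = 3/2 and
    E[1 + sin^2 phi] = 3/2, so E[D] = 9/16 and the average orientation
    effect is 10 log10(9/16) ~= -2.50 dB.

    Note the average is taken on the power scale (mean of D, then dB).
    Averaging delta itself on the dB scale gives ~ -2.75 dB instead; the
    power-scale convention is the physically meaningful one, since powers,
    not their logarithms, add.
    """
    return float(10.0 * np.log10(9.0 / 16.0))


def expected_rssi(r, params: PropagationParams, delta=0.0) -> np.ndarray | float:
    """Deterministic RSSI (dB) at distance ``r`` metres.

    Computes ``kappa + beta * r - 20 log10(r) + gamma * delta``.  Strictly
    decreasing in ``r`` for beta <= 0, with the steepest decline at short
    range — the property that makes close encounters the best-resolved.

    Raises ``ValueError`` for r <= 0 (the spherical-spreading term is
    undefined at zero range).
    """
    rr = _check_finite("r", r)
    if np.any(rr <= 0):
        raise ValueError("distance r must be > 0")
    d = _check_finite("delta", delta)
    out = params.kappa + params.beta * rr - 20.0 * np.log10(rr) + params.gamma * d
    return float(out) if out.ndim == 0 else out


def power_ratio(r, C, beta) -> np.ndarray | float:
    """Received-to-reference power ratio Pr/P0 = C 10^(beta r / 10) / r^2.

    The linear-scale form of the path-loss law: 10 log10 of this quantity
    equals :func:`expected_rssi` with K = 10 log10 C and no directivity
    term.  Requires r > 0 and C > 0.
    """
    rr = _check_finite("r", r)
    cc = _check_finite("C", C)
    if np.any(rr <= 0):
        raise ValueError("distance r must be > 0")
    if np.any(cc <= 0):
        raise ValueError("C must be > 0")
    b = _check_finite("beta", beta)
    out = cc * 10.0 ** (b * rr / 10.0) / rr**2
    return float(out) if out.ndim == 0 else out
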