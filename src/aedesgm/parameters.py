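"""Biological and transport coefficients of the mosquito population model.

The model tracks five *Aedes aegypti* phases — eggs (E), aquatic stages (A,
larvae + pupae), reproductive females (F), wild males (M) and released
genetically modified (GM) males (G) — with densities in mosquitoes/m².
This module holds the coefficient set driving both the reaction–diffusion
system and its single-cell ODE reduction, and the dispersal-radius relation

    R(t) = sqrt(4 D t) · erfinv(0.9)

used to fit the diffusion coefficients from mark–release–recapture style
flight-distance data.  ``erfinv(0.9)`` (≈ 1.1630871537) is the 90% quantile
of the one-axis displacement of a diffusing cloud; see the methods note for
why the one-axis convention is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

from scipy.special import erfinv

__all__ = [
    "ModelParameters",
    "DispersalFit",
    "default_parameters",
    "spreading_radius",
    "fit_diffusion",
    "read_parameter_file",
    "QUANTILE_90",
]

#: 90% one-axis containment quantile, erfinv(0.9).
QUANTILE_90: float = float(erfinv(0.9))


@dataclass(frozen=True)
class ModelParameters:
    """All rate and transport coefficients of the five-phase model.

    Attributes
    ----------
    beta:
        Expected eggs per successful female–wild-male encounter
        (m²/day: multiplies the F·M density product).
    e:
        Egg hatching rate (1/day).
    eta_a:
        Emergence rate from the aquatic phase into adults (1/day).
    mu_a, mu_f, mu_m, mu_g:
        Mortality rates of aquatic, female, wild-male and GM-male
        phases (1/day).
    r:
        Female fraction of emerging adults (dimensionless, 0 < r < 1).
    D_m:
        Diffusion coefficient of wild adults, females and males (m²/day).
    D_g:
        Diffusion coefficient of GM males (m²/day).
    """

    beta: float = 34.0
    e: float = 0.24
    eta_a: float = 0.5596
    mu_a: float = 0.025
    mu_f: float = 0.1177
    mu_m: float = 0.1177
    mu_g: float = 0.62
    r: float = 0.5
    D_m: float = 111.0
    D_g: float = 331.4062

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
        rates = ("beta", "e", "eta_a", "mu_a", "mu_f", "mu_m", "mu_g", "D_m", "D_g")
        for name in rates:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"female fraction r must lie in (0, 1), got {self.r}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given coefficients replaced (re-validated)."""
        return replace(self, **overrides)


def default_parameters() -> ModelParameters:
    """Literature default coefficient set (the package's single source)."""
    return ModelParameters()


def spreading_radius(diffusion: float, time: float) -> float:
    """Radius containing 90% of a point-released diffusing population.

    Parameters
    ----------
    diffusion:
        Diffusion coefficient D (m²/day), ``>= 0``.
    time:
        Elapsed time t (days), ``>= 0``.

    Returns
    -------
    float
        ``sqrt(4 D t) * erfinv(0.9)`` in meters.
    """
    if diffusion < 0:
        raise ValueError(f"diffusion must be non-negative, got {diffusion}")
    if time < 0:
        raise ValueError(f"time must be non-negative, got {time}")
    return math.sqrt(4.0 * diffusion * time) * QUANTILE_90


def fit_diffusion(radius: float, time: float) -> float:
    """Diffusion coefficient implied by a spreading radius at a given time.

    Inverts :func:`spreading_radius`:  ``D = R² / (4 t erfinv(0.9)²)``.
    This is how the adult (65 m over 7 days → ≈111 m²/day) and GM-male
    dispersal data are turned into diffusion coefficients.

    Parameters
    ----------
    radius:
        Spreading distance R (m), ``>= 0``.
    time:
        Characteristic time (days), ``> 0``.
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    if time <= 0:
        raise ValueError(f"time must be strictly positive, got {time}")
    return radius**2 / (4.0 * time * QUANTILE_90**2)


@dataclass(frozen=True)
class DispersalFit:
    """A (radius, time, diffusion) triple satisfying the spreading relation."""

    radius: float
    time: float
    diffusion: float
    quantile_constant: float = QUANTILE_90

    def __post_init__(self) -> None:
        if self.radius < 0 or self.time < 0 or self.diffusion < 0:
            raise ValueError("radius, time and diffusion must be non-negative")
        if self.time > 0:
            expected = spreading_radius(self.diffusion, self.time)
            scale = max(1.0, abs(self.radius))
            if abs(expected - self.radius) > 1e-9 * scale:
                raise ValueError(
                    f"inconsistent fit: R(D={self.diffusion}, t={self.time}) = "
                    f"{expected} != {self.radius}"
                )

    @classmethod
    def from_radius(cls, radius: float, time: float) -> "DispersalFit":
        """Fit D from an observed spreading radius and characteristic time."""
        return cls(radius=radius, time=time, diffusion=fit_diffusion(radius, time))

    @classmethod
    def from_diffusion(cls, diffusion: float, time: float) -> "DispersalFit":
        """Predict the spreading radius from a known diffusion coefficient."""
        return cls(
            radius=spreading_radius(diffusion, time), time=time, diffusion=diffusion
        )


_PARAM_NAMES = tuple(f.name for f in fields(ModelParameters))


def read_parameter_file(path) -> ModelParameters:
    """Read coefficients from a flat ``key = value`` text config.

    Keys use the model symbol names (``beta``, ``e``, ``eta_a``, ``mu_a``,
    ``mu_f``, ``mu_m``, ``mu_g``, ``r``, ``D_m``, ``D_g``).  Omitted keys
    keep their defaults; unknown keys are an error.  Blank lines and lines
    starting with ``#`` are ignored.
    """
    overrides: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in _PARAM_NAMES:
                raise ValueError(
                    f"{path}:{lineno}: unknown parameter {key!r} "
                    f"(known: {', '.join(_PARAM_NAMES)})"
                )
            if key in overrides:
                raise ValueError(f"{path}:{lineno}: duplicate parameter {key!r}")
            try:
                overrides[key] = float(value.strip())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
    return ModelParameters(**overrides)
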