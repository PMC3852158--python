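"""Body-size estimation chain and encephalization calculations.

A damaged fossil often preserves no complete limb bone, so body mass has to
be reached indirectly: (1) fit a reduced major axis (RMA) regression of limb
length on basal skull length across related taxa, (2) predict the missing
limb lengths from an estimated skull length, (3) push those lengths through
published limb-length -> body-mass scaling equations, and (4) combine the
resulting mass with an endocast volume into an encephalization quotient (EQ)
under Eisenberg's mammalian scaling E_expected = 0.055 * P^0.74 (grams).

RMA (also called standardized major axis) is the appropriate line when both
variables carry measurement error: its slope is sign(r) * s_y / s_x on the
chosen scale, which for allometry is conventionally log10.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometricDataset",
    "RmaFit",
    "MassEstimate",
    "EncephalizationResult",
    "fit_rma",
    "predict_limb_length",
    "estimate_masses",
    "eisenberg_eq",
    "brain_fraction",
    "load_mass_equations",
]

# Eisenberg's expected brain mass for a mammal of body mass P grams:
# E_expected = EISENBERG_COEF * P ** EISENBERG_EXP, both masses in grams.
EISENBERG_COEF = 0.055
EISENBERG_EXP = 0.74


@dataclass(frozen=True)
class AllometricDataset:
    """Paired skull/limb measurements across specimens.

    ``skull_mm`` and ``limb_mm`` are basal skull length and limb (humerus or
    femur) length in millimetres; all lengths must be strictly positive.
    """

    specimens: tuple[str, ...]
    taxa: tuple[str, ...]
    skull_mm: np.ndarray
    limb_mm: np.ndarray
    limb_kind: str = "humerus"

    def __post_init__(self) -> None:
        x = np.asarray(self.skull_mm, dtype=float)
        y = np.asarray(self.limb_mm, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("skull_mm and limb_mm must be 1-D and the same length")
        if len(self.specimens) != x.size or len(self.taxa) != x.size:
            raise ValueError("specimen/taxon labels must match measurement count")
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("all lengths must be strictly positive")
        if self.limb_kind not in ("humerus", "femur"):
            raise ValueError(f"limb_kind must be humerus or femur, got {self.limb_kind!r}")
        object.__setattr__(self, "skull_mm", x)
        object.__setattr__(self, "limb_mm", y)

    @property
    def n(self) -> int:
        return self.skull_mm.size

    @classmethod
    def from_csv(cls, path) -> "AllometricDataset":
        """Read a measurements CSV with columns specimen,taxon,skull_mm,limb_mm,limb_kind."""
        df = pd.read_csv(path)
        kinds = set(df["limb_kind"])
        if len(kinds) != 1:
            raise ValueError(f"expected a single limb_kind per table, got {sorted(kinds)}")
        return cls(
            tuple(df["specimen"].astype(str)),
            tuple(df["taxon"].astype(str)),
            df["skull_mm"].to_numpy(float),
            df["limb_mm"].to_numpy(float),
            kinds.pop(),
        )


@dataclass(frozen=True)
class RmaFit:
    """Reduced major axis line y = a + b*x on the transformed scale."""

    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    transform: str  # "linear" or "log10"


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "linear":
        return x
    if transform == "log10":
        if (x <= 0).any():
            raise ValueError("log10 transform requires strictly positive values")
        return np.log10(x)
    raise ValueError(f"transform must be 'linear' or 'log10', got {transform!r}")


def fit_rma(
    dataset: AllometricDataset | None = None,
    transform: str = "log10",
    *,
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
) -> RmaFit:
    """Fit a reduced major axis regression on the transformed scale.

    The slope is the closed form sign(r) * s_y / s_x and the intercept
    ybar - b * xbar; r² equals the squared Pearson correlation.  Accepts
    either an :class:`AllometricDataset` (x = skull, y = limb) or raw
    ``x``/``y`` arrays.
    """
    if dataset is not None:
        xv, yv = dataset.skull_mm, dataset.limb_mm
    else:
        if x is None or y is None:
            raise ValueError("provide a dataset or both x and y")
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if xv.size < 3:
        raise ValueError(f"need at least 3 points to fit, got {xv.size}")
    tx = _transform(xv, transform)
    ty = _transform(yv, transform)
    sx = tx.std(ddof=1)
    sy = ty.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y; RMA slope undefined")
    r = float(stats.pearsonr(tx, ty).statistic)
    b = math.copysign(sy / sx, r if r != 0 else 1.0)
    a = float(ty.mean() - b * tx.mean())
    return RmaFit(slope=float(b), intercept=a, r=r, r2=r * r, n=int(xv.size),
                  transform=transform)


def predict_limb_length(fit: RmaFit, skull_length: float) -> float:
    """Evaluate the fitted line at a skull length, back-transforming if needed."""
    if skull_length <= 0:
        raise ValueError("skull_length must be positive")
    if fit.transform == "log10":
        return float(10 ** (fit.intercept + fit.slope * math.log10(skull_length)))
    return float(fit.intercept + fit.slope * skull_length)


# ---------------------------------------------------------------------------
# mass equations


@dataclass(frozen=True)
class MassEstimate:
    equation: str
    inputs: dict[str, float]
    mass_g: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass must be positive")


def load_mass_equations(path=None) -> dict:
    """Load limb-length -> body-mass equation coefficients.

    Without ``path``, loads the packaged default file.  NOTE: the packaged
    defaults are synthetic stand-in coefficients (see the file's ``notes``
    field); substitute the published regression coefficients for real work.
    Each equation is log-linear: log10(mass_g) = intercept + sum_i slope_i *
    log10(length_i_mm) over its inputs.
    """
    if path is None:
        ref = resources.files("paleokit").joinpath("data/mass_equations_synthetic.json")
        return json.loads(ref.read_text())
    with open(path) as fh:
        return json.load(fh)


def estimate_masses(
    limb_lengths: Mapping[str, Sequence[float] | float],
    equation_set: Mapping | None = None,
) -> tuple[list[MassEstimate], dict[str, float]]:
    """Apply every applicable mass equation to every input combination.

    ``limb_lengths`` maps ``"humerus"``/``"femur"`` to one or more lengths in
    mm (several femur predictions from different reference fits are typical).
    Univariate equations produce one estimate per length; the multivariate
    humerus+femur equation produces one per (humerus, femur) pair.  Returns
    the estimates plus min/max/mean summary in grams.
    """
    if equation_set is None:
        equation_set = load_mass_equations()
    lengths = {
        k: [float(v)] if np.isscalar(v) else [float(u) for u in v]
        for k, v in limb_lengths.items()
    }
    for kind, vals in lengths.items():
        if any(v <= 0 for v in vals):
            raise ValueError(f"nonpositive {kind} length")

    estimates: list[MassEstimate] = []
    for eq in equation_set["equations"]:
        needed = eq["inputs"]
        if not all(k in lengths for k in needed):
            continue
        missing = [c for c in ("slopes", "intercept") if c not in eq]
        if missing:
            raise ValueError(f"equation {eq.get('id', '?')!r} missing {missing}")
        if len(eq["slopes"]) != len(needed):
            raise ValueError(f"equation {eq['id']!r}: slope count != input count")
        combos: list[dict[str, float]] = [{}]
        for kind in needed:
            combos = [dict(c, **{kind: v}) for c in combos for v in lengths[kind]]
        for combo in combos:
            log_m = eq["intercept"] + sum(
                s * math.log10(combo[k]) for s, k in zip(eq["slopes"], needed)
            )
            estimates.append(MassEstimate(eq["id"], combo, 10 ** log_m))
    if not estimates:
        raise ValueError("no equation applicable to the provided limb lengths")
    masses = np.array([e.mass_g for e in estimates])
    summary = {
        "min": float(masses.min()),
        "max": float(masses.max()),
        "mean": float(masses.mean()),
        "n_estimates": len(estimates),
    }
    return estimates, summary


# ---------------------------------------------------------------------------
# encephalization


@dataclass(frozen=True)
class EncephalizationResult:
    """Brain mass, body mass and encephalization quotient.

    ``eq`` is kept at full precision; ``eq_2dp`` rounds to two decimals for
    reporting.  ``expected_brain_mass_g`` is Eisenberg's 0.055 * P^0.74.
    """

    endocast_volume_mm3: float
    density_g_cm3: float
    brain_mass_g: float
    body_mass_g: float
    expected_brain_mass_g: float
    eq: float

    @property
    def eq_2dp(self) -> float:
        return round(self.eq, 2)


def eisenberg_eq(
    endocast_volume_mm3: float,
    body_mass_g: float,
    density: float = 1.0,
) -> EncephalizationResult:
    """Encephalization quotient from endocast volume and body mass.

    Brain mass E = volume [mm³] * density [g/cm³] / 1000; the quotient is
    E / (0.055 * P^0.74) with P the body mass in grams.  Density defaults to
    1.0 g/cm³, the standard brain-tissue assumption.
    """
    if endocast_volume_mm3 <= 0 or body_mass_g <= 0 or density <= 0:
        raise ValueError("volume, body mass and density must all be positive")
    brain_mass = endocast_volume_mm3 * density / 1000.0
    expected = EISENBERG_COEF * body_mass_g ** EISENBERG_EXP
    return EncephalizationResult(
        endocast_volume_mm3=float(endocast_volume_mm3),
        density_g_cm3=float(density),
        brain_mass_g=brain_mass,
        body_mass_g=float(body_mass_g),
        expected_brain_mass_g=expected,
        eq=brain_mass / expected,
    )


def brain_fraction(
    part_volumes_mm3: Iterable[float], total_volume_mm3: float
) -> float:
    """Percentage of total brain volume occupied by the given parts (1 d.p.)."""
    parts = [float(v) for v in part_volumes_mm3]
    if total_volume_mm3 <= 0:
        raise ValueError("total volume must be positive")
    if any(v < 0 for v in parts):
        raise ValueError("part volumes must be nonnegative")
    s = sum(parts)
    if s > total_volume_mm3:
        warnings.warn(
            f"part volumes ({s} mm³) exceed the total ({total_volume_mm3} mm³)",
            stacklevel=2,
        )
    return round(100.0 * s / total_volume_mm3, 1)
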