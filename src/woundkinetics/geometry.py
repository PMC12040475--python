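"""Elliptic wound geometry.

Natural wounds (e.g. canine-tooth lacerations in wild baboons) are
approximately elliptic and are photographed as surface areas rather than
widths.  Assuming the ellipse shape is preserved during healing, the minor
axis *W* (the direction along which healing distance is measured) relates
linearly to the major axis *L* on the first photographed day,

    W = a*L + b,

and the surface area of an ellipse with axes L, W is S = pi*L*W/4.
Substituting L = (W - b)/a gives the quadratic

    W**2 - b*W - 4*a*S/pi = 0,

whose unique positive root recovers the width from an observed area.

Note on the quadratic's coefficient arrangement: the alternative form
``W**2 - a*W - 4*b*S/pi = 0`` (coefficients a and b swapped) circulates in
the applied literature but is not consistent with the substitution above.
This module implements the consistent form by default and exposes the
swapped arrangement via ``form="printed"`` for sensitivity analysis; see
``width_from_area``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EllipseRelation",
    "WoundAxes",
    "ellipse_area",
    "fit_width_length_relation",
    "width_from_area",
    "length_from_width",
]


@dataclass(frozen=True)
class EllipseRelation:
    """Linear width-length relation W = a*L + b for one wound population.

    Parameters
    ----------
    a : float
        Dimensionless slope of width on length; must be positive.
    b : float
        Intercept in mm.  Physically meaningful fits have b >= 0; a
        negative intercept triggers a warning, not an error.
    residual_sd : float, optional
        Residual standard deviation of the fit in mm.
    n_points : int, optional
        Number of day-1 wounds the relation was fitted to.
    """

    a: float
    b: float
    residual_sd: float | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"relation slope a must be finite and > 0, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError(f"relation intercept b must be finite, got {self.b}")
        if self.b < 0:
            warnings.warn(
                f"width-length intercept b={self.b:.4g} mm is negative; the "
                "relation is not physically meaningful near L=0",
                stacklevel=3,
            )

    def to_dict(self) -> dict:
        d = {"a": float(self.a), "b": float(self.b)}
        if self.residual_sd is not None:
            d["residual_sd"] = float(self.residual_sd)
        if self.n_points is not None:
            d["n_points"] = int(self.n_points)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseRelation":
        return cls(
            a=float(d["a"]),
            b=float(d["b"]),
            residual_sd=d.get("residual_sd"),
            n_points=d.get("n_points"),
        )


@dataclass(frozen=True)
class WoundAxes:
    """Ellipse axes of one wound in mm: length = major, width = minor."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValueError(
                f"wound axes must be non-negative, got L={self.length}, W={self.width}"
            )
        if self.width > self.length:
            warnings.warn(
                f"width {self.width} mm exceeds length {self.length} mm; axes may "
                "be swapped (natural wounds are sometimes measured either way)",
                stacklevel=3,
            )


def ellipse_area(axes: WoundAxes | None = None, *, length: float | None = None,
                 width: float | None = None) -> float:
    """Surface area pi*L*W/4 of an elliptic wound, in mm^2.

    Accepts either a :class:`WoundAxes` or explicit ``length``/``width``
    keywords.  Symmetric in the two axes.
    """
    if axes is not None:
        length, width = axes.length, axes.width
    if length is None or width is None:
        raise TypeError("provide WoundAxes or both length= and width=")
    if length < 0 or width < 0:
        raise ValueError(f"axes must be non-negative, got L={length}, W={width}")
    return math.pi * length * width / 4.0


def fit_width_length_relation(day1_axes) -> EllipseRelation:
    """Ordinary least-squares fit of width on length over day-1 wounds.

    Parameters
    ----------
    day1_axes : sequence of WoundAxes or of (length, width) pairs
        At least two points with distinct lengths.

    Returns
    -------
    EllipseRelation with the OLS slope/intercept and the residual SD
    (denominator n-2; 0.0 reported for exactly collinear points or n=2).
    """
    pairs = [
        (ax.length, ax.width) if isinstance(ax, WoundAxes) else (float(ax[0]), float(ax[1]))
        for ax in day1_axes
    ]
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 day-1 wounds to fit W-L relation, got {len(pairs)}")
    L = np.array([p[0] for p in pairs], dtype=float)
    W = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(L) == 0:
        raise ValueError("all lengths identical; W-L slope is not identifiable")
    X = np.column_stack([L, np.ones_like(L)])
    coef, *_ = np.linalg.lstsq(X, W, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = W - X @ coef
    dof = len(pairs) - 2
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return EllipseRelation(a=a, b=b, residual_sd=residual_sd, n_points=len(pairs))


def width_from_area(area, rel: EllipseRelation, form: str = "derived"):
    """Invert an observed wound area to the minor-axis width, in mm.

    Solves ``W**2 - b*W - 4*a*S/pi = 0`` (the arrangement consistent with
    W = a*L + b and S = pi*L*W/4) and returns the positive root

        W = (b + sqrt(b**2 + 16*a*S/pi)) / 2.

    For S > 0 the product of the roots is -4*a*S/pi < 0, so exactly one
    root is positive.  At S = 0 the roots are {0, b}; b is returned (the
    L -> 0 limit of the relation) with a warning, since a fully healed
    wound should be encoded as healing distance = reference size rather
    than pushed through this inversion.

    Parameters
    ----------
    area : float or array-like
        Wound surface area(s), mm^2, >= 0.
    rel : EllipseRelation
    form : {"derived", "printed"}
        "printed" swaps the roles of a and b in the quadratic
        (``W**2 - a*W - 4*b*S/pi = 0``), for sensitivity analysis only.

    Returns
    -------
    float or ndarray, strictly increasing in ``area``.
    """
    S = np.asarray(area, dtype=float)
    scalar = S.ndim == 0
    if np.any(S < 0):
        raise ValueError("wound area must be non-negative")
    if form == "derived":
        lin, const = rel.b, rel.a
    elif form == "printed":
        lin, const = rel.a, rel.b
    else:
        raise ValueError(f"form must be 'derived' or 'printed', got {form!r}")
    if np.any(S == 0):
        warnings.warn(
            "area 0 passed through the ellipse inversion; fully healed wounds "
            "should be encoded as healing distance = reference size",
            stacklevel=2,
        )
    W = 0.5 * (lin + np.sqrt(lin * lin + 16.0 * const * S / math.pi))
    return float(W) if scalar else W


def length_from_width(width: float, rel: EllipseRelation) -> float:
    """Major axis implied by a width under W = a*L + b: L = (W - b)/a.

    Raises a domain error for ``width < rel.b`` (implied negative length).
    """
    if width < rel.b:
        raise ValueError(
            f"width {width} mm is below the relation intercept b={rel.b} mm; "
            "the model implies a negative length"
        )
    return (width - rel.b) / rel.a
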