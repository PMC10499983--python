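"""Exact quadratic polynomials in the family dimension ``t``.

Everything in this package that depends on the dimension parameter of a
network family — edge-partition frequencies and the topological-index
closed forms built from them — is a quadratic ``c2*t**2 + c1*t + c0`` with
integer coefficients.  This module provides that small algebra (addition,
integer scaling, exact evaluation) plus exact Lagrange interpolation used
to certify closed forms recovered from brute-force counts.  No floating
point is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

__all__ = ["QuadraticPolynomial", "fit_quadratic_exact"]


@dataclass(frozen=True)
class QuadraticPolynomial:
    """``c2*t**2 + c1*t + c0`` with exact (integer or rational) coefficients.

    Equality is coefficient-wise.  Coefficients are normalised to ``int``
    whenever they are integral so that ``QuadraticPolynomial(2, 0, 1) ==
    QuadraticPolynomial(Fraction(2), 0, 1)``.
    """

    c2: int | Fraction
    c1: int | Fraction
    c0: int | Fraction

    def __post_init__(self) -> None:
        for name in ("c2", "c1", "c0"):
            value = getattr(self, name)
            if isinstance(value, float):
                raise TypeError("coefficients must be exact (int or Fraction)")
            value = Fraction(value)
            if value.denominator == 1:
                value = int(value)
            object.__setattr__(self, name, value)

    def __call__(self, t: int) -> int | Fraction:
        value = self.c2 * t * t + self.c1 * t + self.c0
        if isinstance(value, Fraction) and value.denominator == 1:
            return int(value)
        return value

    def __add__(self, other: "QuadraticPolynomial") -> "QuadraticPolynomial":
        return QuadraticPolynomial(
            self.c2 + other.c2, self.c1 + other.c1, self.c0 + other.c0
        )

    def scale(self, k: int) -> "QuadraticPolynomial":
        return QuadraticPolynomial(k * self.c2, k * self.c1, k * self.c0)

    @property
    def coefficients(self) -> tuple:
        """Coefficients ``(c2, c1, c0)``, highest degree first."""
        return (self.c2, self.c1, self.c0)

    def is_integral(self) -> bool:
        return all(isinstance(c, int) for c in self.coefficients)

    def __str__(self) -> str:
        terms = []
        for coeff, suffix in ((self.c2, "t^2"), (self.c1, "t"), (self.c0, "")):
            if coeff == 0:
                continue
            sign = "-" if coeff < 0 else "+"
            mag = abs(coeff)
            body = f"{mag}{suffix}" if suffix and mag != 1 else (suffix or str(mag))
            terms.append((sign, body))
        if not terms:
            return "0"
        first_sign, first_body = terms[0]
        out = ("-" if first_sign == "-" else "") + first_body
        for sign, body in terms[1:]:
            out += f" {sign} {body}"
        return out

    @staticmethod
    def zero() -> "QuadraticPolynomial":
        return QuadraticPolynomial(0, 0, 0)


def fit_quadratic_exact(
    points: Sequence[tuple[int, int]],
) -> tuple[QuadraticPolynomial, bool]:
    """Interpolate a quadratic through the first three points, exactly.

    Parameters
    ----------
    points
        At least four distinct ``(t, value)`` pairs.  The first three fix
        the quadratic by exact rational Lagrange interpolation; the rest
        certify it.

    Returns
    -------
    (polynomial, certified)
        ``certified`` is True iff every remaining point lies exactly on the
        interpolated quadratic.  A False flag means the underlying sequence
        is not quadratic in ``t`` (degree > 2, or not polynomial at all).
    """
    points = list(points)
    if len(points) < 4:
        raise ValueError(
            "need at least 4 points: 3 to interpolate and >=1 to certify"
        )
    ts = [t for t, _ in points]
    if len(set(ts)) != len(ts):
        raise ValueError("interpolation points must have distinct t values")

    (t0, v0), (t1, v1), (t2, v2) = points[:3]
    # Lagrange basis, collected into monomial coefficients with Fractions.
    c2 = Fraction(0)
    c1 = Fraction(0)
    c0 = Fraction(0)
    for (ti, vi), (tj, _), (tk, _) in (
        ((t0, v0), (t1, v1), (t2, v2)),
        ((t1, v1), (t0, v0), (t2, v2)),
        ((t2, v2), (t0, v0), (t1, v1)),
    ):
        denom = (ti - tj) * (ti - tk)
        w = Fraction(vi, denom)
        # (t - tj)(t - tk) = t^2 - (tj+tk) t + tj*tk
        c2 += w
        c1 += w * -(tj + tk)
        c0 += w * (tj * tk)
    poly = QuadraticPolynomial(c2, c1, c0)
    certified = all(poly(t) == v for t, v in points[3:])
    return poly, certified
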