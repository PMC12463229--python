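"""Exact Laurent-polynomial arithmetic in one and two variables.

Jones-type invariants live in rings such as Z[a, a^-1], Z[q, q^-1] and
Z[t^{1/4}, t^{-1/4}].  Everything here is exact: coefficients are stored as
:class:`fractions.Fraction` and equality is coefficient-map equality.  The
quarter-power convention stores exponents in units of 1/4, which is how the
Jones polynomial in the variable t arises from the Kauffman polynomial via
a -> t^{-1/4}.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, Mapping, Tuple

__all__ = ["LaurentPolynomial", "TwoVarPolynomial"]


def _clean(coeffs: Mapping[int, Fraction]) -> Dict[int, Fraction]:
    return {e: Fraction(c) for e, c in coeffs.items() if c != 0}


class LaurentPolynomial:
    """A Laurent polynomial ``sum_e c_e * var^e`` with exact coefficients.

    Parameters
    ----------
    coeffs:
        Map exponent -> coefficient.  Exponents are integers; when
        ``quarter`` is true they are counted in units of 1/4 (so the stored
        exponent 4 means ``var^1``).
    var:
        Variable name, purely cosmetic ("a", "q", "t", ...).
    quarter:
        Quarter-power flag used for Jones polynomials in t.
    """

    __slots__ = ("coeffs", "var", "quarter")

    def __init__(self, coeffs: Mapping[int, Fraction] | None = None,
                 var: str = "q", quarter: bool = False):
        self.coeffs: Dict[int, Fraction] = _clean(coeffs or {})
        self.var = var
        self.quarter = quarter

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls, var: str = "q", quarter: bool = False) -> "LaurentPolynomial":
        return cls({}, var, quarter)

    @classmethod
    def one(cls, var: str = "q", quarter: bool = False) -> "LaurentPolynomial":
        return cls({0: Fraction(1)}, var, quarter)

    @classmethod
    def monomial(cls, exponent: int, coeff=1, var: str = "q",
                 quarter: bool = False) -> "LaurentPolynomial":
        return cls({exponent: Fraction(coeff)}, var, quarter)

    # -- ring operations ----------------------------------------------
    def _compat(self, other: "LaurentPolynomial") -> None:
        if self.var != other.var or self.quarter != other.quarter:
            raise ValueError(
                f"incompatible polynomials: {self.var!r}/{other.var!r} "
                f"quarter={self.quarter}/{other.quarter}")

    def __add__(self, other):
        if isinstance(other, int):
            other = LaurentPolynomial({0: Fraction(other)}, self.var, self.quarter)
        self._compat(other)
        out = dict(self.coeffs)
        for e, c in other.coeffs.items():
            out[e] = out.get(e, Fraction(0)) + c
        return LaurentPolynomial(out, self.var, self.quarter)

    __radd__ = __add__

    def __neg__(self):
        return LaurentPolynomial({e: -c for e, c in self.coeffs.items()},
                                 self.var, self.quarter)

    def __sub__(self, other):
        if isinstance(other, int):
            other = LaurentPolynomial({0: Fraction(other)}, self.var, self.quarter)
        return self + (-other)

    def __mul__(self, other):
        if isinstance(other, (int, Fraction)):
            return LaurentPolynomial(
                {e: c * other for e, c in self.coeffs.items()},
                self.var, self.quarter)
        self._compat(other)
        out: Dict[int, Fraction] = {}
        for e1, c1 in self.coeffs.items():
            for e2, c2 in other.coeffs.items():
                e = e1 + e2
                out[e] = out.get(e, Fraction(0)) + c1 * c2
        return LaurentPolynomial(out, self.var, self.quarter)

    __rmul__ = __mul__

    def __pow__(self, n: int):
        if n < 0:
            raise ValueError("negative powers of polynomials not supported")
        out = LaurentPolynomial.one(self.var, self.quarter)
        base = self
        while n:
            if n & 1:
                out = out * base
            base = base * base
            n >>= 1
        return out

    def divide_exact(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        """Exact division in the Laurent ring; raises if not divisible."""
        self._compat(other)
        if not other.coeffs:
            raise ZeroDivisionError("division by the zero polynomial")
        if not self.coeffs:
            return LaurentPolynomial.zero(self.var, self.quarter)
        rem = dict(self.coeffs)
        dmax, dmin = max(other.coeffs), min(other.coeffs)
        dlead = other.coeffs[dmax]
        quot: Dict[int, Fraction] = {}
        while rem:
            e = max(rem)
            if e - min(rem) < dmax - dmin:
                raise ValueError("polynomial is not exactly divisible")
            qexp = e - dmax
            qc = rem[e] / dlead
            quot[qexp] = quot.get(qexp, Fraction(0)) + qc
            for e2, c2 in other.coeffs.items():
                k = qexp + e2
                rem[k] = rem.get(k, Fraction(0)) - qc * c2
                if rem[k] == 0:
                    del rem[k]
        return LaurentPolynomial(quot, self.var, self.quarter)

    # -- queries -------------------------------------------------------
    def __eq__(self, other):
        if isinstance(other, int):
            return self.coeffs == _clean({0: Fraction(other)})
        return (isinstance(other, LaurentPolynomial)
                and self.coeffs == other.coeffs
                and self.quarter == other.quarter)

    def __hash__(self):
        return hash((frozenset(self.coeffs.items()), self.quarter))

    def __bool__(self):
        return bool(self.coeffs)

    def substitute_exponents(self, scale_num: int, scale_den: int,
                             var: str, quarter: bool = False) -> "LaurentPolynomial":
        """Map var^e -> newvar^(e*scale_num/scale_den) (exponent relabeling).

        Used e.g. for a -> t^{-1/4}: each exponent e of ``a`` becomes the
        quarter-exponent -e of ``t``.
        """
        out: Dict[int, Fraction] = {}
        for e, c in self.coeffs.items():
            k, r = divmod(e * scale_num, scale_den)
            if r:
                raise ValueError("exponent substitution is not integral")
            out[k] = out.get(k, Fraction(0)) + c
        return LaurentPolynomial(out, var, quarter)

    def evaluate(self, value: complex) -> complex:
        """Numerically evaluate (quarter exponents use value**(e/4))."""
        den = 4 if self.quarter else 1
        return sum(complex(c) * value ** (e / den) for e, c in self.coeffs.items())

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"var": self.var, "quarter": self.quarter,
                "coeffs": {str(e): str(c) for e, c in sorted(self.coeffs.items())}}

    @classmethod
    def from_dict(cls, data: dict) -> "LaurentPolynomial":
        return cls({int(e): Fraction(c) for e, c in data["coeffs"].items()},
                   data.get("var", "q"), data.get("quarter", False))

    def pretty(self) -> str:
        """Render like ``q^-1 + q^-3 + q^-5 - q^-9``."""
        if not self.coeffs:
            return "0"
        terms = []
        for e in sorted(self.coeffs, reverse=True):
            c = self.coeffs[e]
            sign = "-" if c < 0 else "+"
            mag = abs(c)
            if self.quarter:
                exp = Fraction(e, 4)
                estr = str(exp) if exp.denominator == 1 else f"{exp.numerator}/{exp.denominator}"
            else:
                estr = str(e)
            if e == 0:
                body = str(mag)
            else:
                head = f"{self.var}^{estr}" if estr != "1" else self.var
                body = head if mag == 1 else f"{mag}*{head}"
            terms.append((sign, body))
        first_sign, first_body = terms[0]
        out = ("-" if first_sign == "-" else "") + first_body
        for sign, body in terms[1:]:
            out += f" {sign} {body}"
        return out

    def __repr__(self):
        return f"LaurentPolynomial({self.pretty()!r}, var={self.var!r})"


class TwoVarPolynomial:
    """Exact polynomial in (t, q) with integer Laurent exponents.

    The graded Poincare polynomial Kh(L) = sum_k qdim H^k(L) t^k lives here.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs: Mapping[Tuple[int, int], Fraction] | None = None):
        self.coeffs: Dict[Tuple[int, int], Fraction] = {
            k: Fraction(v) for k, v in (coeffs or {}).items() if v != 0}

    def __add__(self, other: "TwoVarPolynomial") -> "TwoVarPolynomial":
        out = dict(self.coeffs)
        for k, v in other.coeffs.items():
            out[k] = out.get(k, Fraction(0)) + v
        return TwoVarPolynomial(out)

    def __eq__(self, other):
        return isinstance(other, TwoVarPolynomial) and self.coeffs == other.coeffs

    def __hash__(self):
        return hash(frozenset(self.coeffs.items()))

    def specialize_t(self, t_value: int) -> LaurentPolynomial:
        """Substitute an integer value for t, leaving a polynomial in q.

        ``specialize_t(-1)`` turns the Poincare polynomial into the graded
        Euler characteristic.
        """
        out: Dict[int, Fraction] = {}
        for (tk, qk), c in self.coeffs.items():
            out[qk] = out.get(qk, Fraction(0)) + c * (t_value ** tk if tk >= 0
                                                      else Fraction(1, t_value ** (-tk)))
        return LaurentPolynomial(out, "q")

    def to_dict(self) -> dict:
        return {"vars": ["t", "q"],
                "coeffs": {f"{t},{q}": str(c)
                           for (t, q), c in sorted(self.coeffs.items())}}

    def pretty(self) -> str:
        if not self.coeffs:
            return "0"
        parts = []
        for (tk, qk) in sorted(self.coeffs):
            c = self.coeffs[(tk, qk)]
            factors = []
            if c != 1 or (tk == 0 and qk == 0):
                factors.append(str(c))
            if tk:
                factors.append(f"t^{tk}")
            if qk:
                factors.append(f"q^{qk}")
            parts.append("*".join(factors))
        return " + ".join(parts)

    def __repr__(self):
        return f"TwoVarPolynomial({self.pretty()!r})"
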