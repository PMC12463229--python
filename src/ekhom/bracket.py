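"""Kauffman bracket, Kauffman polynomial and Jones polynomials.

Two bracket normalizations are provided.  The classical one in the variable
``a`` satisfies

    <O> = 1,   <O u L> = (-a^2 - a^-2) <L>,   <L> = a <L_0> + a^-1 <L_1>,

and as a state sum  <L> = sum_s a^{alpha(s)-beta(s)} (-a^2-a^-2)^{gamma(s)-1},
where alpha/beta count 0-/1-smoothings of the state s and gamma(s) its
circles.  The q-normalization (substituting q = -a^-2 and renormalizing the
unknot to q + q^-1) satisfies

    <O> = q + q^-1,   <L> = <L_0> - q <L_1>,

with state sum  sum_s (-q)^{beta(s)} (q+q^-1)^{gamma(s)}.  The latter is the
one Khovanov homology categorifies: the unnormalized Jones polynomial

    Jhat(L) = (-1)^{n-} q^{n+ - 2 n-} <L>_q

equals the graded Euler characteristic of the Khovanov complex, and the
Jones polynomial is J(L) = Jhat(L) / (q + q^-1).

All coefficients are exact rationals; nothing here uses floating point.
"""

from __future__ import annotations

from itertools import product

from .diagram import LinkDiagram
from .laurent import LaurentPolynomial

__all__ = [
    "bracket_a", "bracket_q", "bracket_q_recursive", "kauffman_polynomial",
    "jones_t", "unnormalized_jones_q", "jones_q",
]

# a configurable sanity bound: 2^n states are enumerated
MAX_STATE_SUM_CROSSINGS = 20


def _check_size(d: LinkDiagram) -> None:
    if d.n > MAX_STATE_SUM_CROSSINGS:
        raise ValueError(
            f"state sum over 2^{d.n} states refused; "
            f"raise bracket.MAX_STATE_SUM_CROSSINGS to override")


def bracket_a(d: LinkDiagram) -> LaurentPolynomial:
    """Kauffman bracket in ``a``, normalized so a single unknot gives 1.

    The empty diagram (no crossings, no loops) evaluates to 1 (the empty
    product); a diagram of k disjoint circles gives (-a^2-a^-2)^(k-1).
    """
    _check_size(d)
    delta = LaurentPolynomial({2: -1, -2: -1}, "a")
    total = LaurentPolynomial.zero("a")
    n = d.n
    if n == 0:
        k = d.free_loops
        return delta ** (k - 1) if k else LaurentPolynomial.one("a")
    for state in product((0, 1), repeat=n):
        beta = sum(state)
        alpha = n - beta
        gamma = d.resolve(state).count
        term = LaurentPolynomial.monomial(alpha - beta, 1, "a") * delta ** (gamma - 1)
        total = total + term
    return total


def bracket_q(d: LinkDiagram) -> LaurentPolynomial:
    """Kauffman bracket in the q-normalization (unknot -> q + q^-1).

    State sum: sum over all 2^n states of (-q)^beta (q+q^-1)^gamma.
    The empty diagram gives 1.
    """
    _check_size(d)
    delta = LaurentPolynomial({1: 1, -1: 1}, "q")
    total = LaurentPolynomial.zero("q")
    n = d.n
    if n == 0:
        return delta ** d.free_loops
    for state in product((0, 1), repeat=n):
        beta = sum(state)
        gamma = d.resolve(state).count
        coeff = (-1) ** beta
        term = LaurentPolynomial.monomial(beta, coeff, "q") * delta ** gamma
        total = total + term
    return total


def bracket_q_recursive(d: LinkDiagram) -> LaurentPolynomial:
    """Same invariant as :func:`bracket_q`, by the skein recursion
    <L> = <L_0> - q <L_1> instead of the closed state sum.

    Kept as an independent code path; tests assert the two agree.
    """
    if d.n == 0:
        return LaurentPolynomial({1: 1, -1: 1}, "q") ** d.free_loops
    x = d.crossing_ids()[0]
    q = LaurentPolynomial.monomial(1, 1, "q")
    return (bracket_q_recursive(d.smooth(x, 0))
            - q * bracket_q_recursive(d.smooth(x, 1)))


def kauffman_polynomial(d: LinkDiagram) -> LaurentPolynomial:
    """Normalized bracket X_L(a) = (-a)^{-3 w(L)} <L>_a (a knot invariant)."""
    w = d.writhe()
    sign = -1 if (3 * w) % 2 else 1
    return LaurentPolynomial.monomial(-3 * w, sign, "a") * bracket_a(d)


def jones_t(d: LinkDiagram) -> LaurentPolynomial:
    """Jones polynomial V_L(t) = X_L(t^{-1/4}), in quarter powers of t."""
    x = kauffman_polynomial(d)
    # exponent e of a becomes quarter-exponent -e of t
    return LaurentPolynomial({-e: c for e, c in x.coeffs.items()}, "t",
                             quarter=True)


def unnormalized_jones_q(d: LinkDiagram) -> LaurentPolynomial:
    """Jhat(L) = (-1)^{n-} q^{n+ - 2 n-} <L>_q.

    Equals the graded Euler characteristic of the Khovanov complex.
    """
    npl, nmi = d.n_plus, d.n_minus
    sign = -1 if nmi % 2 else 1
    return LaurentPolynomial.monomial(npl - 2 * nmi, sign, "q") * bracket_q(d)


def jones_q(d: LinkDiagram) -> LaurentPolynomial:
    """J(L) = Jhat(L) / (q + q^-1), by exact polynomial division."""
    jhat = unnormalized_jones_q(d)
    delta = LaurentPolynomial({1: 1, -1: 1}, "q")
    try:
        return jhat.divide_exact(delta)
    except Exception as exc:  # non-divisibility signals a malformed diagram
        raise ValueError(
            "unnormalized Jones polynomial is not divisible by q + q^-1; "
            "the diagram is malformed") from exc
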