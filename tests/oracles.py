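"""Independent brute-force oracles, kept deliberately naive.

These enumerate risk sets by explicit membership testing and carry all
arithmetic in exact fractions; they share no code with the package's
estimators.
"""

from fractions import Fraction

KNOWN = ("cancer", "other")


def risk_set(members, t):
    """Explicit membership test: (entry, exit, status) triples at risk at t."""
    return [
        m for m in members if (m[0] < t <= m[1]) or (m[0] == m[1] == t)
    ]


def km_oracle(members, events=("cancer", "other")):
    """Classical product-limit curve as a list of (time, n, d, S) with exact
    fractions; ``events`` lists the statuses counted as deaths."""
    times = sorted({m[1] for m in members if m[2] in events})
    s = Fraction(1)
    out = []
    for t in times:
        at_risk = risk_set(members, t)
        n = len(at_risk)
        if n == 0:
            break
        d = sum(1 for m in members if m[1] == t and m[2] in events)
        s = s * Fraction(n - d, n)
        out.append((t, n, d, s))
    return out


def icm_oracle(members, cause="cancer"):
    """Cumulative incidence of ``cause`` by direct summation: at every
    known-cause death age, add S(t-) * d_cause/n, then drop S.

    Returns (icm, final_survival) as exact fractions.
    """
    times = sorted({m[1] for m in members if m[2] in KNOWN})
    s = Fraction(1)
    icm = Fraction(0)
    for t in times:
        at_risk = risk_set(members, t)
        n = len(at_risk)
        if n == 0:
            break
        d_all = sum(1 for m in members if m[1] == t and m[2] in KNOWN)
        d_c = sum(1 for m in members if m[1] == t and m[2] == cause)
        icm += s * Fraction(d_c, n)
        s = s * Fraction(n - d_all, n)
    return icm, s
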