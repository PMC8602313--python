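"""Independent exhaustive-enumeration oracle in arbitrary precision.

Re-derives the seven-event posterior for a site from first principles with
mpmath: explicit gamma-function beta-binomials, plain products over reads,
and exact rational interval membership.  Shares no code with the package
(only the published linear coefficients of the amplification-bias model,
restated here) so it can serve as an independent cross-check.
"""

from fractions import Fraction as F

import mpmath as mp

mp.mp.dps = 40

COEFF = {
    "alpha": ("-0.00003", "0.06857"),
    "beta": ("0.00745", "2.36749"),
    "w": ("0.00055", "0.54040"),
    "alpha1": ("0.05738", "0.66973"),
    "alpha2": ("0.00323", "0.39926"),
}

SHAPE_FLOOR = mp.mpf("1e-6")


def params(l):
    out = {k: mp.mpf(s) * l + mp.mpf(i) for k, (s, i) in COEFF.items()}
    for key in ("alpha", "beta", "alpha1", "alpha2"):
        out[key] = max(out[key], SHAPE_FLOOR)
    out["w"] = min(max(out["w"], mp.mpf(0)), mp.mpf(1))
    return out


def bb(k, l, a, b):
    return mp.binomial(l, k) * mp.beta(k + a, l - k + b) / mp.beta(a, b)


def sc_pmf(l, theta):
    p = params(l)
    if theta == 0:
        return [bb(k, l, p["alpha"], p["beta"]) for k in range(l + 1)]
    if theta == 1:
        return [bb(k, l, p["beta"], p["alpha"]) for k in range(l + 1)]
    return [
        p["w"] * bb(k, l, p["alpha1"], p["alpha1"])
        + (1 - p["w"]) * bb(k, l, p["alpha2"], p["alpha2"])
        for k in range(l + 1)
    ]


def read_p(cls, e, rho):
    e = mp.mpf(e)
    if cls == "ALT":
        return rho * (1 - e) + (1 - rho) * e / 3
    if cls == "REF":
        return (1 - rho) * (1 - e) + rho * e / 3
    raise ValueError(cls)


# (name, theta_s members, predicate on the exact grid frequency)
EVENTS = [
    ("HOM_REF", (F(0),), lambda f: F(0) <= f < F(1, 2)),
    ("ERR_ALT", (F(1, 2), F(1)), lambda f: f == 0),
    ("ADO_TO_ALT", (F(1),), lambda f: F(0) < f <= F(1, 2)),
    ("HET", (F(1, 2),), lambda f: F(0) < f < F(1)),
    ("ADO_TO_REF", (F(0),), lambda f: F(1, 2) <= f < F(1)),
    ("ERR_REF", (F(0), F(1, 2)), lambda f: f == 1),
    ("HOM_ALT", (F(1),), lambda f: F(1, 2) < f <= F(1)),
]


def oracle_posteriors(sc, bulk):
    """Posterior over the seven events for read lists of (class, error) pairs."""
    sc = [r for r in sc if r[0] != "OTHER"]
    bulk = [r for r in bulk if r[0] != "OTHER"]
    l, n = len(sc), len(bulk)
    if n == 0:
        raise ValueError("oracle requires at least one bulk read")

    sc_lik = {}
    for theta in (F(0), F(1, 2), F(1)):
        pmf = sc_pmf(l, theta)
        total = mp.mpf(0)
        for k in range(l + 1):
            rho = mp.mpf(k) / l if l else mp.mpf(0)
            prod = mp.mpf(1)
            for cls, e in sc:
                prod *= read_p(cls, e, rho)
            total += prod * pmf[k]
        sc_lik[theta] = total

    bulk_lik = []
    for m in range(n + 1):
        rho = mp.mpf(m) / n
        prod = mp.mpf(1)
        for cls, e in bulk:
            prod *= read_p(cls, e, rho)
        bulk_lik.append(prod)

    liks = {}
    for name, thetas, pred in EVENTS:
        b = sum((bulk_lik[m] for m in range(n + 1) if pred(F(m, n))), mp.mpf(0))
        s = sum(sc_lik[t] for t in thetas)
        liks[name] = s * b
    marginal = sum(liks.values())
    return {name: v / marginal for name, v in liks.items()}
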