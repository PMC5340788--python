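"""Independent brute-force reference implementations.

Everything here is deliberately naive — set comprehensions, O(n^2)
loops, grid search — and shares no code with the package internals it
checks.
"""

import itertools

import numpy as np

SENT = -10.0


def brute_tanimoto(a, b) -> float:
    sa = {i for i, bit in enumerate(a) if bit}
    sb = {i for i, bit in enumerate(b) if bit}
    return len(sa & sb) / len(sa | sb)


def brute_network_categories(universe, de):
    """Category -> drug set, straight from the edge-set definitions."""
    dp = universe.drug_protein
    pg = universe.drug_gene_pg
    enzymes = {p for (d, p, r) in dp if d == de and r == "enzyme"}
    transporters = {p for (d, p, r) in dp if d == de and r == "transporter"}
    targets = {p for (d, p, r) in dp if d == de and r == "target"}
    neigh = set()
    for a, b in universe.ppi:
        if a in targets:
            neigh.add(b)
        if b in targets:
            neigh.add(a)
    neigh -= targets
    pd_prot = targets | neigh

    def drugs_on(prots, role):
        return {d for (d, p, r) in dp if r == role and p in prots and d != de}

    def pg_on(prots):
        return {d for (d, g) in pg if g in prots and d != de}

    return {
        "enzyme_int": drugs_on(enzymes, "enzyme"),
        "enzyme_pg": pg_on(enzymes),
        "transporter_int": drugs_on(transporters, "transporter"),
        "transporter_pg": pg_on(transporters),
        "target_int": drugs_on(pd_prot, "target"),
        "target_pg": pg_on(pd_prot),
    }


def brute_scores(universe, dq, de):
    """The seven scores as a dict, by exhaustive per-category maxima."""
    cats = brute_network_categories(universe, de)
    fp_of = {d: drug.fingerprint for d, drug in universe.drugs.items()}
    out = {"s_d": brute_tanimoto(fp_of[dq], fp_of[de])}
    mapping = {
        "enzyme_int": "s_e",
        "enzyme_pg": "s_eg",
        "transporter_int": "s_tr",
        "transporter_pg": "s_trg",
        "target_int": "s_ta",
        "target_pg": "s_tag",
    }
    for cat, score in mapping.items():
        members = cats[cat] - {dq, de}
        if members:
            out[score] = max(brute_tanimoto(fp_of[dq], fp_of[m]) for m in members)
        else:
            out[score] = SENT
    return out


def brute_auc(scores, labels) -> float:
    """P(score+ > score-) + ties/2 by O(n^2) pair counting."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def _loglik(beta0, beta1, x, y):
    eta = beta0 + beta1 * x
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def grid_fit_logistic(x, y, span=8.0, rounds=6, grid=41):
    """Single-feature logistic MLE by iteratively refined grid search."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c0, c1 = 0.0, 0.0
    width = span
    for _ in range(rounds):
        b0s = np.linspace(c0 - width, c0 + width, grid)
        b1s = np.linspace(c1 - width, c1 + width, grid)
        best = (-np.inf, c0, c1)
        for b0, b1 in itertools.product(b0s, b1s):
            ll = _loglik(b0, b1, x, y)
            if ll > best[0]:
                best = (ll, b0, b1)
        _, c0, c1 = best
        width /= grid / 4.0
    return c0, c1
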