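"""Independent brute-force reference implementations used only by tests.

Explicit loops and textbook formulas, deliberately sharing no code with the
package so they can serve as oracles for the vectorized implementations.
"""

import math


def brute_landscape(energies, include_native_in_mean=False, sample_sd=True):
    """Gap, roughness and ISR by explicit loops; first minimum is native."""
    native_idx = 0
    for i, e in enumerate(energies):
        if e < energies[native_idx]:
            native_idx = i
    e_native = energies[native_idx]
    decoys = [e for i, e in enumerate(energies) if i != native_idx]

    pool = list(energies) if include_native_in_mean else decoys
    mean = sum(pool) / len(pool)

    decoy_mean = sum(decoys) / len(decoys)
    ss = sum((e - decoy_mean) ** 2 for e in decoys)
    denom = len(decoys) - 1 if sample_sd else len(decoys)
    roughness = math.sqrt(ss / denom)

    gap = mean - e_native
    return {
        "e_native": e_native,
        "mean_decoy": mean,
        "delta_gap": gap,
        "roughness": roughness,
        "isr": gap / roughness if roughness > 0 else float("nan"),
    }


def brute_pearson(xs, ys):
    """Product-moment correlation by explicit loops."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)
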