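"""Straight-line scalar reference of the mixture background update rules.

Deliberately simple and independent of the package's vectorised
implementation: plain Python floats, dicts and loops, one pixel at a time.
Used as the oracle for the equivalence tests.
"""

import numpy as np


def reference_masks(history, k_init, params):
    """Foreground flags for a single pixel's intensity history.

    ``params`` is a midirseg.GmmParams; only its scalar fields are read.
    The first frame initialises the mixture and yields no flag.
    """
    comps = [
        {"w": 1.0 / k_init, "mu": float(history[0]), "var": params.init_variance}
        for _ in range(k_init)
    ]
    flags = []
    for x in history[1:]:
        x = float(x)
        matched = -1
        for i, c in enumerate(comps):
            if abs(x - c["mu"]) <= params.match_multiplier * np.sqrt(c["var"]):
                matched = i
                break
        cum, bg_count = 0.0, len(comps)
        for i, c in enumerate(comps):
            cum += c["w"]
            if cum >= params.background_ratio - 1e-9:
                bg_count = i + 1
                break
        flags.append(matched == -1 or matched >= bg_count)

        a = params.alpha
        if matched == -1:
            for c in comps:
                c["w"] *= 1.0 - a
            if a > 0:
                comps[-1] = {"w": params.replacement_weight, "mu": x, "var": params.init_variance}
        else:
            for i, c in enumerate(comps):
                if i == matched:
                    old = c["mu"]
                    c["w"] = (1.0 - a) * c["w"] + a
                    c["mu"] = (1.0 - a) * old + a * x
                    c["var"] = max((1.0 - a) * c["var"] + a * (x - old) ** 2,
                                   params.variance_floor)
                else:
                    c["w"] *= 1.0 - a
        total = sum(c["w"] for c in comps)
        for c in comps:
            c["w"] /= total
        comps.sort(key=lambda c: -(c["w"] / c["var"]))  # stable, like the model
    return flags
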