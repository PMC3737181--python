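"""Independent brute-force oracles used to cross-check the implementation."""

import math

import numpy as np

from ryrec.markers import cote_to_assembly


def fisher_two_sided_brute(table, tie_tol=1e-7):
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Works in exact integer arithmetic over all tables with the observed
    margins, summing those no more probable than the observed table (ties
    admitted with a small relative tolerance, as in the tested convention).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denominator = math.comb(n, c1)
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_min, k_max + 1)
    }
    threshold = weights[a] * (1.0 + tie_tol)
    return sum(w for w in weights.values() if w <= threshold) / denominator


def expected_selected_crossovers(config, marker_map):
    """Analytic expectation of recovered crossovers under the tract model.

    A crossover product passes selection only when the junction on the side of
    the recipient's null site falls strictly between the two selected sites;
    the transmitted chromatid is then the functional product with probability
    1/2.  The junction offset from the DSB is geometric on {0, 1, ...} with
    mean mean_tract_bp / 2, and the DSB is uniform on the configured window.
    """
    lo, hi = config.resolved_window(marker_map)
    p = 1.0 / (1.0 + config.mean_tract_bp / 2.0)
    dsb = np.arange(lo, hi + 1, dtype=float)
    sel_lo, sel_hi = cote_to_assembly(-468), cote_to_assembly(3506)

    def cdf(k):
        k = np.asarray(k, dtype=float)
        return np.where(k < 0.0, 0.0, 1.0 - (1.0 - p) ** (np.floor(k) + 1.0))

    # recipient ry606N: right tract end r = dsb + G must satisfy sel_lo <= r < sel_hi
    p_606 = (cdf(sel_hi - 1 - dsb) - cdf(sel_lo - 1 - dsb)).mean()
    # recipient ry609N: left tract end l = dsb - G must satisfy sel_lo < l <= sel_hi
    p_609 = (cdf(dsb - sel_lo - 1) - cdf(dsb - sel_hi - 1)).mean()
    p_junction = 0.5 * (p_606 + p_609)
    return config.n_progeny * config.event_rate * config.p_co * p_junction * 0.5
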