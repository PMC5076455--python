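"""Independent brute-force oracles used to cross-check the implementation.

These are written from the definitions, deliberately not sharing code with
the package: BH step-up from its textbook definition, PAS as a naive
term-by-term sum, and GeroScore as the naive target x pathway double loop.
"""

import math


def bh_brute(pvalues):
    """Benjamini-Hochberg step-up from the definition.

    Sort ascending; q_(i) = min_{j >= i} m * p_(j) / j, capped at 1;
    return in original order.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * pvalues[idx] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return q


def pas_brute(cnr, btif, pathway, log_base=10.0):
    """Naive term-by-term PAS: sum of ARR * BTIF * log(CNR) over measured
    member genes."""
    total = 0.0
    for gene, arr in pathway.members.items():
        if gene not in cnr or cnr[gene] != cnr[gene]:  # absent or NaN
            continue
        total += arr * btif.get(gene, 0) * math.log(cnr[gene], log_base)
    return total


def geroscore_brute(drug, pas_by_pathway, db):
    """Naive double loop over drug targets and pathways:
    sum_t DTI * sum_p NII * ARR * PAS * PAR."""
    total = 0.0
    for gene, dti in drug.targets.items():
        inner = 0.0
        for pathway in db:
            if gene in pathway.members:
                inner += pathway.members[gene] * pas_by_pathway[pathway.pathway_id] * pathway.par
        total += dti * inner
    return total
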