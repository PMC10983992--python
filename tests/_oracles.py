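"""Independent brute-force reference implementations used as test oracles.

These deliberately use plain loops over plain dicts/lists so they share no
code path with the package.
"""

import math


def oracle_direction(log2fc, padj, fc=2.0, p=0.05):
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return "unchanged"
    if padj >= p:
        return "unchanged"
    if log2fc >= math.log2(fc):
        return "up"
    if log2fc <= -math.log2(fc):
        return "down"
    return "unchanged"


def oracle_score(members, de_rows, fc=2.0, p=0.05, threshold=0.30):
    """Engagement counts for one regulon.

    ``de_rows`` is {gene: (log2fc, padj)}; returns a plain dict.
    """
    n_up = n_down = n_detected = 0
    for gene in members:
        if gene not in de_rows:
            continue
        n_detected += 1
        d = oracle_direction(*de_rows[gene], fc=fc, p=p)
        if d == "up":
            n_up += 1
        elif d == "down":
            n_down += 1
    n_engaged = n_up + n_down
    fraction = n_engaged / len(members)
    return {
        "n_total": len(members), "n_detected": n_detected,
        "n_engaged": n_engaged, "n_up": n_up, "n_down": n_down,
        "fraction": fraction, "included": fraction >= threshold,
    }


def oracle_network(regulon_members, de_rows, fc=2.0, p=0.05, threshold=0.30):
    """Node and edge sets of the engagement network, by exhaustive scan.

    ``regulon_members`` is {regulator: set(genes)}. Returns (nodes, edges)
    where edges maps frozenset pairs to (n_shared, n_shared_engaged).
    """
    nodes = {
        r for r, members in regulon_members.items()
        if oracle_score(members, de_rows, fc, p, threshold)["included"]
    }
    de_genes = {
        g for g, (l, q) in de_rows.items()
        if oracle_direction(l, q, fc, p) != "unchanged"
    }
    edges = {}
    done = set()
    for a in nodes:
        for b in nodes:
            if a == b or frozenset((a, b)) in done:
                continue
            done.add(frozenset((a, b)))
            shared = regulon_members[a] & regulon_members[b]
            shared_de = shared & de_genes
            if shared and shared_de:
                edges[frozenset((a, b))] = (len(shared), len(shared_de))
    return nodes, edges


def oracle_venn(set_a, set_b):
    return (
        {x for x in set_a if x not in set_b},
        {x for x in set_b if x not in set_a},
        {x for x in set_a if x in set_b},
    )


def gaussian_area(amplitude, sigma):
    return amplitude * sigma * math.sqrt(2 * math.pi)
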