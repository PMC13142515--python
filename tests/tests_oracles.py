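"""Independent oracle implementations used by the acceptance suite.

These deliberately avoid the package's code paths: plain loops, raw (non-log)
Bayes factors, and explicit set arithmetic.
"""

import numpy as np
from scipy.stats import norm


def h4_enumeration_oracle(stats_a, stats_b, p1=1e-4, p2=1e-4, p12=1e-5,
                          sd_a=0.15, sd_b=0.15):
    union = sorted(set(stats_a["variant_id"]) | set(stats_b["variant_id"]))

    def abf(tab, v, sd):
        row = tab[tab["variant_id"] == v]
        if row.empty:
            return 1.0
        var = float(row["se"].iloc[0]) ** 2
        w = sd**2
        z2 = float(row["beta"].iloc[0]) ** 2 / var
        return float(np.sqrt(var / (var + w)) * np.exp(z2 * w / (var + w) / 2.0))

    ba = {v: abf(stats_a, v, sd_a) for v in union}
    bb = {v: abf(stats_b, v, sd_b) for v in union}
    s0 = 1.0
    s1 = p1 * sum(ba.values())
    s2 = p2 * sum(bb.values())
    s3 = p1 * p2 * sum(ba[i] * bb[j] for i in union for j in union if i != j)
    s4 = p12 * sum(ba[v] * bb[v] for v in union)
    tot = s0 + s1 + s2 + s3 + s4
    return tuple(x / tot for x in (s0, s1, s2, s3, s4))


def pics_transcription_oracle(neglog_p, r2, k=6.4):
    weights = []
    for r2_i in r2:
        mu = r2_i * neglog_p
        sd = np.sqrt(max(1.0 - r2_i ** (k / 2.0), 0.0)) * np.sqrt(neglog_p) / 2.0
        if sd == 0:
            weights.append(1.0)
        else:
            weights.append(2.0 * (1.0 - norm.cdf((neglog_p - mu) / sd)))
    w = np.array(weights)
    return w / w.sum()


def _greedy_distance_leads(pos, p, window=500_000, gws=1e-8):
    idx = list(range(len(pos)))
    leads = []
    while True:
        gws_idx = [i for i in idx if p[i] <= gws]
        if not gws_idx:
            break
        top = min(gws_idx, key=lambda i: (p[i], pos[i]))
        leads.append(top)
        idx = [i for i in idx if abs(pos[i] - pos[top]) > window]
    return leads


def locus_breaker_oracle(pos, p, p_cluster=1e-5, gap=250_000, gws=1e-8,
                         max_span=1_500_000, half_window=750_000):
    """Step-by-step hand transcription of the three-step locus breaker;
    returns the list of member-position sets."""
    pos = list(map(int, pos))
    p = list(map(float, p))
    leads = _greedy_distance_leads(pos, p)
    keep = sorted([i for i in range(len(pos)) if p[i] < p_cluster],
                  key=lambda i: pos[i])
    clusters, current = [], []
    for i in keep:
        if current and pos[i] - pos[current[-1]] > gap:
            clusters.append(current)
            current = []
        current.append(i)
    if current:
        clusters.append(current)
    out = []
    for cl in clusters:
        if not any(p[i] <= gws for i in cl):
            continue
        span = pos[cl[-1]] - pos[cl[0]]
        if span <= max_span:
            out.append({pos[i] for i in cl})
        else:
            for lead in leads:
                if lead in cl:
                    out.append({
                        pos[i] for i in cl
                        if abs(pos[i] - pos[lead]) <= half_window
                    })
    return out


def cluster_reachability_oracle(cs_table, coloc_pairs):
    """Partition equal to connected components of the union relation
    (colocalisation edges plus shared-lead edges), visited in significance
    order."""
    ids = list(cs_table["cs_id"])
    lead = dict(zip(cs_table["cs_id"], cs_table["lead_variant"]))
    edges = {}
    for a, b in coloc_pairs:
        edges.setdefault(a, set()).add(b)
        edges.setdefault(b, set()).add(a)
    for i in ids:
        for j in ids:
            if i != j and lead[i] == lead[j]:
                edges.setdefault(i, set()).add(j)
    order = cs_table.sort_values(["lead_p", "cs_id"])["cs_id"].tolist()
    seen, parts = set(), set()
    for s in order:
        if s in seen:
            continue
        comp, frontier = {s}, [s]
        while frontier:
            nxt = []
            for x in frontier:
                for y in edges.get(x, ()):
                    if y not in comp:
                        comp.add(y)
                        nxt.append(y)
            frontier = nxt
        seen |= comp
        parts.add(frozenset(comp))
    return parts
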