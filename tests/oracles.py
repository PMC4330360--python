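"""Independent brute-force oracles for the pair scores and rankings.

Everything here is deliberately naive — per-sample Python loops, explicit
enumeration of pairs and orientations — and shares no code with the
package's vectorised implementations.
"""

from __future__ import annotations

import math

from scipy.stats import rankdata


def oracle_s1(x_i, x_j, labels, c1, c2, tie_policy="strict"):
    """Direct per-sample counting of the order frequencies."""
    n1 = n2 = 0
    gt1 = lt2 = 0.0
    for xi, xj, lab in zip(x_i, x_j, labels):
        if lab == c1:
            n1 += 1
            if xi > xj:
                gt1 += 1
            elif xi == xj and tie_policy == "half":
                gt1 += 0.5
        else:
            n2 += 1
            if xi < xj:
                lt2 += 1
            elif xi == xj and tie_policy == "half":
                lt2 += 0.5
    return gt1 / n1 + lt2 / n2 - 1.0


def oracle_s2(r_i, r_j, labels, c1, c2):
    """Absolute between-class difference of mean within-sample rank diffs."""
    d1 = [ri - rj for ri, rj, lab in zip(r_i, r_j, labels) if lab == c1]
    d2 = [ri - rj for ri, rj, lab in zip(r_i, r_j, labels) if lab == c2]
    return abs(sum(d1) / len(d1) - sum(d2) / len(d2))


def oracle_ig(votes_tumor, labels, c1, c2):
    """Entropy arithmetic over the rule's vote partition, in bits."""

    def h(counts):
        n = sum(counts)
        return -sum(c / n * math.log2(c / n) for c in counts if c) if n else 0.0

    n1 = sum(1 for l in labels if l == c1)
    n2 = len(labels) - n1
    groups = {True: [0, 0], False: [0, 0]}
    for v, lab in zip(votes_tumor, labels):
        groups[v][0 if lab == c1 else 1] += 1
    n = len(labels)
    h_cond = sum((sum(g) / n) * h(g) for g in groups.values())
    return h([n1, n2]) - h_cond


def oracle_rank_pairs(expression, gene_of, labels, c1, c2, tie_policy="strict"):
    """Exhaustive enumeration + stable sort one-pair-per-gene ranking.

    ``expression``: dict transcript -> list of per-sample values, in dataset
    transcript order.  Returns list of dicts with the listing's columns.
    """
    tids = list(expression)
    matrix = [expression[t] for t in tids]
    ranks = rankdata(matrix, axis=0, method="average")
    rank_of = {t: ranks[i] for i, t in enumerate(tids)}

    by_gene: dict[str, list[str]] = {}
    for t in tids:
        by_gene.setdefault(gene_of[t], []).append(t)

    best_per_gene = []
    for g in by_gene:
        txs = by_gene[g]
        best = None
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                a, b = txs[i], txs[j]
                xa, xb = expression[a], expression[b]
                if all(xi == xj for xi, xj in zip(xa, xb)):
                    continue  # degenerate: tied in every sample
                s_ab = oracle_s1(xa, xb, labels, c1, c2, tie_policy)
                s_ba = oracle_s1(xb, xa, labels, c1, c2, tie_policy)
                if s_ab >= s_ba:
                    normal, tumor, s1 = a, b, s_ab
                else:
                    normal, tumor, s1 = b, a, s_ba
                if s1 < 0:
                    continue
                s2 = oracle_s2(rank_of[a], rank_of[b], labels, c1, c2)
                cand = (s1, s2, normal, tumor)
                # first pair in enumeration order wins ties
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
        if best is not None:
            s1, s2, normal, tumor = best
            votes = [
                t >= n for t, n in zip(expression[tumor], expression[normal])
            ]
            ig = oracle_ig(votes, labels, c1, c2)
            best_per_gene.append(
                {"gene": g, "tumor_isoform": tumor, "normal_isoform": normal,
                 "s1": s1, "s2": s2, "ig": ig}
            )

    best_per_gene.sort(key=lambda r: (-r["s1"], -r["s2"], r["gene"]))
    for k, row in enumerate(best_per_gene, start=1):
        row["rank"] = k
    return best_per_gene


def oracle_max_stats(expression, gene_of, labels, c1, c2, tie_policy="strict"):
    """(max S1, max IG) over per-gene best pairs, without the S1 >= 0 cut."""
    tids = list(expression)
    by_gene: dict[str, list[str]] = {}
    for t in tids:
        by_gene.setdefault(gene_of[t], []).append(t)
    matrix = [expression[t] for t in tids]
    ranks = rankdata(matrix, axis=0, method="average")
    rank_of = {t: ranks[i] for i, t in enumerate(tids)}

    best_s1, best_ig = None, None
    for g, txs in by_gene.items():
        best = None
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                a, b = txs[i], txs[j]
                xa, xb = expression[a], expression[b]
                if all(xi == xj for xi, xj in zip(xa, xb)):
                    continue
                s_ab = oracle_s1(xa, xb, labels, c1, c2, tie_policy)
                s_ba = oracle_s1(xb, xa, labels, c1, c2, tie_policy)
                if s_ab >= s_ba:
                    normal, tumor, s1 = a, b, s_ab
                else:
                    normal, tumor, s1 = b, a, s_ba
                s2 = oracle_s2(rank_of[a], rank_of[b], labels, c1, c2)
                cand = (s1, s2, normal, tumor)
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
        if best is None:
            continue
        s1, s2, normal, tumor = best
        votes = [t >= n for t, n in zip(expression[tumor], expression[normal])]
        ig = oracle_ig(votes, labels, c1, c2)
        best_s1 = s1 if best_s1 is None else max(best_s1, s1)
        best_ig = ig if best_ig is None else max(best_ig, ig)
    return best_s1, best_ig
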