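"""Independent brute-force oracles used to validate the library.

Everything here is written as plain loops over sets and dicts, with no reuse
of the library's vectorised code paths, so agreement between the two is a
meaningful check.
"""

from __future__ import annotations

import itertools
import math


# -- DAG helpers (parent_map: child -> set of parents) ----------------------


def oracle_ancestors(term, parent_map):
    seen = set()
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for parent in parent_map.get(node, ()):
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return seen


def oracle_closure(terms, parent_map, roots):
    out = set()
    for t in terms:
        if t not in roots:
            out.add(t)
        out |= oracle_ancestors(t, parent_map)
    return out - set(roots)


def oracle_descendants(term, parent_map):
    return {t for t in parent_map if term in oracle_ancestors(t, parent_map)}


def oracle_propagate_pairs(pairs, parent_map, roots):
    """True-path closure of (protein, term) pairs, roots removed."""
    out = set()
    for protein, term in pairs:
        for t in oracle_closure([term], parent_map, roots):
            out.add((protein, t))
    return out


def oracle_propagate_scores(scores, parent_map, roots, all_terms):
    """score'(p, t) = max over descendants of t (t included) of score(p, .)."""
    out = {}
    for protein, term_scores in scores.items():
        relevant = oracle_closure(term_scores, parent_map, roots)
        new = {}
        for term in relevant:
            down = oracle_descendants(term, parent_map) | {term}
            new[term] = max(term_scores.get(t, 0.0) for t in down)
        out[protein] = new
    return out


# -- metrics ----------------------------------------------------------------


def oracle_pc_fmax(scores, truth, thresholds):
    """Protein-centric F-max by explicit per-protein set comparison.

    scores: {protein: {term: score}}; truth: {protein: set(term)} (every
    protein of `truth` is evaluated); thresholds: iterable of t values.
    """
    proteins = sorted(truth)
    best = 0.0
    for t in thresholds:
        psum, rsum = 0.0, 0.0
        for protein in proteins:
            predicted = {
                term
                for term, s in scores.get(protein, {}).items()
                if s >= t
            }
            tp = len(predicted & truth[protein])
            if predicted:
                psum += tp / len(predicted)
            rsum += tp / len(truth[protein])
        p = psum / len(proteins)
        r = rsum / len(proteins)
        if p + r > 0:
            best = max(best, 2 * p * r / (p + r))
    return best


def oracle_tc_fmax(scores, truth, thresholds, terms):
    """Per-term F-max over explicit confusion counts; returns {term: fmax}."""
    proteins = sorted(truth)
    out = {}
    for term in terms:
        positives = {p for p in proteins if term in truth[p]}
        if not positives:
            continue
        best = 0.0
        for t in thresholds:
            predicted = {
                p for p in proteins if scores.get(p, {}).get(term, 0.0) >= t
            }
            tp = len(predicted & positives)
            if not predicted or tp == 0:
                continue
            precision = tp / len(predicted)
            recall = tp / len(positives)
            best = max(best, 2 * precision * recall / (precision + recall))
        out[term] = best
    return out


def oracle_auc(positive_scores, negative_scores):
    """Pair-counting ROC AUC: (concordant + ties/2) / (n_pos * n_neg)."""
    total = 0.0
    for pos in positive_scores:
        for neg in negative_scores:
            if pos > neg:
                total += 1.0
            elif pos == neg:
                total += 0.5
    return total / (len(positive_scores) * len(negative_scores))


# -- temporal splits --------------------------------------------------------


def oracle_fig1_sets(records, parent_map, roots, cutoff):
    """Sets A (train), B (NA test), C (NP test) from first principles.

    records: iterable of (protein, term, evidence, year) tuples.
    Returns three sets of (protein, term) pairs.
    """
    pre = [(p, t) for (p, t, _e, y) in records if y <= cutoff]
    post = [(p, t) for (p, t, _e, y) in records if y > cutoff]
    annotated = {p for p, _ in pre}
    a = oracle_propagate_pairs(pre, parent_map, roots)
    b = set()
    for p, t in oracle_propagate_pairs(
        [(p, t) for p, t in post if p in annotated], parent_map, roots
    ):
        if (p, t) in a:
            continue  # rule (a)
        trained = {t2 for p2, t2 in a if p2 == p}
        if any(t in oracle_ancestors(t2, parent_map) for t2 in trained):
            continue  # rule (b): a more specific training annotation exists
        b.add((p, t))
    c = oracle_propagate_pairs(
        [(p, t) for p, t in post if p not in annotated], parent_map, roots
    )
    return a, b, c


# -- predictors -------------------------------------------------------------


def oracle_gba(adjacency, train_pairs, test_proteins, terms):
    """Neighbour-fraction scores by explicit loops.

    adjacency: {protein: set(neighbour)}; train_pairs: set of (protein, term).
    """
    out = {}
    for p in test_proteins:
        neighbours = adjacency.get(p, set())
        out[p] = {}
        for term in terms:
            if not neighbours:
                out[p][term] = 0.0
            else:
                annotated = sum(
                    1 for q in neighbours if (q, term) in train_pairs
                )
                out[p][term] = annotated / len(neighbours)
    return out


def oracle_knn(kernel_order, kernel_values, train_proteins, train_pairs,
               test_protein, terms, k):
    """Top-k kernel neighbours with stable tie-break by kernel order."""
    i = kernel_order.index(test_protein)
    candidates = [
        (q, kernel_values[i][kernel_order.index(q)])
        for q in train_proteins
        if q != test_protein
    ]
    candidates.sort(key=lambda pair: (-pair[1], kernel_order.index(pair[0])))
    chosen = [q for q, _ in candidates[:k]]
    return {
        term: sum(1 for q in chosen if (q, term) in train_pairs) / len(chosen)
        for term in terms
    }


# -- features ---------------------------------------------------------------


def oracle_emax(evalues, term_proteins, query, term, divisor=10.0):
    """e-max by direct enumeration over the term's training proteins."""
    best = 0.0
    for subject in term_proteins.get(term, ()):
        e = evalues.get(query, {}).get(subject)
        if e is None:
            continue
        best = max(best, -math.log10(e / divisor))
    return max(best, 0.0)


def oracle_low_complexity_window(sequence, window):
    """Exhaustive scan for the leftmost window with fewest distinct residues."""
    best = None
    for start in range(len(sequence) - window + 1):
        chunk = sequence[start : start + window]
        distinct = len(set(chunk))
        if best is None or distinct < best[0]:
            best = (distinct, start, chunk)
    return best[2]


# -- discrepancy ------------------------------------------------------------


def oracle_discrepancy(train_pairs, test_pairs, term):
    train_proteins = {p for p, _ in train_pairs}
    test_proteins = {p for p, _ in test_pairs}
    p_tr = (
        sum(1 for p in train_proteins if (p, term) in train_pairs)
        / len(train_proteins)
        if train_proteins
        else 0.0
    )
    p_tst = (
        sum(1 for p in test_proteins if (p, term) in test_pairs)
        / len(test_proteins)
        if test_proteins
        else 0.0
    )
    if p_tr + p_tst == 0:
        return None
    return abs(p_tr - p_tst) / (p_tr + p_tst)
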