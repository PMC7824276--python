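"""Independent brute-force oracles used to validate the implementation.

Deliberately self-contained: nothing here calls into mitocomp's
comparison code beyond plain data structures.
"""

from itertools import combinations


def _canon(order, anchor):
    """Rotate ``anchor`` to the front, J-oriented (reference arithmetic)."""
    order = list(order)
    i = [g for g, _ in order].index(anchor)
    if order[i][1] == "N":
        order = [(g, "J" if s == "N" else "N") for g, s in reversed(order)]
        i = [g for g, _ in order].index(anchor)
    return tuple(order[i:] + order[:i])


def min_displaced_count(ref, qry, anchor):
    """Smallest set of genes (anchor excluded) whose removal makes the
    two circular signed orders identical — exhaustive enumeration."""
    common = {g for g, _ in ref} & {g for g, _ in qry}
    r = [e for e in ref if e[0] in common]
    q = [e for e in qry if e[0] in common]
    candidates = sorted(common - {anchor})
    for k in range(len(candidates) + 1):
        for subset in combinations(candidates, k):
            drop = set(subset)
            r2 = _canon([e for e in r if e[0] not in drop], anchor)
            q2 = _canon([e for e in q if e[0] not in drop], anchor)
            if r2 == q2:
                return k
    raise AssertionError("unreachable: removing all non-anchor genes "
                         "always equalizes the orders")


def degeneracy_oracle(codon):
    """Third-position synonymous-family size via Biopython's table 5."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[5]
    if codon in table.stop_codons:
        return "excluded"
    aa = table.forward_table[codon]
    family = sum(1 for b in "ACGT"
                 if codon[:2] + b not in table.stop_codons
                 and table.forward_table[codon[:2] + b] == aa)
    return {2: "twofold", 4: "fourfold"}[family]
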