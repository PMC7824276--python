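"""Canonical gene vocabulary for metazoan mitochondrial genomes.

The closed vocabulary covers the 37 genes of a typical metazoan mtDNA
(13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus the control region
(``CR``, the A+T-rich region containing the replication origin).  The
two leucine and two serine tRNAs are distinguished by anticodon:

========  ==================  =========
key       isoacceptor family  anticodon
========  ==================  =========
trnL1     Leu(CUN)            uag
trnL2     Leu(UUR)            uaa
trnS1     Ser(AGN)            gcu
trnS2     Ser(UCN)            uga
========  ==================  =========
"""

from __future__ import annotations

PCGS: tuple[str, ...] = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

TRNAS: tuple[str, ...] = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG",
    "trnH", "trnI", "trnK", "trnM", "trnF", "trnP", "trnT", "trnW",
    "trnY", "trnV", "trnL1", "trnL2", "trnS1", "trnS2",
)

RRNAS: tuple[str, ...] = ("rrnS", "rrnL")

CONTROL: tuple[str, ...] = ("CR",)

#: every canonical gene key, in vocabulary order
ALL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS + CONTROL

#: anticodon (lower-case, RNA alphabet) -> canonical key for the
#: ambiguous leucine / serine isoacceptors
LEU_SER_BY_ANTICODON = {
    ("L", "uag"): "trnL1",
    ("L", "uaa"): "trnL2",
    ("S", "gcu"): "trnS1",
    ("S", "uga"): "trnS2",
}


def feature_class(gene: str) -> str:
    """Return the feature class of a canonical key.

    One of ``PCG``, ``tRNA``, ``rRNA`` or ``control``.
    """
    if gene in PCGS:
        return "PCG"
    if gene in TRNAS:
        return "tRNA"
    if gene in RRNAS:
        return "rRNA"
    if gene in CONTROL:
        return "control"
    raise KeyError(f"not a canonical gene key: {gene!r}")


def is_valid(gene: str) -> bool:
    return gene in ALL_GENES
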