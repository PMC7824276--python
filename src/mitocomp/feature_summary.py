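"""Genome-architecture characterization: codons, spacers/overlaps, composition.

Covers the descriptive per-genome summaries typical of mitogenome
reports: start/stop codon classes of the 13 protein-coding genes
(canonical ATA/ATG starts, the alternative TTG start, ATT/ATC starts;
complete TAA/TAG stops vs polyadenylation-completed partial T/TA
stops), intergenic spacers and gene overlaps on the circular molecule,
and whole-molecule base composition.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from . import vocab
from .genome_io import Mitogenome, coding_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "CodonClassification",
    "SpacerOrOverlap",
    "CompositionReport",
    "classify_codons",
    "spacers_and_overlaps",
    "composition",
    "codon_table",
    "junction_table",
    "composition_table",
]

_CANONICAL_STARTS = {"ATA", "ATG"}
_COMPLETE_STOPS = {"TAA", "TAG"}
_PARTIAL_STOPS = {"T", "TA"}


@dataclass
class CodonClassification:
    gene: str
    start_codon: str
    start_class: str   # canonical_ATA_ATG | alternative_TTG | ATT_ATC | other
    stop_codon: str    # 1-3 nt
    stop_class: str    # complete | partial | other


@dataclass
class SpacerOrOverlap:
    left_gene: str
    right_gene: str
    kind: str          # spacer | overlap
    length: int


@dataclass
class CompositionReport:
    """Whole-molecule base counts on the deposited (J) strand.

    Ambiguity codes (including N) are excluded from the counts, so the
    four counts sum to the sequence length minus ambiguous bases.
    Percentages are rounded to one decimal.
    """

    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    def percent(self, base: str) -> float:
        count = getattr(self, base.lower())
        return round(100.0 * count / self.total, 1)

    @property
    def at_percent(self) -> float:
        return round(100.0 * (self.a + self.t) / self.total, 1)


def _start_class(codon: str) -> str:
    if codon in _CANONICAL_STARTS:
        return "canonical_ATA_ATG"
    if codon == "TTG":
        return "alternative_TTG"
    if codon in ("ATT", "ATC"):
        return "ATT_ATC"
    return "other"


def _stop_class(codon: str) -> str:
    if codon in _COMPLETE_STOPS:
        return "complete"
    if codon in _PARTIAL_STOPS:
        return "partial"
    return "other"


def classify_codons(genome: Mitogenome) -> list[CodonClassification]:
    """Start/stop codon classification of every annotated PCG.

    The start codon is the first 3 nt of the mRNA-sense CDS.  The stop
    codon is the trailing 1-3 nt left after removing complete codons: a
    CDS length of 1 or 2 mod 3 implies a partial stop (T or TA,
    completed to UAA by polyadenylation).
    """
    out = []
    for feat in genome.features:
        if feat.gene is None or vocab.feature_class(feat.gene) != "PCG":
            continue
        cds = coding_sequence(genome, feat.gene)
        if len(cds) < 6:
            logger.warning("%s: CDS of %s shorter than 6 nt; skipped",
                           genome.id, feat.gene)
            continue
        start = cds[:3]
        rem = len(cds) % 3
        stop = cds[-3:] if rem == 0 else cds[-rem:]
        out.append(CodonClassification(
            gene=feat.gene, start_codon=start, start_class=_start_class(start),
            stop_codon=stop, stop_class=_stop_class(stop)))
    return out


def spacers_and_overlaps(genome: Mitogenome) -> list[SpacerOrOverlap]:
    """Gaps and overlaps between circularly adjacent features.

    Features are sorted by circular start position; for each adjacent
    pair (including the origin-wrapping pair) a positive gap is a
    spacer, a negative gap an overlap.  A feature nested wholly inside
    its neighbor is reported as an overlap of the inner length, with a
    warning.  Zero-gap junctions produce no record.
    """
    feats = [f for f in genome.features if f.gene is not None]
    if len(feats) < 2:
        raise ValueError(f"{genome.id}: need at least 2 features")
    n = len(genome.sequence)
    intervals = sorted((f.genomic_interval(n) + (f,) for f in feats),
                       key=lambda t: (t[0], t[1]))
    out = []
    for i, (s, e, f) in enumerate(intervals):
        if i + 1 < len(intervals):
            ns, ne, nf = intervals[i + 1]
        else:
            ns, ne, nf = intervals[0]
            ns, ne = ns + n, ne + n
        gap = ns - e
        if gap > 0:
            out.append(SpacerOrOverlap(f.gene, nf.gene, "spacer", gap))
        elif gap < 0:
            inner = ne - ns
            if -gap >= inner:  # nested
                logger.warning("%s: feature %s nested inside %s",
                               genome.id, nf.gene, f.gene)
                out.append(SpacerOrOverlap(f.gene, nf.gene, "overlap", inner))
            else:
                out.append(SpacerOrOverlap(f.gene, nf.gene, "overlap", -gap))
    return out


def composition(genome_or_sequence) -> CompositionReport:
    """Whole-molecule A/C/G/T counts on the deposited strand.

    Accepts a :class:`Mitogenome` or a plain sequence string.  IUPAC
    ambiguity codes are excluded from the counts.
    """
    seq = (genome_or_sequence.sequence
           if isinstance(genome_or_sequence, Mitogenome)
           else genome_or_sequence)
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    rep = CompositionReport(a=counts["A"], c=counts["C"],
                            g=counts["G"], t=counts["T"])
    if rep.total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return rep


# ---------------------------------------------------------------------------
# tabular reports

def codon_table(genomes: Iterable[Mitogenome]):
    import pandas as pd

    rows = []
    for g in genomes:
        for c in classify_codons(g):
            rows.append({"genome_id": g.id, "gene": c.gene,
                         "start_codon": c.start_codon,
                         "start_class": c.start_class,
                         "stop_codon": c.stop_codon,
                         "stop_class": c.stop_class})
    return pd.DataFrame(rows, columns=["genome_id", "gene", "start_codon",
                                       "start_class", "stop_codon",
                                       "stop_class"])


def junction_table(genomes: Iterable[Mitogenome]):
    import pandas as pd

    rows = []
    for g in genomes:
        for j in spacers_and_overlaps(g):
            rows.append({"genome_id": g.id, "left_gene": j.left_gene,
                         "right_gene": j.right_gene, "kind": j.kind,
                         "length": j.length})
    return pd.DataFrame(rows, columns=["genome_id", "left_gene", "right_gene",
                                       "kind", "length"])


def composition_table(genomes: Iterable[Mitogenome]):
    import pandas as pd

    rows = []
    for g in genomes:
        rep = composition(g)
        rows.append({"genome_id": g.id, "length": len(g.sequence),
                     "A": rep.a, "C": rep.c, "G": rep.g, "T": rep.t,
                     "A_pct": rep.percent("a"), "C_pct": rep.percent("c"),
                     "G_pct": rep.percent("g"), "T_pct": rep.percent("t"),
                     "AT_pct": rep.at_percent})
    return pd.DataFrame(rows, columns=["genome_id", "length", "A", "C", "G",
                                       "T", "A_pct", "C_pct", "G_pct",
                                       "T_pct", "AT_pct"])
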