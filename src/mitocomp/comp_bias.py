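"""Strand- and site-class-partitioned nucleotide skews with outlier detection.

Protein-coding genes are read codon-wise in mRNA sense and every base
is assigned to one of eight site classes by gene strand (J/N), codon
position (1/2/3) and, at third positions, the degeneracy of the
codon's synonymous family under the invertebrate mitochondrial genetic
code (translation table 5):

    J1, N1, J2, N2, 2J3, 2N3 (two-fold), 4J3, 4N3 (four-fold)

Skews follow the standard definitions

    AT-skew = (A - T) / (A + T)        CG-skew = (C - G) / (C + G)

and are undefined (``None``, never 0) when the denominator vanishes.
Outliers across a genome set use Tukey-style fences at three times the
interquartile range beyond the 25-75% quartiles; values exactly on a
fence are not flagged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from . import vocab
from .genome_io import Mitogenome, coding_sequence
from .feature_summary import composition

logger = logging.getLogger(__name__)

__all__ = [
    "SITE_CLASSES",
    "SiteClassCounts",
    "SkewRecord",
    "OutlierReport",
    "degeneracy_class",
    "partition_sites",
    "skew",
    "detect_outliers",
    "skew_table",
    "outlier_table",
    "at_percent_distribution",
]

SITE_CLASSES = ("J1", "N1", "J2", "N2", "2J3", "2N3", "4J3", "4N3")

#: codon prefixes whose third-position synonymous family has four
#: members under translation table 5 (note AGN: AGA/AGG encode Ser, so
#: the whole AGN family is synonymous)
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG", "AG"})

#: stop codons of translation table 5 (TGA is Trp, AGA/AGG are Ser)
STOP_CODONS = frozenset({"TAA", "TAG"})

_BASES = ("A", "C", "G", "T")


def degeneracy_class(codon: str) -> str:
    """``fourfold`` / ``twofold`` / ``excluded`` under translation table 5.

    Stop codons and codons containing ambiguity characters are
    excluded.  Families touching the stops (TAN) contribute only their
    sense codons (TAT/TAC, two-fold).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        return "excluded"
    if codon in STOP_CODONS:
        return "excluded"
    return "fourfold" if codon[:2] in FOURFOLD_PREFIXES else "twofold"


@dataclass
class SiteClassCounts:
    genome_id: str
    site_class: str
    counts: Counter = field(default_factory=Counter)

    def __getitem__(self, base: str) -> int:
        return self.counts[base.upper()]


@dataclass
class SkewRecord:
    genome_id: str
    site_class: str
    at_skew: Optional[float]
    cg_skew: Optional[float]


@dataclass
class OutlierReport:
    site_class: str
    metric: str
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outlier_ids: tuple[str, ...]


def partition_sites(genome: Mitogenome) -> list[SiteClassCounts]:
    """Pooled per-class base counts over all annotated PCGs.

    Codons are read in mRNA sense; the gene's strand selects the J or N
    classes.  First/second position bases accumulate into (J|N)1 and
    (J|N)2; third positions go to 2(J|N)3 or 4(J|N)3 by degeneracy.
    Codons of excluded degeneracy (stops, ambiguity) contribute no base
    at all; incomplete trailing codons are skipped.
    """
    acc = {cls: Counter() for cls in SITE_CLASSES}
    n_pcg = 0
    for feat in genome.features:
        if feat.gene is None or vocab.feature_class(feat.gene) != "PCG":
            continue
        n_pcg += 1
        strand = feat.strand
        cds = coding_sequence(genome, feat.gene).upper()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            deg = degeneracy_class(codon)
            if deg == "excluded":
                continue
            acc[f"{strand}1"][codon[0]] += 1
            acc[f"{strand}2"][codon[1]] += 1
            key = f"2{strand}3" if deg == "twofold" else f"4{strand}3"
            acc[key][codon[2]] += 1
    if n_pcg == 0:
        raise ValueError(f"{genome.id}: no annotated protein-coding genes")
    return [SiteClassCounts(genome.id, cls, acc[cls]) for cls in SITE_CLASSES]


def skew(counts: SiteClassCounts) -> SkewRecord:
    """AT- and CG-skew of one site class; undefined encoded as ``None``."""
    a, t = counts["A"], counts["T"]
    c, g = counts["C"], counts["G"]
    at = (a - t) / (a + t) if a + t else None
    cg = (c - g) / (c + g) if c + g else None
    return SkewRecord(counts.genome_id, counts.site_class, at, cg)


def detect_outliers(values: Mapping[str, float], multiplier: float = 3.0,
                    site_class: str = "", metric: str = "") -> OutlierReport:
    """Interquartile-range outliers of a genome -> value mapping.

    Quartiles by linear interpolation; a value is flagged only when
    strictly beyond ``Q1 - multiplier*IQR`` or ``Q3 + multiplier*IQR``.
    Non-finite values are ignored; with fewer than 4 finite values no
    outlier is reported (a warning is logged).
    """
    finite = {k: v for k, v in values.items()
              if v is not None and np.isfinite(v)}
    if len(finite) < 4:
        logger.warning("fewer than 4 finite values (%d); no outlier analysis",
                       len(finite))
        nan = float("nan")
        return OutlierReport(site_class, metric, nan, nan, nan, nan, nan, ())
    arr = np.array(list(finite.values()), dtype=float)
    q1, q3 = np.percentile(arr, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    ids = tuple(sorted(k for k, v in finite.items() if v < lo or v > hi))
    return OutlierReport(site_class, metric, float(q1), float(q3), float(iqr),
                         float(lo), float(hi), ids)


# ---------------------------------------------------------------------------
# genome-set tables

def skew_table(genomes: Iterable[Mitogenome]):
    """Per-genome x site-class skew table (machine-readable skew plot twin)."""
    import pandas as pd

    rows = []
    for g in genomes:
        for counts in partition_sites(g):
            rec = skew(counts)
            rows.append({"genome_id": rec.genome_id,
                         "site_class": rec.site_class,
                         "A": counts["A"], "C": counts["C"],
                         "G": counts["G"], "T": counts["T"],
                         "at_skew": rec.at_skew, "cg_skew": rec.cg_skew})
    return pd.DataFrame(rows, columns=["genome_id", "site_class", "A", "C",
                                       "G", "T", "at_skew", "cg_skew"])


def outlier_table(skews, multiplier: float = 3.0):
    """IQR outlier report over a skew table, per class and metric."""
    import pandas as pd

    rows = []
    for cls in SITE_CLASSES:
        sub = skews[skews["site_class"] == cls]
        for metric in ("at_skew", "cg_skew"):
            values = {r.genome_id: getattr(r, metric)
                      for r in sub.itertuples()}
            rep = detect_outliers(values, multiplier, cls, metric)
            rows.append({"site_class": cls, "metric": metric,
                         "q1": rep.q1, "q3": rep.q3, "iqr": rep.iqr,
                         "lower_fence": rep.lower_fence,
                         "upper_fence": rep.upper_fence,
                         "outliers": ",".join(rep.outlier_ids) or "."})
    return pd.DataFrame(rows, columns=["site_class", "metric", "q1", "q3",
                                       "iqr", "lower_fence", "upper_fence",
                                       "outliers"])


def at_percent_distribution(genomes: Iterable[Mitogenome]):
    """Per-genome whole-molecule AT% with a min/max summary attribute."""
    import pandas as pd

    rows = [{"genome_id": g.id, "AT_pct": composition(g).at_percent}
            for g in genomes]
    if not rows:
        raise ValueError("no genomes")
    df = pd.DataFrame(rows, columns=["genome_id", "AT_pct"])
    df.attrs["min"] = float(df["AT_pct"].min())
    df.attrs["max"] = float(df["AT_pct"].max())
    return df
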