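"""Reading, writing and name-normalization of annotated mitogenomes.

GenBank flat files are parsed with Biopython; heterogeneous gene labels
(``COI``, ``ND4L``, ``tRNA-Leu(UUR)``, ``16S ribosomal RNA`` ...) are
mapped onto the closed canonical vocabulary of :mod:`mitocomp.vocab`.
Coordinates are 0-based half-open internally; the 1-based inclusive
GenBank convention is converted at the I/O boundary.  A feature may span
the origin of a circular molecule, in which case it carries two spans
(tail of the sequence, then head).

The J-strand ("majority" strand) is anchored to the strand that encodes
cox1: if a record deposits cox1 on the minus strand, all strand labels
are flipped so that cox1 is J.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import vocab

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "Mitogenome",
    "ParseError",
    "DuplicateGeneError",
    "normalize_gene_name",
    "parse_genbank",
    "coding_sequence",
    "write_genbank",
    "write_fasta",
    "read_fasta_with_features",
    "write_feature_table",
]

COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                           "TGCAYRMKVHDBNtgcayrmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when a genome file cannot be interpreted."""


class DuplicateGeneError(ParseError):
    """Two annotations map to the same canonical gene."""


@dataclass
class GeneFeature:
    """One annotated gene.

    ``spans`` are 0-based half-open intervals on the deposited sequence,
    listed in mRNA-sense concatenation order *before* reverse
    complementing (so ``coding_sequence`` is the reverse complement of
    their concatenation for N-strand genes).  A feature wrapping the
    origin of a circular genome has two spans.
    """

    gene: Optional[str]          # canonical key, or None if unmappable
    strand: str                  # "J" or "N"
    spans: list[tuple[int, int]]
    anticodon: Optional[str] = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError("feature without spans")
        for s, e in self.spans:
            if s >= e:
                raise ValueError(f"empty span ({s}, {e}) in {self.source_label!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)

    def genomic_interval(self, genome_length: int) -> tuple[int, int]:
        """Occupied interval ``(start, end)`` on the circle.

        ``end`` may exceed ``genome_length`` for origin-wrapping
        features (unwrapped coordinates).
        """
        spans = sorted(self.spans)
        if len(spans) == 2 and spans[1][1] == genome_length and spans[0][0] == 0:
            # wraps the origin: tail piece then head piece
            return spans[1][0], genome_length + spans[0][1]
        return spans[0][0], spans[-1][1]


@dataclass
class Mitogenome:
    """A circular annotated mitochondrial DNA sequence."""

    id: str
    organism: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.spans:
                if e > n:
                    raise ParseError(
                        f"{self.id}: feature {f.source_label or f.gene!r} "
                        f"coordinate {e} beyond sequence length {n}"
                    )

    @property
    def n_runs(self) -> int:
        """Number of stretches of undetermined (N) nucleotides."""
        return len(re.findall(r"N+", self.sequence.upper()))

    def feature_for(self, gene: str) -> GeneFeature:
        for f in self.features:
            if f.gene == gene:
                return f
        raise KeyError(f"{self.id}: gene {gene!r} not annotated")

    def has_gene(self, gene: str) -> bool:
        return any(f.gene == gene for f in self.features)


# ---------------------------------------------------------------------------
# gene-name normalization

_AA3_TO_TRN = {
    "ALA": "trnA", "ARG": "trnR", "ASN": "trnN", "ASP": "trnD",
    "CYS": "trnC", "GLU": "trnE", "GLN": "trnQ", "GLY": "trnG",
    "HIS": "trnH", "ILE": "trnI", "LYS": "trnK", "MET": "trnM",
    "PHE": "trnF", "PRO": "trnP", "THR": "trnT", "TRP": "trnW",
    "TYR": "trnY", "VAL": "trnV",
}
_AA1_TO_TRN = {
    "A": "trnA", "R": "trnR", "N": "trnN", "D": "trnD", "C": "trnC",
    "E": "trnE", "Q": "trnQ", "G": "trnG", "H": "trnH", "I": "trnI",
    "K": "trnK", "M": "trnM", "F": "trnF", "P": "trnP", "T": "trnT",
    "W": "trnW", "Y": "trnY", "V": "trnV",
}

_SYNONYMS = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cytochromecoxidasesubunit1": "cox1", "cytochromecoxidasesubuniti": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cytochromecoxidasesubunit2": "cox2", "cytochromecoxidasesubunitii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytochromecoxidasesubunit3": "cox3", "cytochromecoxidasesubunitiii": "cox3",
    "cob": "cob", "cytb": "cob", "cyb": "cob", "cytochromeb": "cob",
    "nad1": "nad1", "nd1": "nad1", "nadhdehydrogenasesubunit1": "nad1",
    "nad2": "nad2", "nd2": "nad2", "nadhdehydrogenasesubunit2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nadhdehydrogenasesubunit3": "nad3",
    "nad4": "nad4", "nd4": "nad4", "nadhdehydrogenasesubunit4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L", "nadhdehydrogenasesubunit4l": "nad4L",
    "nad5": "nad5", "nd5": "nad5", "nadhdehydrogenasesubunit5": "nad5",
    "nad6": "nad6", "nd6": "nad6", "nadhdehydrogenasesubunit6": "nad6",
    "atp6": "atp6", "atpase6": "atp6", "atpsynthasef0subunit6": "atp6",
    "atpsynthasesubunit6": "atp6",
    "atp8": "atp8", "atpase8": "atp8", "atpsynthasef0subunit8": "atp8",
    "atpsynthasesubunit8": "atp8",
    "rrnl": "rrnL", "16s": "rrnL", "lrrna": "rrnL", "16srrna": "rrnL",
    "16sribosomalrna": "rrnL", "largesubunitribosomalrna": "rrnL", "lsu": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "srrna": "rrnS", "12srrna": "rrnS",
    "12sribosomalrna": "rrnS", "smallsubunitribosomalrna": "rrnS", "ssu": "rrnS",
    "cr": "CR", "dloop": "CR", "controlregion": "CR", "atrich": "CR",
    "atrichregion": "CR", "putativecontrolregion": "CR",
}

# codon-family suffixes that disambiguate the Leu / Ser isoacceptors
_FAMILY_SUFFIX = {
    ("L", "uur"): "trnL2", ("L", "cun"): "trnL1",
    ("S", "agn"): "trnS1", ("S", "ucn"): "trnS2",
    ("L", "taa"): "trnL2", ("L", "uaa"): "trnL2",
    ("L", "tag"): "trnL1", ("L", "uag"): "trnL1",
    ("S", "gct"): "trnS1", ("S", "gcu"): "trnS1",
    ("S", "tga"): "trnS2", ("S", "uga"): "trnS2",
    ("L", "1"): "trnL1", ("L", "2"): "trnL2",
    ("S", "1"): "trnS1", ("S", "2"): "trnS2",
}


def _squash(label: str) -> str:
    return re.sub(r"[^a-z0-9]", "", label.lower())


def normalize_gene_name(raw_label: str, anticodon: Optional[str] = None) -> Optional[str]:
    """Map a raw annotation label to a canonical gene key, or ``None``.

    Matching is case-insensitive and punctuation-insensitive.  Leucine
    and serine tRNAs are disambiguated by the ``anticodon`` argument or
    by a codon-family / numeric suffix in the label (``tRNA-Leu(UUR)``,
    ``trnS1``); with neither, ``None`` is returned with a warning — the
    isoacceptor is never guessed.
    """
    if raw_label is None:
        return None
    label = raw_label.strip()

    # compact isoacceptor labels: trnSuga, trnLuaa, trnL-uag ...
    m = re.match(r"^trn([LS])[-_ ]?(uaa|uag|uga|gcu|taa|tag|tga|gct)$",
                 label, re.IGNORECASE)
    if m:
        return vocab.LEU_SER_BY_ANTICODON[
            (m.group(1).upper(), m.group(2).lower().replace("t", "u"))]

    # tRNA labels: trnX, tRNA-Xxx, tRNA Xxx(UUR), trnL1 ...
    m = re.match(
        r"^(?:trna[-_ ]?|trn)\s*([A-Za-z]{1,3})\s*[-_ ]?\(?([A-Za-z0-9]{1,3})?\)?$",
        label, re.IGNORECASE,
    )
    if m:
        aa_raw, suffix = m.group(1).upper(), m.group(2)
        if aa_raw in _AA3_TO_TRN:
            return _AA3_TO_TRN[aa_raw]
        if len(aa_raw) == 1 and aa_raw in _AA1_TO_TRN:
            return _AA1_TO_TRN[aa_raw]
        one = {"LEU": "L", "SER": "S", "L": "L", "S": "S"}.get(aa_raw)
        if one is not None:
            if anticodon:
                key = vocab.LEU_SER_BY_ANTICODON.get(
                    (one, anticodon.lower().replace("t", "u")))
                if key:
                    return key
            if suffix:
                key = _FAMILY_SUFFIX.get((one, suffix.lower()))
                if key:
                    return key
            logger.warning(
                "ambiguous %s tRNA %r: no anticodon or codon-family suffix; "
                "left unmapped", "leucine" if one == "L" else "serine", raw_label)
            return None

    squashed = _squash(label)
    if squashed in _SYNONYMS:
        return _SYNONYMS[squashed]
    # canonical keys map to themselves (incl. trnL1/L2/S1/S2, case-insensitive)
    for key in vocab.ALL_GENES:
        if squashed == key.lower():
            return key
    return None


# ---------------------------------------------------------------------------
# GenBank parsing

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature")


def _location_spans(loc) -> tuple[list[tuple[int, int]], int]:
    """Spans in sense-concatenation order plus the raw strand (+1/-1)."""
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    strand = loc.strand if loc.strand is not None else 1
    spans = [(int(p.start), int(p.end)) for p in parts]
    if strand == -1:
        # Biopython extracts minus-strand compound locations by reverse
        # complementing each part and joining in listed order; store spans
        # so that revcomp(concat(spans)) reproduces that.
        spans = spans[::-1]
    return spans, strand


def _extract_anticodon(feat: SeqFeature) -> Optional[str]:
    for q in ("anticodon", "note", "product"):
        for val in feat.qualifiers.get(q, []):
            m = re.search(r"(?:anticodon[:= ]*|seq:)([acgtu]{3})\b", val, re.IGNORECASE)
            if m:
                return m.group(1).lower().replace("t", "u")
            m = re.search(r"\(([acgtu]{3})\)\s*$", val.strip(), re.IGNORECASE)
            if m and q == "anticodon":
                return m.group(1).lower().replace("t", "u")
    return None


def _feature_label(feat: SeqFeature) -> str:
    for q in ("gene", "product", "note", "standard_name"):
        if feat.qualifiers.get(q):
            return feat.qualifiers[q][0]
    return feat.type


def parse_genbank(path, duplicate_policy: str = "error") -> Mitogenome:
    """Parse a GenBank flat file into a :class:`Mitogenome`.

    CDS / tRNA / rRNA / D-loop features are mapped to canonical gene
    keys via :func:`normalize_gene_name`; unmappable features are
    retained with ``gene=None`` and logged.  ``duplicate_policy`` is
    ``"error"`` (default: two annotations for one gene raise
    :class:`DuplicateGeneError`) or ``"first"`` (keep the first, warn).
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
        seq = str(record.seq).upper()
    except Exception as exc:  # noqa: BLE001 - re-raise uniformly
        raise ParseError(f"{path}: not a readable GenBank record ({exc})") from exc
    if not seq:
        raise ParseError(f"{path}: record has no ORIGIN sequence")

    circular = record.annotations.get("topology", "circular") == "circular"
    organism = record.annotations.get("organism", "")

    # J-strand := strand carrying cox1 (fall back to plus strand)
    cox1_strand = 1
    for feat in record.features:
        if feat.type == "CDS" and normalize_gene_name(_feature_label(feat)) == "cox1":
            cox1_strand = feat.location.strand or 1
            break

    features: list[GeneFeature] = []
    seen: dict[str, GeneFeature] = {}
    for feat in record.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        label = _feature_label(feat)
        if feat.type == "misc_feature" and normalize_gene_name(label) != "CR":
            continue
        anticodon = _extract_anticodon(feat) if feat.type == "tRNA" else None
        if feat.type == "D-loop":
            gene: Optional[str] = "CR"
        else:
            gene = normalize_gene_name(label, anticodon)
        if gene is None:
            logger.warning("%s: unmappable feature %r retained with null gene key",
                           record.id, label)
        spans, raw_strand = _location_spans(feat.location)
        for s, e in spans:
            if e > len(seq):
                raise ParseError(
                    f"{path}: feature {label!r} coordinate {e} beyond "
                    f"sequence length {len(seq)}")
        strand = "J" if raw_strand == cox1_strand else "N"
        gf = GeneFeature(gene=gene, strand=strand, spans=spans,
                         anticodon=anticodon, source_label=label)
        if gene is not None:
            if gene in seen:
                if duplicate_policy == "first":
                    logger.warning("%s: duplicate annotation for %s (%r); keeping first",
                                   record.id, gene, label)
                    continue
                raise DuplicateGeneError(
                    f"{record.id}: duplicate annotation for {gene} ({label!r})")
            seen[gene] = gf
        features.append(gf)

    return Mitogenome(id=record.id or record.name, organism=organism,
                      sequence=seq, circular=circular, features=features)


def coding_sequence(genome: Mitogenome, gene: str) -> str:
    """mRNA-sense sequence of ``gene`` (reverse-complemented for N-strand)."""
    feat = genome.feature_for(gene)
    raw = "".join(genome.sequence[s:e] for s, e in feat.spans)
    return revcomp(raw) if feat.strand == "N" else raw


# ---------------------------------------------------------------------------
# writing

_CLASS_TO_GBTYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control": "D-loop"}


def _to_seqrecord(genome: Mitogenome) -> SeqRecord:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description=f"{genome.organism} mitochondrion, complete genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    rec.annotations["organism"] = genome.organism
    rec.annotations["date"] = "01-JAN-2020"  # fixed: keeps output reproducible
    for f in genome.features:
        raw_strand = 1 if f.strand == "J" else -1
        spans = f.spans if raw_strand == 1 else f.spans[::-1]
        locs = [SimpleLocation(s, e, strand=raw_strand) for s, e in spans]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        gbtype = _CLASS_TO_GBTYPE[vocab.feature_class(f.gene)] if f.gene else "misc_feature"
        quals: dict[str, list[str]] = {"gene": [f.gene or f.source_label or "unknown"]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        rec.features.append(SeqFeature(loc, type=gbtype, qualifiers=quals))
    return rec


def write_genbank(genome: Mitogenome, path) -> None:
    SeqIO.write([_to_seqrecord(genome)], str(path), "genbank")


def write_fasta(genome: Mitogenome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id,
                    description=genome.organism)
    SeqIO.write([rec], str(path), "fasta")


FEATURE_TABLE_COLUMNS = ("gene", "strand", "start", "end", "anticodon")


def write_feature_table(genome: Mitogenome, path) -> None:
    """TSV annotation side-channel (1-based inclusive coordinates).

    Origin-wrapping features are written with ``end`` exceeding the
    sequence length (unwrapped), mirroring how they are read back.
    """
    n = len(genome.sequence)
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TABLE_COLUMNS) + "\n")
        for f in genome.features:
            s, e = f.genomic_interval(n)
            fh.write("\t".join([
                f.gene or f.source_label or ".",
                f.strand, str(s + 1), str(e), f.anticodon or ".",
            ]) + "\n")


def read_fasta_with_features(fasta_path, table_path,
                             genome_id: Optional[str] = None) -> Mitogenome:
    """Read a bare FASTA plus the TSV feature-table dialect."""
    rec = SeqIO.read(str(fasta_path), "fasta")
    seq = str(rec.seq).upper()
    n = len(seq)
    features: list[GeneFeature] = []
    with open(table_path) as fh:
        header = fh.readline().strip().split("\t")
        if tuple(header) != FEATURE_TABLE_COLUMNS:
            raise ParseError(f"{table_path}: bad feature-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(f"{table_path}:{lineno}: expected 5 columns")
            gene_raw, strand, start_s, end_s, anticodon = fields
            start, end = int(start_s) - 1, int(end_s)
            if end > n:  # wraps the origin: tail piece then head piece
                spans = [(start, n), (0, end - n)]
            else:
                spans = [(start, end)]
            gene = normalize_gene_name(gene_raw,
                                       None if anticodon == "." else anticodon)
            features.append(GeneFeature(
                gene=gene, strand=strand, spans=spans,
                anticodon=None if anticodon == "." else anticodon,
                source_label=gene_raw))
    return Mitogenome(id=genome_id or rec.id, organism=rec.description,
                      sequence=seq, circular=True, features=features)
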