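"""Circular signed gene orders: extraction, comparison, model classification.

A gene order is a circular sequence of ``(gene, strand)`` pairs.  Orders
are canonicalized by rotating cox1 (fallback: cob, rrnL, then the
lexicographically smallest gene) to the front in J orientation; if the
anchor lies on the N strand the whole order is reversed and
strand-flipped first, so a genome and its mirror-deposited twin
canonicalize identically.

Rearrangement detection computes the longest common subsequence (LCS)
of signed elements between the canonical rotations of two orders
(anchor fixed).  Genes outside the LCS are *displaced*: strand-flipped
ones are reported as inverted, same-strand ones as translocated.  Ties
between equally long LCSs are broken deterministically: first maximize
the number of protein-coding + rRNA genes kept, then take the
lexicographically smallest displaced gene set.  For signed permutations
of a common gene set the complement of a maximum common subsequence is
a minimum set of genes whose removal makes the orders identical, so the
displaced-set size is exact; only the choice among equally small sets
is a convention.

The model catalog covers the gene-order models described for
springtails: the ancestral Pancrustacea arrangement plus named derived
models.  Models whose complete signed arrangement is derivable from
their published description are fully specified and eligible for exact
matching; the rest carry an *edit signature* (which genes are deleted /
inverted / translocated relative to the Pancrustacea order) and are
matched on that signature alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import vocab
from .genome_io import Mitogenome

logger = logging.getLogger(__name__)

__all__ = [
    "GeneOrder",
    "GeneOrderModel",
    "RearrangementReport",
    "Classification",
    "PANCRUSTACEA_ORDER",
    "BASE_MODEL_NAME",
    "canonicalize",
    "extract_gene_order",
    "compare_orders",
    "classify_order",
    "default_catalog",
    "load_catalog",
    "write_catalog",
]

SignedGene = tuple[str, str]  # (canonical key, "J" | "N")

#: the ancestral Pancrustacea arrangement: 13 PCGs, 22 tRNAs, 2 rRNAs
#: and the control region, J-oriented at cox1
PANCRUSTACEA_ORDER: tuple[SignedGene, ...] = (
    ("cox1", "J"), ("trnL2", "J"), ("cox2", "J"), ("trnK", "J"), ("trnD", "J"),
    ("atp8", "J"), ("atp6", "J"), ("cox3", "J"), ("trnG", "J"), ("nad3", "J"),
    ("trnA", "J"), ("trnR", "J"), ("trnN", "J"), ("trnS1", "J"), ("trnE", "J"),
    ("trnF", "N"), ("nad5", "N"), ("trnH", "N"), ("nad4", "N"), ("nad4L", "N"),
    ("trnT", "J"), ("trnP", "N"), ("nad6", "J"), ("cob", "J"), ("trnS2", "J"),
    ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"), ("trnV", "N"), ("rrnS", "N"),
    ("CR", "J"), ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"),
)

BASE_MODEL_NAME = "Pancrustacea model"

ANCHOR_PRIORITY = ("cox1", "cob", "rrnL")


class OrderError(ValueError):
    """Raised for uninformative or malformed gene-order comparisons."""


@dataclass
class GeneOrder:
    """Canonical circular signed gene order of one genome."""

    genome_id: str
    order: tuple[SignedGene, ...]
    complete: bool = False

    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.order)

    def strand_of(self, gene: str) -> str:
        for g, s in self.order:
            if g == gene:
                return s
        raise KeyError(gene)


@dataclass
class GeneOrderModel:
    """A named gene-order model.

    ``order`` is the full signed arrangement for fully specified models.
    ``signature`` holds one or more alternative edit signatures (dicts
    with keys among deleted/inverted/translocated/displaced mapping to
    gene sets) for models known only from a rearrangement description;
    ``signature is None`` marks a model that cannot be matched
    automatically (its description names no gene set).
    """

    name: str
    order: Optional[tuple[SignedGene, ...]] = None
    fully_specified: bool = False
    signature: Optional[tuple[dict[str, frozenset[str]], ...]] = None
    note: str = ""


@dataclass
class RearrangementReport:
    deleted: frozenset[str]
    inserted: frozenset[str]
    inverted: frozenset[str]
    translocated: frozenset[str]
    anchored_lcs_length: int
    breakpoints: int

    @property
    def displaced(self) -> frozenset[str]:
        return self.inverted | self.translocated

    def is_empty(self) -> bool:
        return not (self.deleted or self.inserted or self.inverted
                    or self.translocated)


@dataclass
class Classification:
    genome_id: str
    model_name: str            # catalog model name or "novel"
    match: str                 # exact | compatible | signature | novel
    missing_genes: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# canonical form

def flip(order: Sequence[SignedGene]) -> tuple[SignedGene, ...]:
    """Read the circular order from the opposite strand."""
    return tuple((g, "J" if s == "N" else "N") for g, s in reversed(order))


def canonicalize(order: Sequence[SignedGene],
                 anchor: Optional[str] = None) -> tuple[SignedGene, ...]:
    """Rotate ``anchor`` to the front in J orientation.

    Without an explicit anchor the first present gene of
    ``(cox1, cob, rrnL)`` is used, falling back to the lexicographically
    smallest gene.
    """
    order = tuple(order)
    if not order:
        return order
    genes = {g for g, _ in order}
    if anchor is None:
        for cand in ANCHOR_PRIORITY:
            if cand in genes:
                anchor = cand
                break
        else:
            anchor = min(genes)
            logger.info("no priority anchor present; anchoring at %s", anchor)
    if anchor not in genes:
        raise OrderError(f"anchor gene {anchor} absent from order")
    idx = next(i for i, (g, _) in enumerate(order) if g == anchor)
    if order[idx][1] == "N":
        order = flip(order)
        idx = next(i for i, (g, _) in enumerate(order) if g == anchor)
    return order[idx:] + order[:idx]


def extract_gene_order(genome: Mitogenome) -> GeneOrder:
    """Circular signed gene order of an annotated genome.

    Features are sorted by circular start coordinate and the order is
    canonicalized (cox1 first, J-oriented).
    """
    mapped = [f for f in genome.features if f.gene is not None]
    if len(mapped) < 3:
        raise OrderError(f"{genome.id}: fewer than 3 mapped features")
    n = len(genome.sequence)
    mapped.sort(key=lambda f: f.genomic_interval(n)[0])
    order = tuple((f.gene, f.strand) for f in mapped)
    genes = {g for g, _ in order}
    if len(genes) != len(order):
        dupes = sorted({g for g, _ in order if sum(1 for h, _ in order if h == g) > 1})
        raise OrderError(f"{genome.id}: duplicate genes in order: {dupes}")
    complete = genes >= set(vocab.ALL_GENES)
    return GeneOrder(genome_id=genome.id, order=canonicalize(order),
                     complete=complete)


# ---------------------------------------------------------------------------
# comparison

_KEEP_PRIORITY = set(vocab.PCGS) | set(vocab.RRNAS)

# cap on optimal-LCS variants tracked per DP cell; beyond it the
# lexicographic tie-break is best-effort (never hit at mitogenome scale)
_MAX_VARIANTS = 64


def _lcs_kept_sets(ref: Sequence[SignedGene],
                   qry: Sequence[SignedGene]) -> tuple[int, list[frozenset[str]]]:
    """All optimal kept-gene sets of the signed LCS (score-pruned).

    Score is (length, #PCG+rRNA kept), maximized lexicographically.
    """
    m, n = len(ref), len(qry)
    NEG = (-1, -1)
    # dp[i][j] = (score, {kept frozensets}) for prefixes ref[:i], qry[:j]
    dp = [[((0, 0), {frozenset()}) for _ in range(n + 1)] for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_score, best_sets = NEG, set()
            if ref[i - 1] == qry[j - 1]:
                g = ref[i - 1][0]
                w = 1 if g in _KEEP_PRIORITY else 0
                (ls, lp), sets = dp[i - 1][j - 1]
                cand = (ls + 1, lp + w)
                best_score = cand
                best_sets = {ks | {g} for ks in sets}
            for (pi, pj) in ((i - 1, j), (i, j - 1)):
                score, sets = dp[pi][pj]
                if score > best_score:
                    best_score, best_sets = score, set(sets)
                elif score == best_score:
                    best_sets |= sets
            if len(best_sets) > _MAX_VARIANTS:
                best_sets = set(sorted(best_sets,
                                       key=lambda s: tuple(sorted(s)))[:_MAX_VARIANTS])
            dp[i][j] = (best_score, best_sets)
    (length, _), sets = dp[m][n]
    return length, sorted(sets, key=lambda s: tuple(sorted(s)))


def _circular_adjacencies(order: Sequence[SignedGene]) -> set:
    """Strand-symmetric signed adjacency set of a circular order."""
    adj = set()
    n = len(order)
    for i in range(n):
        a, b = order[i], order[(i + 1) % n]
        fwd = (a, b)
        rev = ((b[0], "J" if b[1] == "N" else "N"),
               (a[0], "J" if a[1] == "N" else "N"))
        adj.add(min(fwd, rev))
    return adj


def compare_orders(query: GeneOrder, reference: GeneOrder) -> RearrangementReport:
    """Rearrangements of ``query`` relative to ``reference``.

    Deleted/inserted genes come from the set difference (the control
    region is never reported as deleted — it is frequently
    unannotatable).  On the common gene set, displaced genes are the
    complement of the anchored signed LCS; strand-flipped ones are
    inverted, the rest translocated.  Breakpoints count reference
    adjacencies absent from the query (on the common gene set).
    """
    q_genes, r_genes = query.genes(), reference.genes()
    deleted = frozenset(r_genes - q_genes - {"CR"})
    inserted = frozenset(q_genes - r_genes)
    common = q_genes & r_genes
    if len(common) < 3:
        raise OrderError("fewer than 3 genes in common: uninformative comparison")

    anchor = next((g for g in ANCHOR_PRIORITY if g in common), min(common))
    r_red = canonicalize([e for e in reference.order if e[0] in common], anchor)
    q_red = canonicalize([e for e in query.order if e[0] in common], anchor)

    lcs_len, kept_sets = _lcs_kept_sets(r_red, q_red)
    q_strand = {g: s for g, s in q_red}
    r_strand = {g: s for g, s in r_red}
    best = None
    for kept in kept_sets:
        displaced = tuple(sorted(common - kept))
        if best is None or displaced < best:
            best = displaced
    inverted = frozenset(g for g in best if q_strand[g] != r_strand[g])
    translocated = frozenset(g for g in best if q_strand[g] == r_strand[g])

    breakpoints = len(_circular_adjacencies(r_red) - _circular_adjacencies(q_red))
    return RearrangementReport(deleted=deleted, inserted=inserted,
                               inverted=inverted, translocated=translocated,
                               anchored_lcs_length=lcs_len,
                               breakpoints=breakpoints)


# ---------------------------------------------------------------------------
# classification

def _orders_equal(a: Sequence[SignedGene], b: Sequence[SignedGene]) -> bool:
    """Equality of circular signed orders up to rotation / strand of reading."""
    a, b = tuple(a), tuple(b)
    if len(a) != len(b):
        return False
    common = {g for g, _ in a} & {g for g, _ in b}
    if not common:
        return False
    anchor = next((g for g in ANCHOR_PRIORITY if g in common), min(common))
    try:
        return canonicalize(a, anchor) == canonicalize(b, anchor)
    except OrderError:
        return False


def _signature_matches(report: RearrangementReport,
                       sig: dict[str, frozenset[str]]) -> bool:
    if report.inserted:
        return False
    if report.deleted != sig.get("deleted", frozenset()):
        return False
    if "displaced" in sig:
        if report.displaced != sig["displaced"]:
            return False
        extra = {k for k in ("inverted", "translocated") if k in sig}
        return all(getattr(report, k) == sig[k] for k in extra)
    return (report.inverted == sig.get("inverted", frozenset())
            and report.translocated == sig.get("translocated", frozenset()))


def classify_order(query: GeneOrder,
                   catalog: Sequence[GeneOrderModel]) -> Classification:
    """Assign a query order to a catalog model.

    ``exact``: the query equals a fully specified model up to rotation
    (an unannotated control region is tolerated).  ``compatible``: the
    query's genes are a proper subset of a model's and deleting the
    missing genes from the model yields the query order — the model
    with fewest missing genes wins, ties resolved to the base model
    first, then catalog order.  ``signature``: the query's
    rearrangements relative to the base model equal the edit signature
    of a described-but-not-fully-specified model.  Otherwise ``novel``.
    """
    base = next((m for m in catalog if m.name == BASE_MODEL_NAME), None)
    if base is None or base.order is None:
        raise OrderError("catalog must contain the fully specified base model")
    q_genes = query.genes()

    def model_order_for(model: GeneOrderModel) -> Optional[tuple[SignedGene, ...]]:
        if model.order is None:
            return None
        order = model.order
        if "CR" not in q_genes:
            order = tuple(e for e in order if e[0] != "CR")
        return order

    # exact
    for model in catalog:
        if not model.fully_specified or model.order is None:
            continue
        order = model_order_for(model)
        if {g for g, _ in order} == q_genes and _orders_equal(query.order, order):
            return Classification(query.genome_id, model.name, "exact")

    # compatible
    candidates: list[tuple[int, int, GeneOrderModel, frozenset[str]]] = []
    for rank, model in enumerate(catalog):
        order = model_order_for(model)
        if order is None:
            continue
        m_genes = {g for g, _ in order}
        missing = frozenset(m_genes - q_genes)
        if not missing or not q_genes <= m_genes:
            continue
        reduced = tuple(e for e in order if e[0] not in missing)
        if _orders_equal(query.order, reduced):
            tie = -1 if model.name == BASE_MODEL_NAME else rank
            candidates.append((len(missing), tie, model, missing))
    if candidates:
        n_missing, _, model, missing = min(candidates, key=lambda c: (c[0], c[1]))
        return Classification(query.genome_id, model.name, "compatible", missing)

    # signature
    base_order = GeneOrder("<base>", canonicalize(base.order))
    try:
        report = compare_orders(query, base_order)
    except OrderError:
        report = None
    if report is not None:
        for model in catalog:
            if not model.signature:
                continue
            if any(_signature_matches(report, sig) for sig in model.signature):
                return Classification(query.genome_id, model.name, "signature")

    return Classification(query.genome_id, "novel", "novel")


# ---------------------------------------------------------------------------
# order-editing primitives (shared with the synthetic generator)

def delete_gene(order: Sequence[SignedGene], gene: str) -> tuple[SignedGene, ...]:
    if not any(g == gene for g, _ in order):
        raise OrderError(f"delete: gene {gene} absent from order")
    return tuple(e for e in order if e[0] != gene)


def translocate_gene(order: Sequence[SignedGene], gene: str,
                     new_left_neighbor: str) -> tuple[SignedGene, ...]:
    """Move ``gene`` (keeping its strand) to just after ``new_left_neighbor``."""
    entry = next((e for e in order if e[0] == gene), None)
    if entry is None:
        raise OrderError(f"translocate: gene {gene} absent from order")
    if gene == new_left_neighbor:
        raise OrderError("translocate: gene cannot neighbor itself")
    rest = [e for e in order if e[0] != gene]
    try:
        pos = next(i for i, (g, _) in enumerate(rest) if g == new_left_neighbor)
    except StopIteration:
        raise OrderError(f"translocate: neighbor {new_left_neighbor} absent") from None
    return tuple(rest[:pos + 1] + [entry] + rest[pos + 1:])


def invert_block(order: Sequence[SignedGene], first: str,
                 last: str) -> tuple[SignedGene, ...]:
    """Invert the contiguous block from ``first`` to ``last`` inclusive.

    The block is reversed and every gene's strand flipped.
    """
    order = tuple(order)
    genes = [g for g, _ in order]
    try:
        i, j = genes.index(first), genes.index(last)
    except ValueError as exc:
        raise OrderError(f"invert: {exc}") from None
    if i > j:  # block wraps the origin: rotate so it does not
        order = order[i:] + order[:i]
        genes = [g for g, _ in order]
        i, j = 0, genes.index(last)
    block = tuple((g, "J" if s == "N" else "N") for g, s in reversed(order[i:j + 1]))
    return order[:i] + block + order[j + 1:]


def swap_genes(order: Sequence[SignedGene], a: str, b: str) -> tuple[SignedGene, ...]:
    """Reciprocal exchange of two genes' positions (strands kept)."""
    genes = [g for g, _ in order]
    try:
        i, j = genes.index(a), genes.index(b)
    except ValueError as exc:
        raise OrderError(f"swap: {exc}") from None
    out = list(order)
    out[i], out[j] = out[j], out[i]
    return tuple(out)


# ---------------------------------------------------------------------------
# default catalog

def _fs(*genes: str) -> frozenset[str]:
    return frozenset(genes)


def default_catalog() -> list[GeneOrderModel]:
    """The built-in catalog of springtail gene-order models.

    Fully specified: Pancrustacea (ancestral), Tetrodontophora,
    Sminthurinus, GO A, GO D and the Seira sp. 3 model.  The others are
    described in the literature only by their edits relative to the
    ancestral order (sometimes with unknown destination positions) and
    are matched by signature.
    """
    base = PANCRUSTACEA_ORDER

    tetro = translocate_gene(translocate_gene(base, "trnS2", "CR"), "trnQ", "trnS2")
    sminthurinus = invert_block(base, "trnA", "trnR")
    go_d = swap_genes(base, "trnM", "trnI")

    # GO A: trnQ-trnF-trnE-trnS1-trnS2 moved between CR and trnI, with
    # the trnF-trnE-trnS1 block inverted (strands flipped)
    go_a = base
    for g in ("trnQ", "trnF", "trnE", "trnS1", "trnS2"):
        go_a = delete_gene(go_a, g)
    moved = (("trnQ", "N"), ("trnF", "J"), ("trnE", "N"),
             ("trnS1", "N"), ("trnS2", "J"))
    pos = next(i for i, (g, _) in enumerate(go_a) if g == "CR")
    go_a = go_a[:pos + 1] + moved + go_a[pos + 1:]

    # Seira sp. 3: trnA-trnR-trnN-trnS1-trnE region reordered to
    # trnN-trnS1-trnR-trnE-trnA (all J)
    seira3 = list(base)
    region = [i for i, (g, _) in enumerate(seira3)
              if g in ("trnA", "trnR", "trnN", "trnS1", "trnE")]
    for idx, g in zip(region, ("trnN", "trnS1", "trnR", "trnE", "trnA")):
        seira3[idx] = (g, "J")
    seira3 = tuple(seira3)

    smin_anc_inv = _fs("trnP", "trnT")  # Sminthuridae ancestral trnP/trnT inversion

    return [
        GeneOrderModel(BASE_MODEL_NAME, order=base, fully_specified=True,
                       note="ancestral pancrustacean arrangement"),
        GeneOrderModel("Tetrodontophora model", order=canonicalize(tetro),
                       fully_specified=True,
                       signature=({"translocated": _fs("trnS2", "trnQ")},),
                       note="trnS2+trnQ translocation; destination between CR "
                            "and trnI is an interpretation"),
        GeneOrderModel("Podura model", fully_specified=False,
                       signature=({"translocated": _fs("trnC", "trnW", "trnY")},
                                  {"translocated": _fs("trnC", "trnW"),
                                   "deleted": _fs("trnY")}),
                       note="trnC+trnW double translocation; trnY lost or "
                            "translocated (source mtDNA incomplete)"),
        GeneOrderModel("Pseudachorutes model", fully_specified=False,
                       signature=None,
                       note="only springtail model with protein-coding-gene "
                            "translocations; gene set not described, cannot be "
                            "matched automatically"),
        GeneOrderModel("Sminthurinus model", order=canonicalize(sminthurinus),
                       fully_specified=True,
                       signature=({"inverted": _fs("trnA", "trnR")},),
                       note="inversion between trnA and trnR, encoded as "
                            "inversion of the two-gene block (interpretation)"),
        GeneOrderModel("GO A", order=canonicalize(go_a), fully_specified=True,
                       note="trnQ-trnF-trnE-trnS1-trnS2 between CR and trnI "
                            "with trnF-trnE-trnS1 inverted"),
        GeneOrderModel("GO B", fully_specified=False,
                       signature=({"translocated": _fs("trnC", "trnW")},),
                       note="trnW and trnC translocated to unknown positions"),
        GeneOrderModel("GO C", fully_specified=False,
                       signature=({"inverted": smin_anc_inv,
                                   "translocated": _fs("trnD")},),
                       note="putative Sminthuridae ancestral arrangement: "
                            "trnP/trnT inversion + trnD translocation"),
        GeneOrderModel("GO D", order=canonicalize(go_d), fully_specified=True,
                       note="reciprocal exchange of trnM and trnI"),
        GeneOrderModel("Sminthurus model", fully_specified=False,
                       signature=({"inverted": smin_anc_inv,
                                   "translocated": _fs("trnD", "trnF")},),
                       note="Sminthuridae ancestral edits + trnF translocation"),
        GeneOrderModel("Allacma model", fully_specified=False,
                       signature=({"inverted": smin_anc_inv,
                                   "translocated": _fs("trnD", "trnY", "trnL2")},),
                       note="Sminthuridae ancestral edits + trnY and trnL2 "
                            "translocations"),
        GeneOrderModel("Lipothrix model", fully_specified=False,
                       signature=({"inverted": smin_anc_inv,
                                   "translocated": _fs("trnD", "trnQ", "trnY",
                                                       "trnC", "trnI")},),
                       note="Sminthuridae ancestral edits + trnQ, trnY, trnC, "
                            "trnI translocations"),
        GeneOrderModel("Trogolaphysa model", fully_specified=False,
                       signature=({"deleted": _fs("trnS1"),
                                   "displaced": _fs("trnN", "trnE")},),
                       note="inversion plus deletion yielding a "
                            "trnE-trnN-trnA-trnR arrangement; strands of the "
                            "inverted genes not recoverable from the description"),
        GeneOrderModel("Seira sp. 3 model", order=canonicalize(seira3),
                       fully_specified=True,
                       note="translocation yielding trnN-trnS1-trnR-trnE-trnA"),
        GeneOrderModel("Seira paraibensis model", fully_specified=False,
                       signature=({"deleted": _fs("rrnS"),
                                   "translocated": _fs("rrnL")},),
                       note="rrnS deletion and rrnL translocation"),
    ]


# ---------------------------------------------------------------------------
# catalog I/O

_CATALOG_COLUMNS = ("model_name", "fully_specified", "order", "signature_json", "note")


def _order_to_str(order: Optional[Sequence[SignedGene]]) -> str:
    if order is None:
        return "."
    return ",".join(f"{g}:{s}" for g, s in order)


def _order_from_str(text: str, lineno: int) -> Optional[tuple[SignedGene, ...]]:
    if text == ".":
        return None
    out = []
    for token in text.split(","):
        try:
            g, s = token.split(":")
        except ValueError:
            raise OrderError(f"line {lineno}: bad order token {token!r}") from None
        if not vocab.is_valid(g):
            raise OrderError(f"line {lineno}: unknown gene token {g!r}")
        if s not in ("J", "N"):
            raise OrderError(f"line {lineno}: bad strand {s!r} for {g}")
        out.append((g, s))
    return tuple(out)


def write_catalog(catalog: Sequence[GeneOrderModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for m in catalog:
            if m.signature is None:
                sig = "."
            else:
                sig = json.dumps([{k: sorted(v) for k, v in s.items()}
                                  for s in m.signature])
            fh.write("\t".join([
                m.name, "1" if m.fully_specified else "0",
                _order_to_str(m.order), sig, m.note or ".",
            ]) + "\n")


def load_catalog(path=None) -> list[GeneOrderModel]:
    """Load a catalog TSV; with no path, return the built-in catalog."""
    if path is None:
        return default_catalog()
    models: list[GeneOrderModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CATALOG_COLUMNS:
            raise OrderError(f"{path}: bad catalog header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_CATALOG_COLUMNS):
                raise OrderError(f"{path}: line {lineno}: expected "
                                 f"{len(_CATALOG_COLUMNS)} columns")
            name, fs_flag, order_s, sig_s, note = fields
            order = _order_from_str(order_s, lineno)
            if sig_s == ".":
                signature = None
            else:
                raw = json.loads(sig_s)
                for sig in raw:
                    for genes in sig.values():
                        for g in genes:
                            if not vocab.is_valid(g):
                                raise OrderError(
                                    f"{path}: line {lineno}: unknown gene "
                                    f"token {g!r} in signature")
                signature = tuple({k: frozenset(v) for k, v in s.items()}
                                  for s in raw)
            models.append(GeneOrderModel(
                name=name, order=order, fully_specified=fs_flag == "1",
                signature=signature, note="" if note == "." else note))
    if not models:
        raise OrderError(f"{path}: empty catalog")
    return models


def classification_table(classifications: Iterable[Classification]):
    """Per-genome classification table (pandas DataFrame)."""
    import pandas as pd

    rows = [{
        "genome_id": c.genome_id,
        "model": c.model_name,
        "match": c.match,
        "missing_genes": ",".join(sorted(c.missing_genes)) or ".",
    } for c in classifications]
    return pd.DataFrame(rows, columns=["genome_id", "model", "match",
                                       "missing_genes"])
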