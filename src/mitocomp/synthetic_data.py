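"""Seeded synthetic mitogenome generator.

Builds fully annotated circular genomes with a known gene order
(optionally rearranged by an edit script), known per-class nucleotide
composition, and a planned architecture (start/stop codons, intergenic
spacers, gene overlaps), so that every downstream stage — parsing,
architecture summaries, gene-order classification, skew analysis — can
be exercised against ground truth without any external data.

Protein-coding genes are built codon-wise in mRNA sense: the first and
second position bases are drawn from the (J|N)1 and (J|N)2 composition
targets of the gene's strand, and the third position from the 2x3 or
4x3 target according to the degeneracy of the drawn prefix under the
invertebrate mitochondrial code (a TA- prefix restricts the third base
to T/C so no stop codon ever arises internally).  Codons are *not*
constrained to a sensible protein beyond the planned start/stop — the
analyses under test are composition- and order-based.  tRNAs, rRNAs
and the control region are filled with random sequence at a background
composition.  All randomness flows from a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import vocab
from .gene_order import (
    PANCRUSTACEA_ORDER, BASE_MODEL_NAME, GeneOrder, OrderError, SignedGene,
    canonicalize, default_catalog, delete_gene, invert_block, swap_genes,
    translocate_gene,
)
from .genome_io import (
    GeneFeature, Mitogenome, revcomp, write_feature_table, write_fasta,
    write_genbank,
)
from .comp_bias import FOURFOLD_PREFIXES, SITE_CLASSES

__all__ = [
    "Edit",
    "apply_edits",
    "random_edit_script",
    "SyntheticSpec",
    "composition_from_skews",
    "simulate_genome",
    "write_fixture",
]

Edit = tuple  # ("translocate", gene, new_left) | ("invert", first, last)
#              | ("delete", gene) | ("swap", a, b)

_EDIT_ARITY = {"translocate": 2, "invert": 2, "delete": 1, "swap": 2}


def apply_edits(order: Union[GeneOrder, Sequence[SignedGene]],
                edits: Sequence[Edit]) -> tuple[SignedGene, ...]:
    """Apply an edit script left to right; the result is canonicalized.

    Each edit is a tuple: ``("translocate", gene, new_left_neighbor)``,
    ``("invert", first_gene, last_gene)`` (contiguous block),
    ``("delete", gene)`` or ``("swap", gene_a, gene_b)``.
    """
    current = tuple(order.order if isinstance(order, GeneOrder) else order)
    for edit in edits:
        kind, *args = edit
        if kind not in _EDIT_ARITY:
            raise OrderError(f"unknown edit kind {kind!r}")
        if len(args) != _EDIT_ARITY[kind]:
            raise OrderError(f"edit {edit!r}: expected {_EDIT_ARITY[kind]} arguments")
        try:
            if kind == "translocate":
                current = translocate_gene(current, *args)
            elif kind == "invert":
                current = invert_block(current, *args)
            elif kind == "delete":
                current = delete_gene(current, *args)
            else:
                current = swap_genes(current, *args)
        except OrderError as exc:
            raise OrderError(f"edit {edit!r}: {exc}") from None
    return canonicalize(current)


def random_edit_script(rng: np.random.Generator,
                       order: Sequence[SignedGene] = PANCRUSTACEA_ORDER,
                       n_edits: int = 3,
                       kinds: Sequence[str] = ("translocate", "invert"),
                       protect: Sequence[str] = ("cox1",),
                       ) -> tuple[list[Edit], frozenset[str]]:
    """A random edit script touching pairwise non-adjacent genes.

    Returns the script and the set of edited genes.  Single-gene
    translocations move a gene between two genes that are not adjacent
    to it; inversions flip a short contiguous block.  Edited genes are
    kept non-adjacent to one another (and away from the anchor) so each
    edit is independently recoverable.
    """
    genes = [g for g, _ in order]
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    touched: set[str] = set(protect)

    def neighborhood(g: str) -> set[str]:
        i = pos[g]
        return {genes[(i - 1) % n], g, genes[(i + 1) % n]}

    blocked: set[str] = set()
    for g in protect:
        blocked |= neighborhood(g)
    script: list[Edit] = []
    edited: set[str] = set()
    attempts = 0
    while len(script) < n_edits and attempts < 200:
        attempts += 1
        kind = kinds[rng.integers(len(kinds))]
        if kind == "invert":
            size = int(rng.integers(1, 3))  # block of 1 or 2 genes
            start = int(rng.integers(n))
            block = [genes[(start + k) % n] for k in range(size)]
            if any(b in blocked for b in block):
                continue
            script.append(("invert", block[0], block[-1]))
            for b in block:
                edited.add(b)
                blocked |= neighborhood(b)
        else:
            g = genes[int(rng.integers(n))]
            if g in blocked:
                continue
            dest = genes[int(rng.integers(n))]
            # destination must not touch the gene's own neighborhood or
            # any previously edited gene
            if dest in blocked or dest in neighborhood(g) or genes[
                    (pos[dest] + 1) % n] in (neighborhood(g) - {g}):
                continue
            script.append(("translocate", g, dest))
            edited.add(g)
            blocked |= neighborhood(g) | neighborhood(dest)
    return script, frozenset(edited)


# ---------------------------------------------------------------------------
# composition targets

def composition_from_skews(at_fraction: float, at_skew: float,
                           cg_skew: float) -> tuple[float, float, float, float]:
    """Probability vector (A, C, G, T) realizing the given targets."""
    if not 0.0 < at_fraction < 1.0:
        raise ValueError("at_fraction must be in (0, 1)")
    a = at_fraction * (1 + at_skew) / 2
    t = at_fraction * (1 - at_skew) / 2
    c = (1 - at_fraction) * (1 + cg_skew) / 2
    g = (1 - at_fraction) * (1 - cg_skew) / 2
    return (a, c, g, t)


#: default per-class composition targets: AT-rich, mildly skewed on the
#: J strand and oppositely on the N strand, with third-position classes
#: the most variable — echoing the compositional structure typical of
#: springtail mitogenomes
DEFAULT_CLASS_COMPOSITION: dict[str, tuple[float, float, float, float]] = {
    "J1": composition_from_skews(0.66, 0.06, -0.05),
    "N1": composition_from_skews(0.66, -0.20, -0.30),
    "J2": composition_from_skews(0.60, -0.35, 0.27),
    "N2": composition_from_skews(0.60, -0.38, -0.02),
    "2J3": composition_from_skews(0.74, 0.05, 0.45),
    "2N3": composition_from_skews(0.74, -0.12, -0.35),
    "4J3": composition_from_skews(0.78, 0.10, 0.40),
    "4N3": composition_from_skews(0.78, -0.18, -0.30),
}

#: approximate codon counts (start codon included, stop excluded) of
#: invertebrate mitochondrial protein-coding genes
DEFAULT_CODON_COUNTS: dict[str, int] = {
    "cox1": 512, "cox2": 229, "cox3": 262, "cob": 379, "nad1": 312,
    "nad2": 341, "nad3": 117, "nad4": 446, "nad4L": 97, "nad5": 572,
    "nad6": 174, "atp6": 226, "atp8": 53,
}

DEFAULT_RNA_LENGTHS = {"tRNA": 65, "rrnL": 1250, "rrnS": 780, "CR": 600}

#: background composition for tRNA / rRNA / control region / spacers
BACKGROUND_COMPOSITION = composition_from_skews(0.70, 0.02, 0.05)


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic genome.

    ``junction_plan`` maps ``(left_gene, right_gene)`` to a signed gap
    in bp: positive = intergenic spacer, negative = overlap (the later
    gene's sequence takes precedence over the overlapped bases).
    Unlisted junctions get ``default_gap``.
    """

    genome_id: str = "SYNTH"
    organism: str = "Synthetica exemplaris"
    base_order: Union[str, tuple[SignedGene, ...]] = BASE_MODEL_NAME
    edits: tuple[Edit, ...] = ()
    codon_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CODON_COUNTS))
    class_composition: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COMPOSITION))
    start_codons: dict[str, str] = field(default_factory=dict)  # default ATG
    stop_codons: dict[str, str] = field(default_factory=dict)   # default TAA
    rna_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RNA_LENGTHS))
    junction_plan: dict[tuple[str, str], int] = field(default_factory=dict)
    default_gap: int = 2
    offset: int = 0          # rotation of the deposited origin, in bp
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, probs in self.class_composition.items():
            if cls not in SITE_CLASSES:
                raise ValueError(f"unknown site class {cls!r}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"composition for {cls} does not sum to 1")
        for gene, count in self.codon_counts.items():
            if count < 2:
                raise ValueError(f"{gene}: need at least 2 codons")

    def resolved_order(self) -> tuple[SignedGene, ...]:
        if isinstance(self.base_order, str):
            model = next((m for m in default_catalog()
                          if m.name == self.base_order), None)
            if model is None or model.order is None:
                raise ValueError(
                    f"base order {self.base_order!r} is not a fully "
                    f"specified catalog model")
            order = model.order
        else:
            order = tuple(self.base_order)
        return apply_edits(order, self.edits)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "genome_id": self.genome_id,
            "organism": self.organism,
            "base_order": (self.base_order if isinstance(self.base_order, str)
                           else [f"{g}:{s}" for g, s in self.base_order]),
            "edits": [list(e) for e in self.edits],
            "codon_counts": dict(self.codon_counts),
            "class_composition": {k: list(map(float, v))
                                  for k, v in self.class_composition.items()},
            "start_codons": dict(self.start_codons),
            "stop_codons": dict(self.stop_codons),
            "rna_lengths": dict(self.rna_lengths),
            "junction_plan": {f"{l}|{r}": gap
                              for (l, r), gap in self.junction_plan.items()},
            "default_gap": self.default_gap,
            "offset": self.offset,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        base = d.get("base_order", BASE_MODEL_NAME)
        if isinstance(base, list):
            base = tuple(tuple(tok.split(":")) for tok in base)
        junctions = {}
        for key, gap in d.get("junction_plan", {}).items():
            left, right = key.split("|")
            junctions[(left, right)] = int(gap)
        return cls(
            genome_id=d.get("genome_id", "SYNTH"),
            organism=d.get("organism", "Synthetica exemplaris"),
            base_order=base,
            edits=tuple(tuple(e) for e in d.get("edits", [])),
            codon_counts=dict(d.get("codon_counts", DEFAULT_CODON_COUNTS)),
            class_composition={k: tuple(v) for k, v in d.get(
                "class_composition", DEFAULT_CLASS_COMPOSITION).items()},
            start_codons=dict(d.get("start_codons", {})),
            stop_codons=dict(d.get("stop_codons", {})),
            rna_lengths=dict(d.get("rna_lengths", DEFAULT_RNA_LENGTHS)),
            junction_plan=junctions,
            default_gap=int(d.get("default_gap", 2)),
            offset=int(d.get("offset", 0)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# sequence synthesis

def _draw(rng: np.random.Generator, probs, size: int) -> str:
    idx = rng.choice(4, size=size, p=np.asarray(probs) / np.sum(probs))
    return "".join("ACGT"[i] for i in idx)


def _twofold_third_distributions(p1, p2, p2f):
    """Distributions for third positions of two-fold codons.

    TA-prefixed codons (Tyr) can only carry C/T at the third position
    (TAA/TAG are stops), which would bias the realized 2x3 marginal low
    in A/G.  The non-TA two-fold codons therefore draw from a
    compensated distribution ``q`` such that the mixture over prefixes
    reproduces the target ``p2f`` exactly (clamped at zero, with
    renormalization, if the target is structurally unreachable).
    """
    restricted = np.array([0.0, p2f[1], 0.0, p2f[3]])
    if restricted.sum() == 0:
        restricted = np.array([0.0, 0.5, 0.0, 0.5])
    restricted = restricted / restricted.sum()
    twofold_mass = sum(p1[i] * p2[j] for i in range(4) for j in range(4)
                       if "ACGT"[i] + "ACGT"[j] not in FOURFOLD_PREFIXES)
    f_ta = (p1[3] * p2[0]) / twofold_mass if twofold_mass > 0 else 0.0
    if f_ta >= 1.0:
        return restricted, restricted
    q = (np.asarray(p2f) - f_ta * restricted) / (1.0 - f_ta)
    if (q < 0).any():
        q = np.clip(q, 0.0, None)
    q = q / q.sum()
    return restricted, q


def _pcg_sequence(rng: np.random.Generator, spec: SyntheticSpec, gene: str,
                  strand: str) -> str:
    n_codons = spec.codon_counts.get(gene, 150)
    start = spec.start_codons.get(gene, "ATG").upper()
    stop = spec.stop_codons.get(gene, "TAA").upper()
    p1 = np.asarray(spec.class_composition[f"{strand}1"])
    p2 = np.asarray(spec.class_composition[f"{strand}2"])
    p2f = np.asarray(spec.class_composition[f"2{strand}3"])
    p4f = np.asarray(spec.class_composition[f"4{strand}3"])
    ta_probs, q2f = _twofold_third_distributions(p1, p2, p2f)
    codons = [start]
    n_internal = n_codons - 1
    b1 = _draw(rng, p1, n_internal)
    b2 = _draw(rng, p2, n_internal)
    for first, second in zip(b1, b2):
        prefix = first + second
        if prefix in FOURFOLD_PREFIXES:
            third = _draw(rng, p4f, 1)
        elif prefix == "TA":
            third = _draw(rng, ta_probs, 1)
        else:
            third = _draw(rng, q2f, 1)
        codons.append(prefix + third)
    return "".join(codons) + stop


def _gene_length(spec: SyntheticSpec, gene: str) -> int:
    cls = vocab.feature_class(gene)
    if cls == "PCG":
        return 3 * spec.codon_counts.get(gene, 150) + \
            len(spec.stop_codons.get(gene, "TAA"))
    if cls == "tRNA":
        return spec.rna_lengths.get(gene, spec.rna_lengths.get("tRNA", 65))
    if cls == "rRNA":
        return spec.rna_lengths.get(gene, 1000)
    return spec.rna_lengths.get("CR", 600)


def simulate_genome(spec: SyntheticSpec) -> Mitogenome:
    """Generate the annotated genome described by ``spec``.

    Deterministic under ``spec.seed``: identical specs yield
    byte-identical sequences and annotations.
    """
    rng = np.random.default_rng(spec.seed)
    order = spec.resolved_order()
    n_genes = len(order)

    sense: dict[str, str] = {}
    for gene, strand in order:
        if vocab.feature_class(gene) == "PCG":
            sense[gene] = _pcg_sequence(rng, spec, gene, strand)
        else:
            sense[gene] = _draw(rng, BACKGROUND_COMPOSITION,
                                _gene_length(spec, gene))

    # layout on the circle
    lengths = {g: len(sense[g]) for g, _ in order}
    gaps = []
    for i in range(n_genes):
        left, right = order[i][0], order[(i + 1) % n_genes][0]
        gap = spec.junction_plan.get((left, right), spec.default_gap)
        if gap < 0 and -gap >= min(lengths[left], lengths[right]):
            raise ValueError(f"infeasible plan: overlap of {-gap} bp at "
                             f"{left}|{right} exceeds a gene length")
        gaps.append(gap)
    total = sum(lengths.values()) + sum(gaps)
    if total <= 0:
        raise ValueError("infeasible plan: non-positive genome length")

    seq = np.frombuffer(
        _draw(rng, BACKGROUND_COMPOSITION, total).encode(), dtype="S1").copy()
    positions = []
    cursor = 0
    for i, (gene, strand) in enumerate(order):
        deposited = sense[gene] if strand == "J" else revcomp(sense[gene])
        start = cursor % total
        for k, ch in enumerate(deposited):
            seq[(start + k) % total] = ch.encode()
        positions.append((gene, strand, start))
        cursor += lengths[gene] + gaps[i]

    offset = spec.offset % total
    features = []
    for gene, strand, start in positions:
        s = (start + offset) % total
        e = s + lengths[gene]
        if e <= total:
            spans = [(s, e)]
        else:
            spans = [(s, total), (0, e - total)]  # tail then head
        features.append(GeneFeature(gene=gene, strand=strand, spans=spans,
                                    source_label=gene))
    sequence = seq.tobytes().decode()
    sequence = sequence[-offset:] + sequence[:-offset] if offset else sequence
    return Mitogenome(id=spec.genome_id, organism=spec.organism,
                      sequence=sequence, circular=True, features=features)


def write_fixture(genome: Mitogenome, directory,
                  stem: Optional[str] = None) -> dict[str, Path]:
    """Write GenBank + FASTA + feature-table files for a genome."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or genome.id
    paths = {
        "genbank": directory / f"{stem}.gb",
        "fasta": directory / f"{stem}.fasta",
        "features": directory / f"{stem}.features.tsv",
    }
    write_genbank(genome, paths["genbank"])
    write_fasta(genome, paths["fasta"])
    write_feature_table(genome, paths["features"])
    return paths
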