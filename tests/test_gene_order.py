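"""Canonicalization, rearrangement detection and model classification."""

import numpy as np
import pytest

from mitocomp.gene_order import (
    BASE_MODEL_NAME, GeneOrder, OrderError, PANCRUSTACEA_ORDER, canonicalize,
    classify_order, compare_orders, default_catalog, extract_gene_order, flip,
    load_catalog, write_catalog,
)
from mitocomp.synthetic_data import (
    SyntheticSpec, apply_edits, random_edit_script, simulate_genome,
)
from oracles import min_displaced_count

BASE = canonicalize(PANCRUSTACEA_ORDER)
BASE_GO = GeneOrder("<base>", BASE, complete=True)


def _go(order, gid="q"):
    return GeneOrder(gid, canonicalize(order))


class TestCanonicalization:
    def test_rotation_invariant(self):
        rotated = PANCRUSTACEA_ORDER[7:] + PANCRUSTACEA_ORDER[:7]
        assert canonicalize(rotated) == BASE

    def test_strand_flip_invariant(self):
        assert canonicalize(flip(PANCRUSTACEA_ORDER)) == BASE

    def test_anchor_fallback_without_cox1(self):
        order = tuple(e for e in PANCRUSTACEA_ORDER if e[0] != "cox1")
        canon = canonicalize(order)
        assert canon[0] == ("cob", "J")

    def test_extracted_order_matches_base(self, base_genome):
        go = extract_gene_order(base_genome)
        assert go.order == BASE and go.complete

    def test_mirror_deposited_genome_same_order(self):
        spec = SyntheticSpec(seed=13)
        g = simulate_genome(spec)
        from mitocomp.genome_io import Mitogenome, GeneFeature, revcomp

        n = len(g.sequence)
        flipped_feats = []
        for f in g.features:
            spans = [(n - e, n - s) for s, e in f.spans]
            flipped_feats.append(GeneFeature(
                gene=f.gene, strand={"J": "N", "N": "J"}[f.strand],
                spans=spans, source_label=f.source_label))
        twin = Mitogenome(id="twin", organism="", sequence=revcomp(g.sequence),
                          features=flipped_feats)
        assert extract_gene_order(twin).order == extract_gene_order(g).order


class TestCompareOrders:
    def test_identity_is_empty(self):
        rep = compare_orders(BASE_GO, BASE_GO)
        assert rep.is_empty() and rep.breakpoints == 0
        assert rep.anchored_lcs_length == len(BASE)

    def test_identity_for_every_catalog_model(self):
        for model in default_catalog():
            if model.order is None:
                continue
            go = _go(model.order, model.name)
            assert compare_orders(go, go).is_empty(), model.name

    def test_rotation_invariance_of_comparison(self):
        q = PANCRUSTACEA_ORDER[11:] + PANCRUSTACEA_ORDER[:11]
        assert compare_orders(_go(q), BASE_GO).is_empty()

    def test_single_move_tie_broken_lexicographically(self):
        ref = _go((("a", "J"), ("b", "J"), ("c", "J"), ("d", "J")))
        qry = _go((("a", "J"), ("c", "J"), ("b", "J"), ("d", "J")))
        rep = compare_orders(qry, ref)
        assert rep.translocated == {"b"}

    def test_double_trna_translocation(self):
        # two tRNAs moved to unambiguous new homes
        edited = apply_edits(PANCRUSTACEA_ORDER, [
            ("translocate", "trnS2", "trnG"),
            ("translocate", "trnQ", "nad4"),
        ])
        rep = compare_orders(_go(edited), BASE_GO)
        assert rep.translocated == {"trnS2", "trnQ"}
        assert not rep.inverted and not rep.deleted and not rep.inserted

    def test_inversion_reported_with_flipped_strand(self):
        edited = apply_edits(PANCRUSTACEA_ORDER, [("invert", "trnA", "trnR")])
        rep = compare_orders(_go(edited), BASE_GO)
        assert rep.inverted == {"trnA", "trnR"} and not rep.translocated

    def test_deleted_gene_reported(self):
        edited = apply_edits(PANCRUSTACEA_ORDER, [("delete", "trnC")])
        rep = compare_orders(_go(edited), BASE_GO)
        assert rep.deleted == {"trnC"} and rep.is_empty() is False

    def test_control_region_never_deleted(self):
        edited = apply_edits(PANCRUSTACEA_ORDER, [("delete", "CR")])
        rep = compare_orders(_go(edited), BASE_GO)
        assert rep.deleted == frozenset()

    def test_too_few_common_genes_rejected(self):
        a = _go((("a", "J"), ("b", "J"), ("c", "J"), ("d", "J")))
        b = _go((("a", "J"), ("x", "J"), ("y", "J"), ("z", "J")))
        with pytest.raises(OrderError):
            compare_orders(a, b)

    def test_breakpoints_count_disrupted_adjacencies(self):
        edited = apply_edits(PANCRUSTACEA_ORDER,
                             [("translocate", "trnD", "nad4")])
        rep = compare_orders(_go(edited), BASE_GO)
        # one excision (2 adjacencies lost) + one insertion splitting a third
        assert rep.breakpoints == 3

    def test_agrees_with_bruteforce_on_small_signed_orders(self):
        rng = np.random.default_rng(42)
        letters = "abcdefgh"
        for _ in range(150):
            n = int(rng.integers(4, 9))
            genes = list(letters[:n])
            ref = tuple((g, "JN"[rng.integers(2)]) for g in genes)
            perm = rng.permutation(n)
            qry = tuple((genes[i], "JN"[rng.integers(2)]) for i in perm)
            # anchor must share orientation handling: canonicalize both
            ref_go, qry_go = _go(ref, "r"), _go(qry, "q")
            rep = compare_orders(qry_go, ref_go)
            oracle = min_displaced_count(ref_go.order, qry_go.order, "a")
            assert len(rep.displaced) == oracle, (ref, qry)

    def test_edit_recovery_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            k = int(rng.integers(1, 5))  # up to 4 non-adjacent edits
            script, edited = random_edit_script(rng, n_edits=k)
            q = apply_edits(PANCRUSTACEA_ORDER, script)
            rep = compare_orders(_go(q), BASE_GO)
            assert rep.displaced == edited, script


class TestClassification:
    CATALOG = default_catalog()

    def test_exact_base_model(self):
        c = classify_order(BASE_GO, self.CATALOG)
        assert (c.model_name, c.match) == (BASE_MODEL_NAME, "exact")

    def test_missing_trnc_is_compatible(self):
        order = apply_edits(PANCRUSTACEA_ORDER, [("delete", "trnC")])
        c = classify_order(_go(order, "Tmix"), self.CATALOG)
        assert (c.model_name, c.match) == (BASE_MODEL_NAME, "compatible")
        assert c.missing_genes == {"trnC"}

    def test_missing_control_region_still_exact(self):
        order = apply_edits(PANCRUSTACEA_ORDER, [("delete", "CR")])
        c = classify_order(_go(order), self.CATALOG)
        assert (c.model_name, c.match) == (BASE_MODEL_NAME, "exact")

    def test_every_fully_specified_model_self_classifies(self):
        for model in self.CATALOG:
            if not model.fully_specified:
                continue
            c = classify_order(_go(model.order, model.name), self.CATALOG)
            assert (c.model_name, c.match) == (model.name, "exact")

    def test_signature_matching_lipothrix(self):
        # Sminthuridae ancestral trnP/trnT inversion + trnD translocation,
        # then the four extra translocations diagnostic of this model
        order = apply_edits(PANCRUSTACEA_ORDER, [
            ("invert", "trnT", "trnP"),
            ("translocate", "trnD", "cox3"),
            ("translocate", "trnQ", "nad3"),
            ("translocate", "trnY", "trnH"),
            ("translocate", "trnC", "cob"),
            ("translocate", "trnI", "trnL2"),
        ])
        c = classify_order(_go(order), self.CATALOG)
        assert (c.model_name, c.match) == ("Lipothrix model", "signature")

    def test_novel_arrangement(self):
        from mitocomp.gene_order import swap_genes

        order = canonicalize(swap_genes(PANCRUSTACEA_ORDER, "nad2", "cob"))
        c = classify_order(_go(order), self.CATALOG)
        assert (c.model_name, c.match) == ("novel", "novel")


class TestCatalog:
    def test_default_catalog_size_and_base(self):
        catalog = default_catalog()
        assert len(catalog) >= 13
        names = [m.name for m in catalog]
        assert BASE_MODEL_NAME in names
        base = catalog[names.index(BASE_MODEL_NAME)]
        assert base.fully_specified and len(base.order) == 38

    def test_roundtrip_tsv(self, tmp_path):
        catalog = default_catalog()
        write_catalog(catalog, tmp_path / "cat.tsv")
        back = load_catalog(tmp_path / "cat.tsv")
        assert [m.name for m in back] == [m.name for m in catalog]
        assert all(a.order == b.order and a.signature == b.signature
                   and a.fully_specified == b.fully_specified
                   for a, b in zip(back, catalog))

    def test_unknown_gene_token_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("model_name\tfully_specified\torder\tsignature_json\tnote\n"
                     "X model\t1\tcox1:J,frobnicase:J,cob:J\t.\t.\n")
        with pytest.raises(OrderError, match="frobnicase"):
            load_catalog(p)

    def test_empty_catalog_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("model_name\tfully_specified\torder\tsignature_json\tnote\n")
        with pytest.raises(OrderError, match="empty"):
            load_catalog(p)

    def test_user_extension(self, tmp_path):
        catalog = default_catalog()
        write_catalog(catalog, tmp_path / "cat.tsv")
        with open(tmp_path / "cat.tsv", "a") as fh:
            fh.write("My model\t0\t.\t"
                     '[{"translocated": ["trnV"]}]\t.\n')
        back = load_catalog(tmp_path / "cat.tsv")
        assert len(back) == len(catalog) + 1
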