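"""Toxin-name grammar: building, parsing, batch assignment."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from venomkit import refdata
from venomkit.nomenclature import (
    GREEK_BY_NAME,
    SeqEntry,
    assign_names,
    build_peptide_name,
    build_protein_name,
    normalize_spelling,
    parse_name,
    transliterate,
)


class TestBuildPeptideName:
    def test_greek_prefix_with_variant(self):
        name = build_peptide_name(
            "delta", "paraponeritoxin", "Paraponera", "clavata", 1, "e", 2
        )
        assert name == "δ-paraponeritoxin-Pc1e_2"

    def test_unknown_activity_prefix(self):
        name = build_peptide_name(
            "U", "paraponeritoxin", "Paraponera", "clavata", 1, "a", prefix_index=1
        )
        assert name == "U1-paraponeritoxin-Pc1a"

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_peptide_name("delta", "", "Paraponera", "clavata", 1, "a")


class TestBuildProteinName:
    def test_generic_name_hyphenated_and_capitalised(self):
        name = build_protein_name("phospholipase A2", 1, "a", "Paraponera", "clavata", 1)
        assert name == "Phospholipase-A2-1a_1-P-clavata"

    def test_without_variant(self):
        name = build_protein_name("serine protease", 5, "a", "Paraponera", "clavata")
        assert name == "Serine-protease-5a-P-clavata"

    def test_uncharacterised_prefix(self):
        assert build_protein_name("U", 1, "a", "Paraponera", "clavata") == "U-1a-P-clavata"


class TestParseName:
    def test_peptide_components(self):
        n = parse_name("δ-paraponeritoxin-Pc1e_2")
        assert n.kind == "peptide"
        assert n.activity_prefix == "δ"
        assert n.toxin_stem == "paraponeritoxin"
        assert n.species_code == "Pc"
        assert (n.family, n.isoform, n.nt_variant) == (1, "e", 2)

    def test_protein_components_spelling_preserved_verbatim(self):
        n = parse_name("Hyalyronidase-1a_1-P-clavata")
        assert n.kind == "protein"
        assert n.generic_name == "Hyalyronidase"
        assert (n.family, n.isoform, n.nt_variant) == (1, "a", 1)
        assert n.genus_initial == "P" and n.species == "clavata"

    def test_unknown_prefix_with_subscript_artefacts(self):
        for raw in ("U_1_-Paraponeritoxin-Pc1a", "U₁-paraponeritoxin-Pc1a"):
            n = parse_name(raw)
            assert n.activity_prefix == "U" and n.prefix_index == 1

    @pytest.mark.parametrize("name", refdata.PUBLISHED_TOXIN_NAMES)
    def test_every_published_name_round_trips(self, name):
        parsed = parse_name(name)
        rendered = parse_name(name).render()
        reparsed = parse_name(rendered)
        # the grammar fields survive exactly; the rendered form is a fixed
        # point (rendering canonicalises spacing/hyphenation once)
        for field in ("kind", "family", "isoform", "nt_variant",
                      "activity_prefix", "prefix_index", "species_code",
                      "genus_initial", "species", "toxin_stem"):
            assert getattr(reparsed, field) == getattr(parsed, field)
        assert reparsed.render() == rendered

    def test_unparseable_name_raises(self):
        with pytest.raises(ValueError, match="unparseable"):
            parse_name("not a toxin name")


@given(
    prefix=st.sampled_from(sorted(GREEK_BY_NAME.values()) + ["U"]),
    stem=st.from_regex(r"[a-z]{3,12}toxin", fullmatch=True),
    family=st.integers(min_value=1, max_value=40),
    isoform=st.from_regex(r"[a-z]{1,2}", fullmatch=True),
    variant=st.one_of(st.none(), st.integers(min_value=1, max_value=9)),
)
def test_peptide_build_parse_identity(prefix, stem, family, isoform, variant):
    name = build_peptide_name(
        prefix, stem, "Paraponera", "clavata", family, isoform, variant,
        prefix_index=2 if prefix == "U" else None,
    )
    n = parse_name(name)
    assert n.kind == "peptide"
    assert n.activity_prefix == prefix
    assert n.toxin_stem == stem
    assert (n.family, n.isoform, n.nt_variant) == (family, isoform, variant)
    assert n.render() == name


@given(
    generic=st.from_regex(r"[a-z]{3,10}( [a-z]{2,8}){0,2}", fullmatch=True),
    family=st.integers(min_value=1, max_value=40),
    isoform=st.from_regex(r"[a-z]{1,2}", fullmatch=True),
    variant=st.one_of(st.none(), st.integers(min_value=1, max_value=9)),
)
def test_protein_build_parse_identity(generic, family, isoform, variant):
    name = build_protein_name(generic, family, isoform, "Paraponera", "clavata", variant)
    n = parse_name(name)
    assert n.kind == "protein"
    assert (n.family, n.isoform, n.nt_variant) == (family, isoform, variant)
    assert n.render() == name


def test_transliterate_is_ascii_safe():
    out = transliterate("δ-paraponeritoxin-Pc1e_2")
    assert out == "delta-paraponeritoxin-Pc1e_2"
    out.encode("ascii")


def test_spelling_normalisation_table():
    assert (
        normalize_spelling("Hyalyronidase-1a_1-P-clavata")
        == "Hyaluronidase-1a_1-P-clavata"
    )


class TestAssignNames:
    def test_identical_proteins_get_variant_numerals_by_descending_tpm(self):
        tpms = [39657.0, 9279.0, 2414.0, 797.0, 2.0, 0.0]
        entries = [
            SeqEntry(seq_id=f"DN{i}", protein_seq="FLPLLILGSLLMTPPVIQAIHDVQRGK", tpm=t)
            for i, t in enumerate(tpms)
        ]
        named = assign_names(
            entries, kind="peptide", genus="Paraponera", species="clavata",
            toxin_stem="paraponeritoxin", prefix="delta",
        )
        by_id = {a.seq_id: a for a in named}
        for i, t in enumerate(tpms):
            assert by_id[f"DN{i}"].variant == i + 1
        assert by_id["DN0"].name == "δ-paraponeritoxin-Pc1e_1".replace("e_1", "a_1")

    def test_distinct_sequences_get_isoform_letters_by_abundance(self):
        entries = [
            SeqEntry("c1", "AAAA", tpm=10.0),
            SeqEntry("c2", "AAAV", tpm=100.0),
        ]
        named = assign_names(
            entries, kind="protein", genus="Paraponera", species="clavata",
            generic_name="serine protease",
        )
        by_id = {a.seq_id: a for a in named}
        assert by_id["c2"].isoform == "a"
        assert by_id["c1"].isoform == "b"
        assert by_id["c2"].variant is None

    def test_single_sequence(self):
        [a] = assign_names(
            [SeqEntry("c1", "AAAA", tpm=1.0)],
            kind="protein", genus="Paraponera", species="clavata",
            generic_name="hyaluronidase",
        )
        assert (a.family, a.isoform, a.variant) == (1, "a", None)
        assert a.name == "Hyaluronidase-1a-P-clavata"

    def test_stable_under_input_reordering(self):
        entries = [
            SeqEntry(f"c{i}", seq, tpm=t, family_key=k)
            for i, (seq, t, k) in enumerate(
                [("AA", 5.0, "f1"), ("AV", 50.0, "f1"), ("GG", 7.0, "f2"),
                 ("AA", 2.0, "f1"), ("GL", 1.0, "f2")]
            )
        ]
        fwd = assign_names(entries, kind="protein", genus="P", species="clavata",
                           generic_name="lipase")
        rev = assign_names(entries[::-1], kind="protein", genus="P", species="clavata",
                           generic_name="lipase")
        assert fwd == rev

    def test_more_than_26_isoforms_extend_to_double_letters(self):
        entries = [
            SeqEntry(f"c{i:02d}", "A" * (i + 1), tpm=1000.0 - i) for i in range(28)
        ]
        named = assign_names(entries, kind="protein", genus="P", species="clavata",
                             generic_name="esterase")
        isoforms = [a.isoform for a in named]
        assert isoforms[25] == "z" and isoforms[26] == "aa" and isoforms[27] == "ab"
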