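"""Rational toxin nomenclature: building, parsing and batch assignment.

Two grammars are implemented.

Peptide toxins (< 10 kDa) follow the rational venom-peptide convention:

    <activity prefix>-<toxin stem>-<Gs><family><isoform>[_<variant>]

e.g. ``δ-paraponeritoxin-Pc1e_2``: a Greek-letter activity prefix (or
``U<n>`` when the pharmacology is unknown), a genus-derived toxin stem, a
two-letter species code (genus initial uppercase + species initial
lowercase), an integer family designator, a lowercase isoform letter, and an
optional nucleotide-variant numeral for transcripts that encode an identical
protein from different nucleotide sequences.

Protein toxins (>= 10 kDa) use an adapted grammar led by the generic
protein name:

    <Generic-Name>-<family><isoform>[_<variant>]-<G>-<species>

e.g. ``Phospholipase-A2-1a_1-P-clavata``; an uncharacterised protein takes
the generic prefix ``U``.

``assign_names`` performs deterministic batch assignment: isoform letters
rank distinct protein sequences by descending peak abundance (TPM), and
variant numerals rank identical-protein transcripts the same way, so the
output is independent of input order.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

__all__ = [
    "GREEK_BY_NAME",
    "NAME_BY_GREEK",
    "ToxinName",
    "NameAssignment",
    "SeqEntry",
    "build_peptide_name",
    "build_protein_name",
    "parse_name",
    "assign_names",
    "transliterate",
    "normalize_spelling",
    "SPELLING_NORMALISATION",
]

GREEK_BY_NAME = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "zeta": "ζ", "eta": "η", "theta": "θ", "iota": "ι", "kappa": "κ",
    "lambda": "λ", "mu": "μ", "nu": "ν", "xi": "ξ", "omicron": "ο",
    "pi": "π", "rho": "ρ", "sigma": "σ", "tau": "τ", "upsilon": "υ",
    "phi": "φ", "chi": "χ", "psi": "ψ", "omega": "ω",
}
NAME_BY_GREEK = {v: k for k, v in GREEK_BY_NAME.items()}
_GREEK_CHARS = "".join(NAME_BY_GREEK)

#: Known published misspellings; applied only on request, never emitted.
SPELLING_NORMALISATION = {"Hyalyronidase": "Hyaluronidase"}

_SUBSCRIPTS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")

_PEPTIDE_RE = re.compile(
    rf"^(?:(?P<greek>[{_GREEK_CHARS}])|U_?(?P<uidx>\d+)_?|(?P<uplain>U))"
    r"-(?P<stem>[A-Za-z]+)"
    r"-(?P<code>[A-Z][a-z])(?P<family>\d+)(?P<iso>[a-z]+)(?:_(?P<var>\d+))?$"
)

_PROTEIN_RE = re.compile(
    r"^(?P<generic>.+)-(?P<family>\d+)(?P<iso>[a-z]+)(?:_(?P<var>\d+))?"
    r"-(?P<gi>[A-Z])-(?P<species>[a-z]+)$"
)


@dataclasses.dataclass(frozen=True)
class ToxinName:
    """Structured components of a peptide or protein toxin name."""

    kind: str  # "peptide" | "protein"
    family: int
    isoform: str
    nt_variant: int | None = None
    # peptide grammar
    activity_prefix: str | None = None  # Greek letter (unicode) or "U"
    prefix_index: int | None = None
    toxin_stem: str | None = None
    species_code: str | None = None  # e.g. "Pc"
    # protein grammar
    generic_name: str | None = None
    genus_initial: str | None = None
    species: str | None = None

    def render(self) -> str:
        if self.kind == "peptide":
            return _render_peptide(self)
        if self.kind == "protein":
            return _render_protein(self)
        raise ValueError(f"unknown name kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class SeqEntry:
    """One transcript entering batch naming."""

    seq_id: str
    protein_seq: str
    tpm: float
    family_key: str | None = None


@dataclasses.dataclass(frozen=True)
class NameAssignment:
    seq_id: str
    name: str
    family: int
    isoform: str
    variant: int | None
    basis: str


def _require(value, what: str):
    if value is None or value == "":
        raise ValueError(f"missing name component: {what}")
    return value


def _resolve_prefix(prefix: str) -> str:
    """Accept a Greek unicode letter, its ASCII name, or 'U'."""
    if prefix in NAME_BY_GREEK or prefix == "U":
        return prefix
    if prefix.lower() in GREEK_BY_NAME:
        return GREEK_BY_NAME[prefix.lower()]
    raise ValueError(f"unknown activity prefix {prefix!r}")


def _species_code(genus: str, species: str) -> str:
    return genus[0].upper() + species[0].lower()


def _normalise_generic(generic: str) -> str:
    joined = "-".join(re.split(r"[\s\-]+", generic.strip()))
    return joined[0].upper() + joined[1:]


def _render_peptide(n: ToxinName) -> str:
    prefix = _require(n.activity_prefix, "activity_prefix")
    if prefix == "U":
        prefix_str = "U" if n.prefix_index is None else f"U{n.prefix_index}"
    else:
        prefix_str = prefix
    stem = _require(n.toxin_stem, "toxin_stem")
    code = _require(n.species_code, "species_code")
    var = "" if n.nt_variant is None else f"_{n.nt_variant}"
    return f"{prefix_str}-{stem}-{code}{n.family}{n.isoform}{var}"


def _render_protein(n: ToxinName) -> str:
    generic = _normalise_generic(_require(n.generic_name, "generic_name"))
    gi = _require(n.genus_initial, "genus_initial")
    species = _require(n.species, "species").lower()
    var = "" if n.nt_variant is None else f"_{n.nt_variant}"
    return f"{generic}-{n.family}{n.isoform}{var}-{gi}-{species}"


def build_peptide_name(
    prefix: str,
    toxin_stem: str,
    genus: str,
    species: str,
    family: int,
    isoform: str,
    variant: int | None = None,
    prefix_index: int | None = None,
) -> str:
    """Render a peptide-toxin name, e.g. ``δ-paraponeritoxin-Pc1e_2``."""
    _require(genus, "genus")
    _require(species, "species")
    _require(isoform, "isoform")
    if int(family) < 1:
        raise ValueError("family must be a positive integer")
    name = ToxinName(
        kind="peptide",
        family=int(family),
        isoform=isoform,
        nt_variant=variant,
        activity_prefix=_resolve_prefix(prefix),
        prefix_index=prefix_index,
        toxin_stem=toxin_stem,
        species_code=_species_code(genus, species),
    )
    return name.render()


def build_protein_name(
    generic_name: str,
    family: int,
    isoform: str,
    genus: str,
    species: str,
    variant: int | None = None,
) -> str:
    """Render a protein-toxin name, e.g. ``Phospholipase-A2-1a_1-P-clavata``.

    An uncharacterised protein should pass ``generic_name='U'``.
    """
    _require(genus, "genus")
    _require(isoform, "isoform")
    if int(family) < 1:
        raise ValueError("family must be a positive integer")
    name = ToxinName(
        kind="protein",
        family=int(family),
        isoform=isoform,
        nt_variant=variant,
        generic_name=generic_name,
        genus_initial=genus[0].upper(),
        species=species,
    )
    return name.render()


def parse_name(name: str) -> ToxinName:
    """Parse a toxin name in either grammar back into its components.

    The grammar kind is inferred from the string shape. Published
    subscript digits (``U₁``) and underscore-subscript artefacts (``U_1_``)
    are accepted for the unknown-activity prefix. Raises ``ValueError``
    naming the violating token on failure.
    """
    if not name or not name.strip():
        raise ValueError("empty name")
    cleaned = name.strip().translate(_SUBSCRIPTS)
    m = _PEPTIDE_RE.match(cleaned)
    if m:
        if m.group("greek"):
            prefix, idx = m.group("greek"), None
        elif m.group("uidx") is not None:
            prefix, idx = "U", int(m.group("uidx"))
        else:
            prefix, idx = "U", None
        return ToxinName(
            kind="peptide",
            family=int(m.group("family")),
            isoform=m.group("iso"),
            nt_variant=None if m.group("var") is None else int(m.group("var")),
            activity_prefix=prefix,
            prefix_index=idx,
            toxin_stem=m.group("stem"),
            species_code=m.group("code"),
        )
    m = _PROTEIN_RE.match(cleaned)
    if m:
        return ToxinName(
            kind="protein",
            family=int(m.group("family")),
            isoform=m.group("iso"),
            nt_variant=None if m.group("var") is None else int(m.group("var")),
            generic_name=m.group("generic"),
            genus_initial=m.group("gi"),
            species=m.group("species"),
        )
    # locate the first token that fits neither grammar, for the error message
    first_token = cleaned.split("-", 1)[0]
    raise ValueError(f"unparseable toxin name {name!r} (first token {first_token!r})")


def transliterate(name: str) -> str:
    """ASCII-safe form of a name: Greek prefixes become their names."""
    out = name
    for greek, ascii_name in NAME_BY_GREEK.items():
        out = out.replace(greek, ascii_name)
    return out


def normalize_spelling(name: str, table: dict[str, str] | None = None) -> str:
    """Apply a spelling-normalisation table to a (parsed-verbatim) name."""
    table = SPELLING_NORMALISATION if table is None else table
    out = name
    for wrong, right in table.items():
        out = out.replace(wrong, right)
    return out


def _isoform_letters(i: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, ... (bijective base 26)."""
    out = []
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out.append(chr(ord("a") + r))
    return "".join(reversed(out))


def assign_names(
    entries: Sequence[SeqEntry],
    kind: str,
    genus: str,
    species: str,
    toxin_stem: str | None = None,
    prefix: str | None = None,
    prefix_index: int | None = None,
    generic_name: str | None = None,
) -> list[NameAssignment]:
    """Assign names to one group of transcripts sharing a naming target.

    Family numbers are given to paralog families (``family_key``) ranked by
    descending peak TPM; isoform letters to distinct protein sequences
    within a family, again by descending peak TPM; and nucleotide-variant
    numerals to transcripts encoding an identical protein, by descending
    TPM. All ties break on lexicographic keys, so the assignment is a pure
    function of ``(sequences, TPMs)`` and stable under input reordering.
    """
    if kind not in ("peptide", "protein"):
        raise ValueError(f"unknown name kind {kind!r}")
    if not entries:
        return []

    def build(family: int, isoform: str, variant: int | None) -> str:
        if kind == "peptide":
            return build_peptide_name(
                prefix or "U", toxin_stem or "toxin", genus, species,
                family, isoform, variant, prefix_index,
            )
        return build_protein_name(
            generic_name or "U", family, isoform, genus, species, variant
        )

    # family_key -> entries
    families: dict[str, list[SeqEntry]] = {}
    for e in entries:
        families.setdefault(e.family_key or "", []).append(e)
    fam_rank = sorted(
        families,
        key=lambda k: (-max(e.tpm for e in families[k]), k),
    )
    out: list[NameAssignment] = []
    for fam_no, fam_key in enumerate(fam_rank, start=1):
        members = families[fam_key]
        by_seq: dict[str, list[SeqEntry]] = {}
        for e in members:
            by_seq.setdefault(e.protein_seq, []).append(e)
        seq_rank = sorted(
            by_seq,
            key=lambda s: (-max(e.tpm for e in by_seq[s]), min(e.seq_id for e in by_seq[s])),
        )
        for iso_i, seq in enumerate(seq_rank):
            iso = _isoform_letters(iso_i)
            group = sorted(by_seq[seq], key=lambda e: (-e.tpm, e.seq_id))
            if len(group) == 1:
                e = group[0]
                out.append(
                    NameAssignment(
                        seq_id=e.seq_id,
                        name=build(fam_no, iso, None),
                        family=fam_no,
                        isoform=iso,
                        variant=None,
                        basis="distinct protein sequence",
                    )
                )
            else:
                for var_no, e in enumerate(group, start=1):
                    out.append(
                        NameAssignment(
                            seq_id=e.seq_id,
                            name=build(fam_no, iso, var_no),
                            family=fam_no,
                            isoform=iso,
                            variant=var_no,
                            basis="identical protein, distinct nucleotide sequence",
                        )
                    )
    out.sort(key=lambda a: (a.family, len(a.isoform), a.isoform, a.variant or 0, a.seq_id))
    return out


def write_naming_report(assignments: Iterable[NameAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("old_id\tassigned_name\tfamily\tisoform\tvariant\tbasis\n")
        for a in assignments:
            var = "" if a.variant is None else str(a.variant)
            fh.write(f"{a.seq_id}\t{a.name}\t{a.family}\t{a.isoform}\t{var}\t{a.basis}\n")
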