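"""Cysteine-scaffold extraction and conotoxin-framework / ICK classification.

A cysteine scaffold records the spacing of cysteines along a peptide as a
string such as ``x_8CCx_1Cx_19Cx_5``: ``x_n`` is a run of n non-cysteine
residues and each ``C`` a cysteine, adjacent cysteines rendering as ``CC``.
Peptides with an even count of four or more cysteines are treated as
toxin-like. Two named patterns are recognised:

* conotoxin framework I — exactly four cysteines arranged CC-C-C
  (first pair adjacent, the other two isolated);
* ICK (inhibitor cystine knot, conotoxin frameworks VI/VII at pattern
  level) — exactly six cysteines arranged C-C-CC-C-C.

Classification here is purely pattern-level: disulfide connectivity beyond
the count (framework I: 1-3/2-4; VI/VII: 1-4/2-5/3-6) is emitted as a label
and never structurally verified.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FRAMEWORK_I",
    "ICK_VI_VII",
    "OTHER_EVEN",
    "NONE",
    "CONNECTIVITY_LABELS",
    "CysteineScaffold",
    "scaffold_string",
    "parse_scaffold",
    "toxin_like_filter",
    "classify_framework",
    "predict_disulfide_count",
    "cysteine_distribution",
    "write_scaffold_tsv",
]

FRAMEWORK_I = "framework_I"
ICK_VI_VII = "ICK_VI_VII"
OTHER_EVEN = "other_even"
NONE = "none"

#: Canonical disulfide connectivities, reported as labels only.
CONNECTIVITY_LABELS = {
    FRAMEWORK_I: "1-3,2-4",
    ICK_VI_VII: "1-4,2-5,3-6",
}

_TOKEN = re.compile(r"C|x_(\d+)_?")


@dataclasses.dataclass(frozen=True)
class CysteineScaffold:
    peptide_id: str
    length: int
    cys_positions: tuple[int, ...]
    scaffold: str
    framework: str

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)


def _scaffold_notation(aa_seq: str, display: bool = False) -> str:
    """Render the scaffold string; ``display`` keeps trailing underscores
    after each spacer subscript (the table-style variant)."""
    parts: list[str] = []
    run = 0
    for ch in aa_seq:
        if ch == "C":
            if run:
                parts.append(f"x_{run}_" if display else f"x_{run}")
                run = 0
            parts.append("C")
        else:
            run += 1
    if run:
        parts.append(f"x_{run}_" if display else f"x_{run}")
    return "".join(parts)


def scaffold_string(aa_seq: str, peptide_id: str = "") -> CysteineScaffold:
    """Extract the cysteine scaffold of a peptide sequence.

    Zero-length spacers are omitted, so adjacent cysteines render as ``CC``.
    A cysteine-free peptide yields the bare spacer scaffold ``x_L``.
    """
    if not aa_seq:
        raise ValueError("empty peptide sequence")
    positions = tuple(i + 1 for i, ch in enumerate(aa_seq) if ch == "C")
    return CysteineScaffold(
        peptide_id=peptide_id,
        length=len(aa_seq),
        cys_positions=positions,
        scaffold=_scaffold_notation(aa_seq),
        framework=classify_framework(aa_seq),
    )


def scaffold_display(aa_seq: str) -> str:
    """Table-style scaffold variant with trailing underscores (``x_8_CC...``)."""
    return _scaffold_notation(aa_seq, display=True)


def parse_scaffold(scaffold: str) -> tuple[int, int]:
    """Parse a scaffold string into ``(length, n_cys)``.

    Accepts both the compact (``x_8CC``) and the underscored display
    (``x_8_CC``) notations. Raises on malformed input, naming the first
    offending position.
    """
    if not scaffold:
        raise ValueError("empty scaffold string")
    length = 0
    n_cys = 0
    pos = 0
    while pos < len(scaffold):
        m = _TOKEN.match(scaffold, pos)
        if m is None:
            raise ValueError(f"malformed scaffold string at position {pos + 1}: "
                             f"{scaffold[pos:pos + 8]!r}")
        if m.group(0) == "C":
            n_cys += 1
            length += 1
        else:
            length += int(m.group(1))
        pos = m.end()
    return length, n_cys


def cysteine_count(aa_seq: str) -> int:
    return aa_seq.count("C")


def toxin_like_filter(peptides: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    """Keep peptides with an even cysteine count of at least four.

    ``peptides`` are ``(peptide_id, aa_seq)`` pairs; order is preserved.
    """
    out = []
    for pid, seq in peptides:
        n = cysteine_count(seq)
        if n >= 4 and n % 2 == 0:
            out.append((pid, seq))
    return out


def _adjacency(aa_seq: str) -> list[bool]:
    """For each cysteine, whether the next cysteine is immediately adjacent."""
    pos = [i for i, ch in enumerate(aa_seq) if ch == "C"]
    return [pos[i + 1] == pos[i] + 1 for i in range(len(pos) - 1)]


def classify_framework(aa_seq: str) -> str:
    """Label the cysteine pattern of a peptide.

    ``framework_I`` for exactly four cysteines as CC-C-C; ``ICK_VI_VII`` for
    exactly six as C-C-CC-C-C; ``other_even`` for any other even count >= 4
    (putatively novel cysteine-rich scaffolds); ``none`` otherwise.
    """
    if not aa_seq:
        raise ValueError("empty peptide sequence")
    n = cysteine_count(aa_seq)
    adj = _adjacency(aa_seq)
    if n == 4 and adj == [True, False, False]:
        return FRAMEWORK_I
    if n == 6 and adj == [False, False, True, False, False]:
        return ICK_VI_VII
    if n >= 4 and n % 2 == 0:
        return OTHER_EVEN
    return NONE


def predict_disulfide_count(n_cys: int) -> int:
    """Disulfide bonds implied by full cysteine pairing: ``n_cys / 2``."""
    if n_cys < 0:
        raise ValueError("cysteine count must be non-negative")
    if n_cys % 2:
        raise ValueError(
            f"odd cysteine count ({n_cys}): free cysteine, cannot fully pair"
        )
    return n_cys // 2


def cysteine_distribution(peptides: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Histogram of cysteine counts: n_cys -> peptide count and fraction."""
    counts: dict[int, int] = {}
    for _, seq in peptides:
        n = cysteine_count(seq)
        counts[n] = counts.get(n, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["n_cys", "n_peptides", "fraction"])
    total = sum(counts.values())
    rows = [
        {"n_cys": n, "n_peptides": c, "fraction": c / total}
        for n, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def write_scaffold_tsv(
    scaffolds: Sequence[CysteineScaffold],
    path: str | Path,
    tpm: dict[str, float] | None = None,
) -> None:
    """Scaffold report TSV; column order is fixed."""
    with open(path, "w") as fh:
        fh.write(
            "peptide_id\tlength\tn_cys\tscaffold\tframework"
            "\tpredicted_disulfides\ttpm\n"
        )
        for sc in scaffolds:
            n = sc.n_cys
            dis = str(n // 2) if n % 2 == 0 else "free-cysteine"
            t = "" if tpm is None or sc.peptide_id not in tpm else f"{tpm[sc.peptide_id]:.2f}"
            fh.write(
                f"{sc.peptide_id}\t{sc.length}\t{n}\t{sc.scaffold}"
                f"\t{sc.framework}\t{dis}\t{t}\n"
            )
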