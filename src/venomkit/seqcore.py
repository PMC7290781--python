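"""Sequence primitives for venom-gland transcriptome analysis.

Six-frame translation, open-reading-frame (ORF) extraction, FASTA I/O and
pairwise global alignment with percent-identity / percent-similarity
statistics of the kind quoted for toxin isoform comparisons.

Coordinates in all outputs are 1-based inclusive on the forward strand,
the convention biologists expect when reading ORF tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "OrfRecord",
    "AlignmentStats",
    "DEFAULT_SIMILARITY_GROUPS",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "find_orfs",
    "write_orfs_tsv",
    "global_align",
    "identity_similarity",
]

NUCLEOTIDES = set("ACGTN")
# Full IUPAC ambiguity alphabet; anything outside ACGT translates through 'X'
# unless the codon is unambiguous.
IUPAC_NT = set("ACGTNRYSWKMBDHV")

STOP = "*"

#: Conservative-substitution classes. Grouping A with V/L/I/M makes an
#: Ala<->Val exchange a conservative substitution, which is how venom
#: peptide isoform similarity percentages are conventionally counted.
DEFAULT_SIMILARITY_GROUPS: tuple[str, ...] = (
    "AVLIM", "FWY", "ST", "KR", "DE", "NQ", "H", "C", "G", "P",
)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


@dataclasses.dataclass(frozen=True)
class Contig:
    """An assembled transcript with its mapped read count."""

    id: str
    nt_seq: str
    read_count: int = 0

    def __post_init__(self) -> None:
        if not self.nt_seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        if self.read_count < 0:
            raise ValueError(f"contig {self.id!r}: negative read count")

    @property
    def length(self) -> int:
        return len(self.nt_seq)


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """A stop-free translated stretch located on a contig.

    ``start_nt``/``end_nt`` are 1-based inclusive forward-strand coordinates
    regardless of the reading frame's strand.
    """

    contig_id: str
    frame: int
    start_nt: int
    end_nt: int
    aa_seq: str

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if STOP in self.aa_seq:
            raise ValueError("ORF contains a stop symbol")
        if self.end_nt - self.start_nt + 1 != 3 * len(self.aa_seq):
            raise ValueError("ORF coordinates inconsistent with length")

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


@dataclasses.dataclass(frozen=True)
class AlignmentStats:
    pct_identity: float
    pct_similarity: float
    aligned_length: int
    n_identical: int
    n_similar: int


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` pairs from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as 60-column-wrapped FASTA."""
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def _validate_nt(nt_seq: str) -> str:
    if not nt_seq:
        raise ValueError("empty nucleotide sequence")
    seq = nt_seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_NT:
            raise ValueError(f"non-nucleotide character {ch!r} at position {i + 1}")
    return seq


def reverse_complement(nt_seq: str) -> str:
    return _validate_nt(nt_seq).translate(_COMPLEMENT)[::-1]


def _codon_maps(table: int) -> tuple[Mapping[str, str], frozenset[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    return tbl.forward_table, frozenset(tbl.stop_codons)


def translate_frame(nt_seq: str, offset: int, table: int = 1) -> str:
    """Translate one forward frame starting at ``offset`` (0..2).

    Stops render as ``*``; codons with ambiguity characters render as ``X``;
    a trailing partial codon is dropped.
    """
    seq = _validate_nt(nt_seq)
    fwd, stops = _codon_maps(table)
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in stops:
            out.append(STOP)
        else:
            out.append(fwd.get(codon, "X"))
    return "".join(out)


def six_frame_translate(nt_seq: str, table: int = 1) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 read the forward strand at offsets 0..2; frames -1..-3
    read the reverse complement at offsets 0..2.
    """
    seq = _validate_nt(nt_seq)
    rc = reverse_complement(seq)
    return {
        1: translate_frame(seq, 0, table),
        2: translate_frame(seq, 1, table),
        3: translate_frame(seq, 2, table),
        -1: translate_frame(rc, 0, table),
        -2: translate_frame(rc, 1, table),
        -3: translate_frame(rc, 2, table),
    }


def find_orfs(
    nt_seq: str,
    min_orf_len: int = 50,
    contig_id: str = "",
    table: int = 1,
    require_start: bool = False,
) -> list[OrfRecord]:
    """Report every maximal stop-free stretch of >= ``min_orf_len`` residues.

    All six frames are scanned. With ``require_start`` the stretch is trimmed
    to begin at its first methionine (off by default: venom transcripts are
    frequently 5'-truncated, so an internal stretch without ATG is still a
    useful ORF).
    """
    if min_orf_len < 1:
        raise ValueError("min_orf_len must be >= 1")
    seq = _validate_nt(nt_seq)
    L = len(seq)
    orfs: list[OrfRecord] = []
    for frame, aa in six_frame_translate(seq, table).items():
        offset = abs(frame) - 1
        # maximal stop-free runs in frame translation
        start = 0
        for chunk in aa.split(STOP):
            if chunk:
                run_start = start  # aa index of run start within this frame
                sub = chunk
                if require_start:
                    m = sub.find("M")
                    if m < 0:
                        sub = ""
                    else:
                        run_start += m
                        sub = sub[m:]
                if len(sub) >= min_orf_len:
                    i0, i1 = run_start, run_start + len(sub)
                    if frame > 0:
                        s_nt = offset + 3 * i0 + 1
                        e_nt = offset + 3 * i1
                    else:
                        s_nt = L - (offset + 3 * i1) + 1
                        e_nt = L - (offset + 3 * i0)
                    orfs.append(
                        OrfRecord(
                            contig_id=contig_id,
                            frame=frame,
                            start_nt=s_nt,
                            end_nt=e_nt,
                            aa_seq=sub,
                        )
                    )
            start += len(chunk) + 1
    orfs.sort(key=lambda o: (o.start_nt, o.end_nt, o.frame))
    return orfs


def write_orfs_tsv(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tframe\tstart\tend\tlength_aa\taa_seq\n")
        for o in orfs:
            fh.write(
                f"{o.contig_id}\t{o.frame:+d}\t{o.start_nt}\t{o.end_nt}"
                f"\t{o.length_aa}\t{o.aa_seq}\n"
            )


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

def _class_of(groups: Sequence[str]) -> dict[str, int]:
    cls = {}
    for k, g in enumerate(groups):
        for ch in g:
            cls[ch] = k
    return cls


def _pair_score(
    a: str,
    b: str,
    cls: Mapping[str, int],
    match: float,
    similar: float,
    mismatch: float,
) -> float:
    if a == b and a != "X":
        return match
    if a != "X" and b != "X" and cls.get(a) is not None and cls.get(a) == cls.get(b):
        return similar
    return mismatch


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    similar: float = 0.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with class-aware mismatch scoring.

    Scoring: identical residues score ``match``; residues sharing a
    conservative-substitution class score ``similar``; other substitutions
    score ``mismatch``; each gap position scores ``gap``. Traceback ties are
    broken diagonal > up > left, so the alignment is deterministic.

    Returns ``(aligned_a, aligned_b, score)`` with ``-`` as the gap symbol.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    cls = _class_of(groups)
    n, m = len(a), len(b)
    NEG = float("-inf")
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        score[i][0] = i * gap
        move[i][0] = 1
    for j in range(1, m + 1):
        score[0][j] = j * gap
        move[0][j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            d = score[i - 1][j - 1] + _pair_score(ai, b[j - 1], cls, match, similar, mismatch)
            u = score[i - 1][j] + gap
            l = score[i][j - 1] + gap
            best, mv = d, 0
            if u > best:
                best, mv = u, 1
            if l > best:
                best, mv = l, 2
            score[i][j] = best
            move[i][j] = mv
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif mv == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


def identity_similarity(
    aligned_a: str,
    aligned_b: str,
    groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
) -> AlignmentStats:
    """Percent identity / percent similarity over an aligned pair.

    Identity counts identical non-gap, non-'X' columns. Similarity
    additionally counts columns whose residues fall in the same
    conservative-substitution class. Percentages are over the full aligned
    length, gap columns included.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    if not aligned_a:
        raise ValueError("empty alignment")
    cls = _class_of(groups)
    n_id = 0
    n_sim = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-" or x == "X" or y == "X":
            continue
        if x == y:
            n_id += 1
            n_sim += 1
        elif cls.get(x) is not None and cls.get(x) == cls.get(y):
            n_sim += 1
    L = len(aligned_a)
    return AlignmentStats(
        pct_identity=100.0 * n_id / L,
        pct_similarity=100.0 * n_sim / L,
        aligned_length=L,
        n_identical=n_id,
        n_similar=n_sim,
    )
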