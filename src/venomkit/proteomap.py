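"""Proteome-to-transcriptome evidence mapping and filtering.

Peptide-spectrum evidence (sequence, -10lgP score, confidence, decoy flag)
produced by an external database-search engine is filtered with a
target-decoy FDR threshold and a confidence floor, then located by exact
substring matching inside the translated ORF database. Protein-level
acceptance requires a minimum number of matched peptides and a minimum best
score; proteins without a predicted signal peptide are partitioned out of
the secreted-toxin candidate list.

The spectral scoring itself is never reimplemented: scores, confidences and
mass errors are inputs, and the parent/fragment mass tolerances act as
validity predicates on the evidence records.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PeptideEvidence",
    "ProteinMatch",
    "DEFAULT_CATEGORY_KEYWORDS",
    "read_evidence_tsv",
    "digest",
    "fdr_threshold",
    "psm_filter",
    "map_and_infer",
    "secretion_filter",
    "categorize_proteins",
    "write_protein_report",
]


@dataclasses.dataclass(frozen=True)
class PeptideEvidence:
    peptide_seq: str
    score_neg10lgP: float
    confidence: float
    is_decoy: bool
    ppm_error: float = 0.0
    fragment_error: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 100:
            raise ValueError("confidence must be within [0, 100]")


@dataclasses.dataclass
class ProteinMatch:
    contig_id: str
    group_id: str
    n_peptides: int
    n_unique_peptides: int
    coverage_pct: float
    best_score: float
    has_signal: bool = False
    category: str = ""
    exclusion_reason: str = ""


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "score", "confidence", "is_decoy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def evidence_mass_ok(
    ppm_error: float,
    fragment_error: float,
    max_ppm: float = 50.0,
    max_fragment_da: float = 0.1,
) -> bool:
    """Validity predicate for the parent (ppm) and fragment (Da) tolerances."""
    return abs(ppm_error) <= max_ppm and abs(fragment_error) <= max_fragment_da


# ---------------------------------------------------------------------------
# In-silico digestion
# ---------------------------------------------------------------------------

def _tryptic_sites(protein: str) -> list[int]:
    """Cleavage points (index after which the bond is cut): after K/R not
    before P."""
    return [
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def digest(
    protein: str,
    max_missed: int = 3,
    mode: str = "full",
    min_len: int = 5,
) -> set[str]:
    """In-silico tryptic digestion of a protein sequence.

    ``full`` mode yields every peptide bounded by cleavage sites (or the
    protein termini) containing at most ``max_missed`` internal sites.
    ``semi`` mode additionally yields every proper prefix and suffix of each
    such fully-tryptic peptide — peptides with exactly one non-tryptic
    terminus. Peptides shorter than ``min_len`` are dropped.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if mode not in ("full", "semi"):
        raise ValueError(f"unknown digestion mode {mode!r}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + _tryptic_sites(protein) + [len(protein)]
    peptides: set[str] = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            pep = protein[bounds[i] : bounds[j]]
            if len(pep) >= min_len:
                peptides.add(pep)
            if mode == "semi":
                for k in range(1, len(pep)):
                    if len(pep) - k >= min_len:
                        peptides.add(pep[k:])  # non-tryptic N-terminus
                        peptides.add(pep[:-k])  # non-tryptic C-terminus
    if mode == "semi":
        peptides = {p for p in peptides if len(p) >= min_len}
    return peptides


# ---------------------------------------------------------------------------
# PSM filtering
# ---------------------------------------------------------------------------

def fdr_threshold(
    scores: Sequence[float],
    is_decoy: Sequence[bool],
    max_fdr_pct: float = 2.0,
    estimator: str = "decoy/target",
) -> float:
    """Lowest score threshold with estimated FDR below ``max_fdr_pct``.

    Candidate thresholds are the observed scores; accepting all records with
    score >= t, the FDR estimate is ``decoys/targets`` (or
    ``2*decoys/(targets+decoys)`` with the symmetric estimator). Returns
    ``inf`` when no threshold satisfies the bound.
    """
    if estimator not in ("decoy/target", "2*decoy/total"):
        raise ValueError(f"unknown FDR estimator {estimator!r}")
    pairs = sorted(zip(scores, is_decoy), key=lambda p: -p[0])
    if not any(not d for _, d in pairs):
        raise ValueError("no target records")
    best = float("inf")
    n_t = n_d = 0
    i = 0
    while i < len(pairs):
        score = pairs[i][0]
        # absorb ties so the threshold is well defined
        while i < len(pairs) and pairs[i][0] == score:
            n_d += pairs[i][1]
            n_t += not pairs[i][1]
            i += 1
        if n_t == 0:
            continue
        if estimator == "decoy/target":
            fdr = 100.0 * n_d / n_t
        else:
            fdr = 100.0 * 2 * n_d / (n_t + n_d)
        if fdr < max_fdr_pct:
            best = score
    return best


def psm_filter(
    evidence: pd.DataFrame,
    min_confidence: float = 95.0,
    max_fdr_pct: float = 2.0,
    estimator: str = "decoy/target",
) -> pd.DataFrame:
    """Filter PSM evidence by target-decoy FDR and confidence, conjunctively.

    The score threshold is the lowest score at which the decoy-based FDR
    estimate among accepted records stays below ``max_fdr_pct``; records
    under ``min_confidence`` are removed regardless. Decoy records are
    excluded from the returned evidence.
    """
    if evidence.empty or not (~evidence["is_decoy"]).any():
        raise ValueError("no target records in evidence")
    t = fdr_threshold(
        evidence["score"].tolist(),
        evidence["is_decoy"].tolist(),
        max_fdr_pct,
        estimator,
    )
    keep = (
        (~evidence["is_decoy"])
        & (evidence["score"] >= t)
        & (evidence["confidence"] >= min_confidence)
    )
    return evidence[keep]


# ---------------------------------------------------------------------------
# Peptide-to-protein mapping and inference
# ---------------------------------------------------------------------------

def map_and_infer(
    evidence: pd.DataFrame,
    orfs: Sequence[tuple[str, str]],
    min_peptides: int = 2,
    min_score: float = 15.0,
) -> list[ProteinMatch]:
    """Locate filtered peptides in translated ORFs and call proteins.

    Identical protein sequences are collapsed into one group (their contigs
    share peptide counts and coverage). A peptide is *unique* when it maps
    into exactly one group. A protein is accepted when it accumulates at
    least ``min_peptides`` distinct peptides and its best -10lgP score
    reaches ``min_score``. Ile/Leu are kept distinct: this is sequence-
    database matching, not spectral matching.
    """
    groups: dict[str, list[str]] = {}
    for contig_id, seq in orfs:
        groups.setdefault(seq, []).append(contig_id)
    group_list = [
        (";".join(sorted(ids)), seq) for seq, ids in groups.items()
    ]
    group_list.sort()

    peptides = evidence.drop_duplicates("peptide")
    pep_hits: dict[str, list[int]] = {}
    for gi, (_, seq) in enumerate(group_list):
        for pep in peptides["peptide"]:
            if pep in seq:
                pep_hits.setdefault(pep, []).append(gi)

    best_scores = evidence.groupby("peptide")["score"].max()

    matches: list[ProteinMatch] = []
    for gi, (gid, seq) in enumerate(group_list):
        matched = [p for p, gs in pep_hits.items() if gi in gs]
        if not matched:
            continue
        unique = [p for p in matched if len(pep_hits[p]) == 1]
        covered: set[int] = set()
        for pep in matched:
            start = seq.find(pep)
            while start != -1:
                covered.update(range(start, start + len(pep)))
                start = seq.find(pep, start + 1)
        best = max(best_scores[p] for p in matched)
        if len(matched) >= min_peptides and best >= min_score:
            for contig_id in gid.split(";"):
                matches.append(
                    ProteinMatch(
                        contig_id=contig_id,
                        group_id=gid,
                        n_peptides=len(matched),
                        n_unique_peptides=len(unique),
                        coverage_pct=100.0 * len(covered) / len(seq),
                        best_score=float(best),
                    )
                )
    matches.sort(key=lambda m: (-m.best_score, m.contig_id))
    return matches


def secretion_filter(
    matches: Sequence[ProteinMatch],
    signal_annotations: Mapping[str, bool],
) -> tuple[list[ProteinMatch], list[ProteinMatch]]:
    """Partition matches into secreted-toxin candidates vs excluded.

    A match is retained only when its contig carries a predicted signal
    peptide; excluded records keep a reason string. The two partitions
    always conserve the input.
    """
    retained: list[ProteinMatch] = []
    excluded: list[ProteinMatch] = []
    for m in matches:
        has_signal = bool(signal_annotations.get(m.contig_id, False))
        m = dataclasses.replace(m, has_signal=has_signal)
        if has_signal:
            retained.append(m)
        else:
            m.exclusion_reason = "no predicted signal peptide"
            excluded.append(m)
    return retained, excluded


DEFAULT_CATEGORIES = (
    "uncharacterised",
    "structural/motor",
    "cellular",
    "toxin-like",
    "metabolic",
    "regulation",
    "chaperone",
    "oxidoreductase",
    "kinase",
    "transport",
    "miscellaneous",
)

#: description keyword -> functional category
DEFAULT_CATEGORY_KEYWORDS: dict[str, str] = {
    "actin": "structural/motor",
    "myosin": "structural/motor",
    "tubulin": "structural/motor",
    "ribosomal": "cellular",
    "histone": "cellular",
    "elongation factor": "cellular",
    "toxin": "toxin-like",
    "phospholipase": "toxin-like",
    "hyaluronidase": "toxin-like",
    "venom": "toxin-like",
    "dehydrogenase": "metabolic",
    "synthase": "metabolic",
    "transferase": "metabolic",
    "ubiquitin": "regulation",
    "transcription factor": "regulation",
    "heat shock": "chaperone",
    "chaperon": "chaperone",
    "oxidase": "oxidoreductase",
    "reductase": "oxidoreductase",
    "peroxidase": "oxidoreductase",
    "kinase": "kinase",
    "transporter": "transport",
}


def categorize_proteins(
    matches: Sequence[ProteinMatch],
    annotation: pd.DataFrame,
    category_keywords: Mapping[str, str] | None = None,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> tuple[pd.DataFrame, float]:
    """Place each accepted protein into a functional category.

    Categories come from description keywords (longest match first);
    proteins without an annotation or keyword fall into ``uncharacterised``.
    Returns the per-category count table and the toxin-like fraction.
    """
    if category_keywords is None:
        category_keywords = DEFAULT_CATEGORY_KEYWORDS
    bad = set(category_keywords.values()) - set(categories)
    if bad:
        raise ValueError(f"unknown categories in configuration: {sorted(bad)}")
    desc_by_query = (
        annotation.drop_duplicates("query_id")
        .set_index("query_id")["description"]
        .to_dict()
        if not annotation.empty
        else {}
    )
    ordered = sorted(
        category_keywords.items(), key=lambda kv: (-len(kv[0]), kv[1], kv[0])
    )
    counts: dict[str, int] = {}
    for m in matches:
        desc = str(desc_by_query.get(m.contig_id, "")).lower()
        category = "uncharacterised"
        for kw, cat in ordered:
            if kw in desc:
                category = cat
                break
        m.category = category
        counts[category] = counts.get(category, 0) + 1
    table = pd.DataFrame(
        [{"category": c, "n_proteins": n} for c, n in sorted(counts.items())]
    ).sort_values(["n_proteins", "category"], ascending=[False, True], kind="mergesort")
    total = sum(counts.values())
    toxin_fraction = counts.get("toxin-like", 0) / total if total else 0.0
    return table.reset_index(drop=True), toxin_fraction


def write_protein_report(
    matches: Iterable[ProteinMatch],
    path: str | Path,
    names: Mapping[str, str] | None = None,
    tpm: Mapping[str, float] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "name\tcontig_id\tunique_peptides\tn_peptides\tpct_cover\tscore"
            "\ttpm\tsignal\tcategory\texclusion_reason\n"
        )
        for m in matches:
            name = (names or {}).get(m.contig_id, "")
            t = "" if tpm is None or m.contig_id not in tpm else f"{tpm[m.contig_id]:.2f}"
            fh.write(
                f"{name}\t{m.contig_id}\t{m.n_unique_peptides}\t{m.n_peptides}"
                f"\t{m.coverage_pct:.1f}\t{m.best_score:.1f}\t{t}"
                f"\t{'y' if m.has_signal else 'n'}\t{m.category}\t{m.exclusion_reason}\n"
            )
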