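"""Keyword-driven toxin mining of homology-annotation tables.

Contigs annotated by sequence similarity (query id, subject accession,
species, free-text description, e-value) are screened for venom relevance:
hits are first filtered on e-value, then assigned to a toxin family by a
case-insensitive keyword search of the description, longest keyword first.
Family summaries join those assignments against the expression table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_KEYWORD_MAP",
    "FamilyAssignment",
    "read_annotation_tsv",
    "evalue_filter",
    "classify_by_keywords",
    "family_summary",
    "top_expressed_report",
]

#: keyword (lowercase) -> toxin family. Covers the families conventionally
#: mined from venom-gland annotations; user maps can replace or extend it.
DEFAULT_KEYWORD_MAP: dict[str, str] = {
    "serine protease": "Protease",
    "serine proteinase": "Protease",
    "aspartic protease": "Protease",
    "cathepsin": "Protease",
    "protease": "Protease",
    "proteinase": "Protease",
    "peptidase": "Peptidase",
    "dipeptidyl peptidase": "Peptidase",
    "carboxypeptidase": "Peptidase",
    "neprilysin": "Peptidase",
    "neurotoxin": "Neurotoxin",
    "poneratoxin": "Neurotoxin",
    "phospholipase": "Phospholipase",
    "hyaluronidase": "Hyaluronidase",
    "metalloproteinase": "Metalloproteinase",
    "metalloprotease": "Metalloproteinase",
    "arginine kinase": "Arginine kinase",
    "allergen": "Allergen",
    "icarapin": "Allergen",
    "pilosulin": "Allergen",
    "defensin": "Defensin",
    "antimicrobial": "Antimicrobial",
    "lipase": "Esterase/lipase",
    "esterase": "Esterase/lipase",
    "acid phosphatase": "Phosphatase",
    "alkaline phosphatase": "Phosphatase",
    "phosphatase": "Phosphatase",
    "protease inhibitor": "Protease inhibitor",
    "serpin": "Protease inhibitor",
    "alaserpin": "Protease inhibitor",
    "kinase": "Kinase",
    "lectin": "Lectin-like",
    "conotoxin": "Toxin-like",
    "latrotoxin": "Toxin-like",
    "agatoxin": "Toxin-like",
    "sphingomyelinase": "Toxin-like",
    "toxin": "Toxin-like",
    "venom": "Other-toxin",
}


@dataclasses.dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    family: str
    matched_keyword: str


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str})
    required = {"query_id", "subject_accession", "subject_species", "description", "e_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def evalue_filter(hits: pd.DataFrame, cutoff: float = 1e-4) -> pd.DataFrame:
    """Keep hits with e-value strictly below ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("e-value cutoff must be positive")
    return hits[hits["e_value"] < cutoff]


def classify_by_keywords(
    hits: pd.DataFrame,
    keyword_map: Mapping[str, str] | None = None,
    word_boundary: bool = False,
) -> list[FamilyAssignment]:
    """Assign each hit a toxin family from keywords in its description.

    Keywords are matched case-insensitively as substrings (or whole words
    with ``word_boundary``); the longest matching keyword wins, with
    alphabetical family order as the deterministic tie-break. Hits matching
    no keyword are left unassigned (omitted from the result).
    """
    if keyword_map is None:
        keyword_map = DEFAULT_KEYWORD_MAP
    if not keyword_map:
        raise ValueError("empty keyword map")
    ordered = sorted(
        ((kw.lower(), fam) for kw, fam in keyword_map.items()),
        key=lambda kv: (-len(kv[0]), kv[1], kv[0]),
    )
    out: list[FamilyAssignment] = []
    for _, row in hits.iterrows():
        desc = str(row["description"]).lower()
        for kw, fam in ordered:
            if word_boundary:
                import re

                if not re.search(rf"\b{re.escape(kw)}\b", desc):
                    continue
            elif kw not in desc:
                continue
            out.append(FamilyAssignment(str(row["query_id"]), fam, kw))
            break
    return out


def family_summary(
    assignments: list[FamilyAssignment], expression: pd.DataFrame
) -> pd.DataFrame:
    """Per-family transcript counts and TPM min/median/max.

    Queries without an expression record are counted but excluded from the
    TPM statistics and flagged in ``n_missing_expression``.
    """
    if not assignments:
        return pd.DataFrame(
            columns=[
                "family", "n_transcripts", "tpm_min", "tpm_median", "tpm_max",
                "n_missing_expression",
            ]
        )
    adf = pd.DataFrame(
        [{"query_id": a.query_id, "family": a.family} for a in assignments]
    )
    merged = adf.merge(
        expression[["contig_id", "tpm"]],
        left_on="query_id",
        right_on="contig_id",
        how="left",
    )
    rows = []
    for family, grp in merged.groupby("family"):
        tpm = grp["tpm"].dropna()
        rows.append(
            {
                "family": family,
                "n_transcripts": len(grp),
                "tpm_min": tpm.min() if len(tpm) else np.nan,
                "tpm_median": tpm.median() if len(tpm) else np.nan,
                "tpm_max": tpm.max() if len(tpm) else np.nan,
                "n_missing_expression": int(grp["tpm"].isna().sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["n_transcripts", "family"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def top_expressed_report(
    assignments: list[FamilyAssignment],
    hits: pd.DataFrame,
    expression: pd.DataFrame,
    n: int = 20,
) -> pd.DataFrame:
    """Top-n expressed mined transcripts with annotation context."""
    if not assignments:
        return pd.DataFrame(
            columns=[
                "query_id", "family", "matched_keyword", "description",
                "subject_accession", "subject_species", "tpm",
            ]
        )
    adf = pd.DataFrame(dataclasses.asdict(a) for a in assignments)
    merged = (
        adf.merge(
            hits[["query_id", "subject_accession", "subject_species", "description"]]
            .drop_duplicates("query_id"),
            on="query_id",
            how="left",
        )
        .merge(
            expression[["contig_id", "tpm"]],
            left_on="query_id",
            right_on="contig_id",
            how="left",
        )
        .drop(columns=["contig_id"])
    )
    merged = merged.sort_values(
        ["tpm", "query_id"], ascending=[False, True], kind="mergesort"
    )
    return merged.head(n).reset_index(drop=True)
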