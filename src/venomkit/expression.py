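"""Transcript-abundance computation (TPM) and abundance-based filtering.

TPM (transcripts per million) is the length-normalised relative abundance

    tpm_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)

where ``c`` are mapped read counts and ``l`` effective transcript lengths;
the vector sums to one million by construction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "compute_tpm",
    "effective_length",
    "filter_min_tpm",
    "top_expressed",
    "read_counts_tsv",
    "expression_table",
    "write_expression_tsv",
]


def compute_tpm(counts, lengths) -> np.ndarray:
    """Compute TPM from read counts and (effective) transcript lengths."""
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if c.shape != l.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(l <= 0):
        raise ValueError("all lengths must be > 0")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    rate = c / l
    total = rate.sum()
    if total == 0:
        raise ZeroDivisionError("cannot compute TPM: all counts are zero")
    return 1e6 * rate / total


def effective_length(lengths, mean_fragment_length: float | None = None) -> np.ndarray:
    """Effective length for TPM; optionally ``l - mu_frag + 1`` floored at 1."""
    l = np.asarray(lengths, dtype=float)
    if mean_fragment_length is None:
        return l
    return np.maximum(l - float(mean_fragment_length) + 1.0, 1.0)


def filter_min_tpm(records: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep records with ``tpm >= threshold`` (boundary inclusive); order kept."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return records[records["tpm"] >= threshold]


def top_expressed(records: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Top ``n`` records by descending TPM; ties broken by contig id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = records.sort_values(
        ["tpm", "contig_id"], ascending=[False, True], kind="mergesort"
    )
    return out.head(n).reset_index(drop=True)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a counts table: contig_id, read_count, length."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    required = {"contig_id", "read_count", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def expression_table(
    counts: pd.DataFrame, mean_fragment_length: float | None = None
) -> pd.DataFrame:
    """Add ``effective_length`` and ``tpm`` columns to a counts table."""
    out = counts.copy()
    out["effective_length"] = effective_length(out["length"], mean_fragment_length)
    out["tpm"] = compute_tpm(out["read_count"], out["effective_length"])
    return out


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["tpm"] = out["tpm"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)
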