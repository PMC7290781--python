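"""End-to-end orchestration of the venom-gland analysis workflow.

Ties the stages together in the order a venomics study runs them:
transcriptome in, TPM quantification, homology-annotation mining, ORF
extraction, precursor/mass analysis, cysteine-scaffold classification,
nomenclature assignment, proteome-to-transcriptome mapping, reports out.

All thresholds live in one config mapping (see ``PAPER_DEFAULTS``) and the
run writes an audit log recording every parameter together with SHA-256
digests of the inputs; identical inputs and config produce byte-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import annotate, expression, frameworks, nomenclature, precursor, proteomap
from .seqcore import find_orfs, read_fasta

__all__ = ["PAPER_DEFAULTS", "load_config", "run_pipeline"]

#: Default thresholds of the workflow, centralised.
PAPER_DEFAULTS: dict[str, Any] = {
    "min_orf_len": 50,           # aa
    "evalue_cutoff": 1e-4,       # strict 'below'
    "min_tpm": 1.0,              # toxin tables include TPM >= 1 only
    "max_fdr_pct": 2.0,          # target-decoy FDR < 2%
    "min_confidence": 95.0,      # percent
    "min_peptides": 2,           # peptides per protein identification
    "min_score": 15.0,           # -10lgP
    "max_missed_cleavages": 3,
    "digestion_mode": "semi",
    "mass_tolerance_da": 0.5,    # candidate-vs-observed match window
    "mean_fragment_length": None,
    "genus": "Paraponera",
    "species": "clavata",
    "toxin_stem": "paraponeritoxin",
}

_REQUIRED_INPUTS = ("contigs", "counts", "annotations", "signal_annotations", "evidence")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError("config must be a mapping with an 'inputs' section")
    return cfg


def _resolve_params(cfg: Mapping) -> dict:
    params = dict(PAPER_DEFAULTS)
    params.update(cfg.get("params") or {})
    return params


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Run every stage and write the six reports plus an audit log.

    ``config`` is a mapping (or YAML path) with an ``inputs`` section naming
    the five input files and an optional ``params`` section overriding
    ``PAPER_DEFAULTS``. Returns report name -> path.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    inputs = {k: Path(v) for k, v in (config.get("inputs") or {}).items()}
    missing = [k for k in _REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise ValueError(f"config missing input entries: {missing}")
    absent = [str(p) for p in inputs.values() if not p.exists()]
    if absent:
        raise FileNotFoundError(f"missing input file(s): {absent}")
    params = _resolve_params(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- expression -------------------------------------------------------
    counts = expression.read_counts_tsv(inputs["counts"])
    expr = expression.expression_table(counts, params["mean_fragment_length"])
    expression.write_expression_tsv(expr, out_dir / "expression.tsv")

    # ---- annotation mining ------------------------------------------------
    hits = annotate.read_annotation_tsv(inputs["annotations"])
    kept_hits = annotate.evalue_filter(hits, params["evalue_cutoff"])
    assignments = annotate.classify_by_keywords(kept_hits)
    expr_min = expression.filter_min_tpm(expr, params["min_tpm"])
    mined_ids = {a.query_id for a in assignments}
    expressed_assignments = [
        a for a in assignments if a.query_id in set(expr_min["contig_id"])
    ]
    fam = annotate.family_summary(expressed_assignments, expr_min)
    _write_df(fam, out_dir / "family_summary.tsv")
    top20 = annotate.top_expressed_report(expressed_assignments, kept_hits, expr_min)
    _write_df(top20, out_dir / "top_expressed.tsv")

    # ---- ORFs -------------------------------------------------------------
    contig_seqs = dict(read_fasta(inputs["contigs"]))
    orfs = []
    for cid, seq in contig_seqs.items():
        orfs.extend(find_orfs(seq, params["min_orf_len"], contig_id=cid))
    from .seqcore import write_orfs_tsv

    write_orfs_tsv(orfs, out_dir / "orfs.tsv")

    # ---- precursor / mass report -----------------------------------------
    cleavages = precursor.read_precursor_annotations(inputs["signal_annotations"])
    longest_orf: dict[str, str] = {}
    for o in orfs:
        if len(o.aa_seq) > len(longest_orf.get(o.contig_id, "")):
            longest_orf[o.contig_id] = o.aa_seq
    matures: dict[str, str] = {}
    precursor_rows = []
    for cid in sorted(mined_ids & set(longest_orf)):
        s_end, p_end = cleavages.get(cid, (None, None))
        prec = precursor.parse_precursor(longest_orf[cid], cid, s_end, p_end)
        if not prec.mature:
            continue
        try:
            cands = precursor.processing_candidates(prec.mature)
        except ValueError:
            continue
        matures[cid] = prec.mature
        for cand in cands:
            precursor_rows.append((cid, cand, None, None))
    precursor.write_processing_report(precursor_rows, out_dir / "precursor_report.tsv")

    # ---- cysteine scaffolds ----------------------------------------------
    tpm_by_id = dict(zip(expr["contig_id"], expr["tpm"]))
    scaffolds = [
        frameworks.scaffold_string(seq, peptide_id=cid)
        for cid, seq in sorted(matures.items())
    ]
    frameworks.write_scaffold_tsv(scaffolds, out_dir / "scaffold_report.tsv", tpm_by_id)

    # ---- nomenclature -----------------------------------------------------
    fam_by_id = {a.query_id: a.family for a in assignments}
    by_family: dict[str, list[nomenclature.SeqEntry]] = {}
    for cid, seq in sorted(longest_orf.items()):
        if cid not in fam_by_id:
            continue
        by_family.setdefault(fam_by_id[cid], []).append(
            nomenclature.SeqEntry(
                seq_id=cid, protein_seq=seq, tpm=float(tpm_by_id.get(cid, 0.0))
            )
        )
    all_assignments = []
    for family in sorted(by_family):
        if family == "Neurotoxin":
            named = nomenclature.assign_names(
                by_family[family],
                kind="peptide",
                genus=params["genus"],
                species=params["species"],
                toxin_stem=params["toxin_stem"],
                prefix="U",
                prefix_index=1,
            )
        else:
            named = nomenclature.assign_names(
                by_family[family],
                kind="protein",
                genus=params["genus"],
                species=params["species"],
                generic_name=family,
            )
        all_assignments.extend(named)
    nomenclature.write_naming_report(all_assignments, out_dir / "naming_report.tsv")

    # ---- proteome mapping -------------------------------------------------
    evidence = proteomap.read_evidence_tsv(inputs["evidence"])
    filtered = proteomap.psm_filter(
        evidence, params["min_confidence"], params["max_fdr_pct"]
    )
    orf_db = [(o.contig_id, o.aa_seq) for o in orfs]
    matches = proteomap.map_and_infer(
        filtered, orf_db, params["min_peptides"], params["min_score"]
    )
    has_signal = {cid: s_end is not None for cid, (s_end, _) in cleavages.items()}
    retained, excluded = proteomap.secretion_filter(matches, has_signal)
    _, toxin_fraction = proteomap.categorize_proteins(retained + excluded, kept_hits)
    names_by_id = {a.seq_id: a.name for a in all_assignments}
    proteomap.write_protein_report(
        retained + excluded, out_dir / "protein_report.tsv", names_by_id, tpm_by_id
    )

    # ---- audit log --------------------------------------------------------
    log = {
        "parameters": {
            k: (v if v is None or isinstance(v, (int, float, str, bool)) else str(v))
            for k, v in params.items()
        },
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(inputs.items())},
        "summary": {
            "n_contigs": len(contig_seqs),
            "n_orfs": len(orfs),
            "n_annotation_hits": int(len(hits)),
            "n_hits_passing_evalue": int(len(kept_hits)),
            "n_mined_toxin_transcripts": len(mined_ids),
            "n_psms_accepted": int(len(filtered)),
            "n_proteins_accepted": len(matches),
            "n_secreted_toxin_candidates": len(retained),
            "toxin_like_fraction": round(toxin_fraction, 6),
        },
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)

    return {
        name: out_dir / f"{name}.tsv"
        for name in (
            "expression",
            "family_summary",
            "top_expressed",
            "orfs",
            "precursor_report",
            "scaffold_report",
            "naming_report",
            "protein_report",
        )
    }


def _write_df(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)
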