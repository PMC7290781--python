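"""Seeded generator of a complete synthetic venom-gland dataset.

Emulates the data shape of a venom-gland RNA-seq + shotgun-proteomics
experiment so that every pipeline stage can be exercised without any
download: toxin precursor contigs with signal/propeptide/mature
architecture (some carrying a C-terminal amidation signal), cysteine-
framework peptides realising published scaffold patterns, housekeeping
contigs, a long-tailed expression profile dominated by a single toxin
transcript, keyword-bearing homology annotations, signal-peptide
annotations and target/decoy peptide evidence derived from tryptic
digestion of a subset of the planted precursors.

Everything is driven by one integer seed; regenerating with the same seed
reproduces every output file byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import frameworks, proteomap
from .seqcore import write_fasta

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "plant_framework_peptides",
    "reverse_translate",
]

_AA_NO_C = "ADEFGHIKLMNPQRSTVWY"

#: (description, expected mined family) pool for planted toxin precursors.
_TOXIN_FAMILIES: tuple[tuple[str, str], ...] = (
    ("Poneratoxin", "Neurotoxin"),
    ("PREDICTED: phospholipase A2", "Phospholipase"),
    ("PREDICTED: hyaluronidase-like", "Hyaluronidase"),
    ("Serine proteinase stubble", "Protease"),
    ("Zinc metalloproteinase", "Metalloproteinase"),
    ("PREDICTED: arginine kinase isoform X1", "Arginine kinase"),
    ("PREDICTED: defensin-2-like", "Defensin"),
    ("PREDICTED: venom allergen 3-like", "Allergen"),
    ("PREDICTED: venom dipeptidyl peptidase 4", "Peptidase"),
    ("PREDICTED: venom acid phosphatase Acph-1", "Phosphatase"),
)

_HOUSEKEEPING_DESC = (
    "actin", "alpha-tubulin", "40S ribosomal protein S3",
    "60S ribosomal protein L7", "elongation factor 1-alpha",
    "heat shock protein 70", "ATP synthase subunit beta",
    "glyceraldehyde-3-phosphate dehydrogenase", "histone H2A",
    "ubiquitin-conjugating enzyme",
)

_SPECIES_POOL = (
    "Harpegnathos saltator", "Dinoponera quadriceps", "Camponotus floridanus",
    "Monomorium pharaonis", "Ooceraea biroi",
)

_DEFAULT_SCAFFOLD_TEMPLATES = (
    "x_8CCx_1Cx_19Cx_5",
    "x_1CCx_34Cx_1Cx_1",
    "x_5CCx_1Cx_16Cx_14",
    "CCx_23Cx_7Cx_6",
    "x_14CCx_11Cx_7Cx_33",
    "CCx_1Cx_27Cx_12",
    "x_3CCx_6Cx_15Cx_9",
    "x_6CCx_7Cx_11Cx_8",
    "x_8CCx_5Cx_12Cx_6",
    "Cx_6Cx_5CCx_4Cx_6Cx_29",
    "x_18Cx_6Cx_3CCx_8Cx_24Cx_7",
    "x_7Cx_8Cx_21CCx_5Cx_22Cx_20",
    "x_8Cx_6Cx_5CCx_4Cx_6Cx_25",
    "x_14Cx_9Cx_3Cx_5Cx_5CCx_3Cx_4Cx_26",
    "x_10Cx_5Cx_4CCx_11Cx_9Cx_28Cx_1Cx_5Cx_6Cx_1",
)


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for the synthetic venom-gland dataset."""

    n_contigs: int = 300
    n_toxins: int = 20
    n_framework_peptides: int = 15
    variant_group_frac: float = 0.05
    expression_sigma: float = 2.0
    dominant_toxin_share: float = 0.30
    read_depth: int = 100_000
    decoy_frac: float = 0.5
    detectable_frac: float = 0.6
    n_unsecreted_toxins: int = 2
    scaffold_templates: tuple[str, ...] = _DEFAULT_SCAFFOLD_TEMPLATES

    def validate(self) -> None:
        if self.n_contigs < self.n_toxins + self.n_framework_peptides + 1:
            raise ValueError("n_contigs too small for requested toxin counts")
        if not 0 <= self.variant_group_frac <= 1:
            raise ValueError("variant_group_frac must be within [0, 1]")
        if not 0 < self.dominant_toxin_share < 1:
            raise ValueError("dominant_toxin_share must be within (0, 1)")
        if self.read_depth < 1:
            raise ValueError("read_depth must be positive")
        if not 0 <= self.decoy_frac <= 2:
            raise ValueError("decoy_frac out of range")
        if not 0 <= self.detectable_frac <= 1:
            raise ValueError("detectable_frac must be within [0, 1]")
        if self.n_unsecreted_toxins >= self.n_toxins:
            raise ValueError("n_unsecreted_toxins must be < n_toxins")
        for t in self.scaffold_templates:
            frameworks.parse_scaffold(t)

    @classmethod
    def published_mimic(cls) -> "GeneratorConfig":
        """Preset scaled to the published proportions (~4.4% toxin contigs)."""
        return cls(n_contigs=300, n_toxins=13, n_framework_peptides=10)


@dataclasses.dataclass
class GroundTruth:
    """What was planted, so every stage can be checked against it."""

    seed: int
    toxins: list[dict]
    framework_peptides: list[dict]
    housekeeping_ids: list[str]
    evidence_sources: dict[str, list[str]]  # peptide -> planted contig ids
    expression_weights: dict[str, float]  # contig id -> generating weight
    decoy_fraction: float
    read_depth: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


_BACK_TABLE: dict[str, list[str]] = {}


def _back_table() -> dict[str, list[str]]:
    if not _BACK_TABLE:
        tbl = CodonTable.unambiguous_dna_by_id[1]
        for codon, aa in sorted(tbl.forward_table.items()):
            _BACK_TABLE.setdefault(aa, []).append(codon)
        _BACK_TABLE["*"] = sorted(tbl.stop_codons)
    return _BACK_TABLE


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform synonymous codon choice."""
    bt = _back_table()
    return "".join(bt[aa][rng.integers(len(bt[aa]))] for aa in aa_seq)


def _random_aa(rng: np.random.Generator, n: int, alphabet: str = _AA_NO_C) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _signal_peptide(rng: np.random.Generator) -> str:
    # M + hydrophobic core + polar tail: enough to look like a signal
    core = "".join("AVLIF"[i] for i in rng.integers(0, 5, 18))
    tail = _random_aa(rng, 5, "STAGN")
    return "M" + core + tail


def plant_framework_peptides(
    templates, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Realise each scaffold template as a concrete peptide sequence.

    Returns ``(template, sequence)`` pairs; non-cysteine spacer positions
    are filled with random residues drawn from the 19 non-C letters, so the
    realised sequence's scaffold equals the template exactly.
    """
    out = []
    for template in templates:
        frameworks.parse_scaffold(template)  # raises on malformed input
        seq_parts: list[str] = []
        for m in frameworks._TOKEN.finditer(template):
            if m.group(0) == "C":
                seq_parts.append("C")
            else:
                seq_parts.append(_random_aa(rng, int(m.group(1))))
        out.append((template, "".join(seq_parts)))
    return out


def _embed_cds(protein: str, rng: np.random.Generator) -> str:
    """Contig = 5'UTR, in-frame stop, CDS, stop, 3'UTR.

    The flanking in-frame stops guarantee that the maximal ORF in the CDS
    frame is exactly the planted precursor.
    """
    utr5 = _random_nt(rng, int(rng.integers(20, 80)))
    utr3 = _random_nt(rng, int(rng.integers(20, 80)))
    cds = reverse_translate(protein, rng)
    return utr5 + "TAA" + cds + "TAA" + utr3


def generate_dataset(
    config: GeneratorConfig, seed: int, out_dir: str | Path
) -> GroundTruth:
    """Write the five input files plus a ground-truth JSON into ``out_dir``.

    Files: ``contigs.fasta``, ``counts.tsv``, ``annotations.tsv``,
    ``signal_annotations.tsv``, ``evidence.tsv``, ``ground_truth.json``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    toxins: list[dict] = []
    contigs: list[tuple[str, str]] = []
    annotations: list[dict] = []
    signal_rows: list[tuple[str, int | None, int | None]] = []

    n_variant_groups = int(round(config.variant_group_frac * config.n_toxins))

    # --- toxin precursors -------------------------------------------------
    for i in range(config.n_toxins):
        desc, family = _TOXIN_FAMILIES[i % len(_TOXIN_FAMILIES)]
        secreted = i >= config.n_unsecreted_toxins
        signal = _signal_peptide(rng) if secreted else ""
        propeptide = _random_aa(rng, int(rng.integers(8, 16))) if secreted and rng.random() < 0.5 else ""
        mature = _random_aa(rng, int(rng.integers(25, 45)))
        amidated = bool(rng.random() < 0.5)
        if amidated:
            mature += "GK"
        protein = signal + propeptide + mature
        contig_id = f"TOX{i + 1:03d}"
        n_variants = int(rng.integers(2, 4)) if i < n_variant_groups else 1
        member_ids = []
        for v in range(n_variants):
            cid = contig_id if n_variants == 1 else f"{contig_id}_v{v + 1}"
            member_ids.append(cid)
            contigs.append((cid, _embed_cds(protein, rng)))
            annotations.append(
                {
                    "query_id": cid,
                    "subject_accession": f"XP_{9000000 + i * 10 + v}",
                    "subject_species": _SPECIES_POOL[i % len(_SPECIES_POOL)],
                    "description": desc,
                    "e_value": float(10.0 ** -rng.uniform(6, 20)),
                }
            )
            signal_rows.append(
                (
                    cid,
                    len(signal) or None,
                    (len(signal) + len(propeptide)) if propeptide else None,
                )
            )
        toxins.append(
            {
                "contig_ids": member_ids,
                "family": family,
                "description": desc,
                "signal": signal,
                "propeptide": propeptide,
                "mature": mature,
                "has_signal": secreted,
                "amidated_tail": amidated,
            }
        )

    # --- cysteine-framework peptides -------------------------------------
    templates = [
        config.scaffold_templates[i % len(config.scaffold_templates)]
        for i in range(config.n_framework_peptides)
    ]
    planted = plant_framework_peptides(templates, rng)
    fw_records: list[dict] = []
    for i, (template, mature) in enumerate(planted):
        signal = _signal_peptide(rng)
        protein = signal + mature
        cid = f"FWP{i + 1:03d}"
        contigs.append((cid, _embed_cds(protein, rng)))
        annotations.append(
            {
                "query_id": cid,
                "subject_accession": f"XP_{9500000 + i}",
                "subject_species": _SPECIES_POOL[i % len(_SPECIES_POOL)],
                "description": "PREDICTED: omega-conotoxin-like protein 1",
                "e_value": float(10.0 ** -rng.uniform(6, 20)),
            }
        )
        signal_rows.append((cid, len(signal), None))
        fw_records.append(
            {"contig_id": cid, "scaffold": template, "mature": mature,
             "signal": signal}
        )

    # --- housekeeping / background contigs --------------------------------
    n_house = config.n_contigs - len(contigs)
    housekeeping_ids: list[str] = []
    for i in range(n_house):
        cid = f"HK{i + 1:04d}"
        housekeeping_ids.append(cid)
        contigs.append((cid, _random_nt(rng, int(rng.integers(300, 900)))))
        if rng.random() < 0.5:
            # annotated housekeeping gene, keyword-free description
            annotations.append(
                {
                    "query_id": cid,
                    "subject_accession": f"XP_{8000000 + i}",
                    "subject_species": _SPECIES_POOL[i % len(_SPECIES_POOL)],
                    "description": _HOUSEKEEPING_DESC[i % len(_HOUSEKEEPING_DESC)],
                    "e_value": float(10.0 ** -rng.uniform(5, 30)),
                }
            )
        else:
            # junk hit: above the e-value cutoff half the time
            annotations.append(
                {
                    "query_id": cid,
                    "subject_accession": f"XP_{7000000 + i}",
                    "subject_species": _SPECIES_POOL[i % len(_SPECIES_POOL)],
                    "description": "hypothetical protein",
                    "e_value": float(10.0 ** -rng.uniform(0, 8)),
                }
            )

    # --- expression: long-tailed with one dominant toxin ------------------
    n_total = len(contigs)
    weights = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=n_total)
    weights /= weights.sum()
    # first toxin contig becomes the dominant transcript
    dom = config.dominant_toxin_share
    weights *= (1.0 - dom) / weights.sum()
    weights[0] = dom
    weights /= weights.sum()
    counts = rng.multinomial(config.read_depth, weights)

    # --- peptide evidence --------------------------------------------------
    secreted_idx = [i for i, t in enumerate(toxins) if t["has_signal"]]
    n_detect = int(round(config.detectable_frac * len(secreted_idx)))
    detect_idx = list(secreted_idx[:n_detect])
    evidence_rows: list[dict] = []
    evidence_sources: dict[str, list[str]] = {}
    for i in detect_idx:
        t = toxins[i]
        protein = t["signal"] + t["propeptide"] + t["mature"]
        peps = sorted(
            p
            for p in proteomap.digest(protein, max_missed=1, mode="full", min_len=7)
            if len(p) <= 30
        )
        if not peps:
            continue
        k = min(len(peps), int(rng.integers(2, 7)))
        chosen = [peps[j] for j in sorted(rng.choice(len(peps), size=k, replace=False))]
        for pep in chosen:
            evidence_sources.setdefault(pep, [])
            evidence_sources[pep] = sorted(set(evidence_sources[pep] + t["contig_ids"]))
            evidence_rows.append(
                {
                    "peptide": pep,
                    "score": float(max(0.0, rng.normal(40.0, 10.0))),
                    "confidence": float(rng.uniform(95.0, 100.0))
                    if rng.random() < 0.9
                    else float(rng.uniform(80.0, 95.0)),
                    "is_decoy": False,
                    "ppm_error": float(np.clip(rng.normal(0.0, 10.0), -50, 50)),
                    "frag_error": float(np.clip(rng.normal(0.0, 0.02), -0.1, 0.1)),
                }
            )
    n_decoys = int(round(config.decoy_frac * len(evidence_rows)))
    target_peps = [r["peptide"] for r in evidence_rows]
    for j in range(n_decoys):
        src = target_peps[j % len(target_peps)] if target_peps else _random_aa(rng, 12)
        decoy = src[::-1]
        if decoy == src:
            decoy = src + "A"
        evidence_rows.append(
            {
                "peptide": decoy,
                "score": float(max(0.0, rng.normal(15.0, 5.0))),
                "confidence": float(rng.uniform(50.0, 100.0)),
                "is_decoy": True,
                "ppm_error": float(np.clip(rng.normal(0.0, 20.0), -50, 50)),
                "frag_error": float(np.clip(rng.normal(0.0, 0.04), -0.1, 0.1)),
            }
        )
    order = rng.permutation(len(evidence_rows))
    evidence_rows = [evidence_rows[i] for i in order]

    # --- write files -------------------------------------------------------
    write_fasta(contigs, out_dir / "contigs.fasta")
    with open(out_dir / "counts.tsv", "w") as fh:
        fh.write("contig_id\tread_count\tlength\n")
        for (cid, seq), c in zip(contigs, counts):
            fh.write(f"{cid}\t{int(c)}\t{len(seq)}\n")
    with open(out_dir / "annotations.tsv", "w") as fh:
        fh.write("query_id\tsubject_accession\tsubject_species\tdescription\te_value\n")
        for a in annotations:
            fh.write(
                f"{a['query_id']}\t{a['subject_accession']}\t{a['subject_species']}"
                f"\t{a['description']}\t{a['e_value']:.6e}\n"
            )
    with open(out_dir / "signal_annotations.tsv", "w") as fh:
        fh.write("orf_id\tsignal_end\tpropeptide_end\n")
        for cid, s_end, p_end in signal_rows:
            fh.write(
                f"{cid}\t{'' if s_end is None else s_end}"
                f"\t{'' if p_end is None else p_end}\n"
            )
    with open(out_dir / "evidence.tsv", "w") as fh:
        fh.write("peptide\tscore\tconfidence\tis_decoy\tppm_error\tfrag_error\n")
        for r in evidence_rows:
            fh.write(
                f"{r['peptide']}\t{r['score']:.4f}\t{r['confidence']:.4f}"
                f"\t{str(r['is_decoy']).lower()}\t{r['ppm_error']:.4f}"
                f"\t{r['frag_error']:.6f}\n"
            )

    truth = GroundTruth(
        seed=int(seed),
        toxins=toxins,
        framework_peptides=fw_records,
        housekeeping_ids=housekeeping_ids,
        evidence_sources=evidence_sources,
        expression_weights={
            cid: float(w) for (cid, _), w in zip(contigs, weights)
        },
        decoy_fraction=config.decoy_frac,
        read_depth=config.read_depth,
    )
    truth.to_json(out_dir / "ground_truth.json")
    return truth
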