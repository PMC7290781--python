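"""Toxin-precursor architecture and mass-based C-terminal processing inference.

Secreted peptide toxins are translated as precursors with a signal peptide,
often a propeptide, and the mature toxin. A mature sequence ending in a
glycine followed by up to two basic residues (G, GK, GR, GKK, GRR ...) carries
an amidation signal: maturation can clip the basic residues, clip the
glycine, and optionally leave the new C-terminus amidated (the glycine's
nitrogen is retained as the amide, a net mass change of -0.98402 Da relative
to the free acid). Comparing candidate masses against an observed MALDI/ESI
mass identifies which processing state the venom actually contains.

Masses are computed from standard residue tables (monoisotopic or average)
plus one water; the monoisotopic convention is the default verification
surface for printed toxin masses.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "AMIDATION_MASS_SHIFT",
    "WATER_MONO",
    "ToxinPrecursor",
    "ProcessingCandidate",
    "MassMatch",
    "peptide_mass",
    "parse_precursor",
    "processing_candidates",
    "match_observed_mass",
    "read_precursor_annotations",
    "write_processing_report",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Free acid -> C-terminal amide: replace -OH by -NH2 (monoisotopic).
AMIDATION_MASS_SHIFT = -0.98402

WATER_MONO = 18.0105646863

_AMIDATION_MOTIF = re.compile(r"G[KR]{0,2}$")


@dataclasses.dataclass(frozen=True)
class ToxinPrecursor:
    """Signal / propeptide / mature partition of a translated toxin ORF."""

    orf_id: str
    signal: str
    propeptide: str
    mature: str

    @property
    def has_signal(self) -> bool:
        return bool(self.signal)

    @property
    def full_seq(self) -> str:
        return self.signal + self.propeptide + self.mature


@dataclasses.dataclass(frozen=True)
class ProcessingCandidate:
    variant_label: str
    processed_seq: str
    mass_mono: float
    mass_avg: float
    amidated: bool = False


@dataclasses.dataclass(frozen=True)
class MassMatch:
    observed_mass: float
    best_variant: str
    delta: float
    within_tolerance: bool


def peptide_mass(seq: str, mode: str = "mono") -> float:
    """Neutral peptide mass in Da: residue masses plus one water.

    ``mode`` is ``"mono"`` (monoisotopic) or ``"average"``. Only the 20
    standard amino-acid letters are accepted.
    """
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard amino acid letter(s): {sorted(bad)}")
    if mode == "mono":
        return float(_pmass.calculate_mass(sequence=seq, monoisotopic=True))
    if mode == "average":
        return float(_pmass.calculate_mass(sequence=seq, average=True))
    raise ValueError(f"unknown mass mode {mode!r}")


def parse_precursor(
    aa_seq: str,
    orf_id: str = "",
    signal_end: int | None = None,
    propeptide_end: int | None = None,
) -> ToxinPrecursor:
    """Partition a precursor at annotated cleavage positions (1-based ends).

    ``signal_end`` is the last residue of the signal peptide and
    ``propeptide_end`` the last residue of the propeptide. Absent annotations
    leave the corresponding segment empty, so with no annotation at all the
    mature peptide is the full translation.
    """
    if not aa_seq:
        raise ValueError("empty precursor sequence")
    s_end = 0 if signal_end is None else int(signal_end)
    p_end = s_end if propeptide_end is None else int(propeptide_end)
    if not (0 <= s_end <= p_end <= len(aa_seq)):
        raise ValueError(
            f"cleavage positions out of order/range: signal_end={signal_end}, "
            f"propeptide_end={propeptide_end}, length={len(aa_seq)}"
        )
    return ToxinPrecursor(
        orf_id=orf_id,
        signal=aa_seq[:s_end],
        propeptide=aa_seq[s_end:p_end],
        mature=aa_seq[p_end:],
    )


def _candidate(seq: str, label: str, amidated: bool = False) -> ProcessingCandidate:
    mono = peptide_mass(seq, "mono")
    avg = peptide_mass(seq, "average")
    if amidated:
        mono += AMIDATION_MASS_SHIFT
        avg += AMIDATION_MASS_SHIFT
    return ProcessingCandidate(
        variant_label=label, processed_seq=seq, mass_mono=mono, mass_avg=avg,
        amidated=amidated,
    )


def processing_candidates(mature: str) -> list[ProcessingCandidate]:
    """Enumerate C-terminal processing states of a mature toxin sequence.

    Always emits the intact sequence. When the C-terminus carries an
    amidation-signal motif (glycine plus a trailing run of 0-2 K/R), also
    emits the stepwise des-basic variants, the des-G... variant with the
    glycine removed, and its amidated form. Candidates are ordered from
    least to most processed, with strictly decreasing mass.
    """
    if not mature:
        raise ValueError("empty mature sequence")
    out = [_candidate(mature, "intact")]
    m = _AMIDATION_MOTIF.search(mature)
    if m is None:
        return out
    motif = m.group(0)  # e.g. "GK"
    basics = motif[1:]
    # strip trailing basic residues one at a time: des-K, des-KK, ...
    for k in range(1, len(basics) + 1):
        stripped = mature[-k:]
        out.append(_candidate(mature[:-k], f"des-{stripped}"))
    # remove the glycine as well, then the amidated form of that sequence
    core = mature[: len(mature) - len(motif)]
    if core:
        out.append(_candidate(core, f"des-{motif}"))
        out.append(_candidate(core, f"des-{motif}-amidated", amidated=True))
    return out


def match_observed_mass(
    observed: float,
    candidates: Sequence[ProcessingCandidate],
    tolerance: float = 0.5,
) -> MassMatch:
    """Pick the processing candidate whose monoisotopic mass is closest.

    Ties prefer the less-processed variant (candidate emission order).
    ``tolerance`` (Da) flags whether the best match is acceptable at all;
    the 0.5 Da default suits MALDI-TOF measurements of small peptides.
    """
    if observed <= 0:
        raise ValueError("observed mass must be positive")
    if not candidates:
        raise ValueError("no processing candidates supplied")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    best = min(candidates, key=lambda c: abs(observed - c.mass_mono))
    delta = observed - best.mass_mono
    return MassMatch(
        observed_mass=observed,
        best_variant=best.variant_label,
        delta=delta,
        within_tolerance=abs(delta) <= tolerance,
    )


def read_precursor_annotations(path: str | Path) -> dict[str, tuple[int | None, int | None]]:
    """Read a cleavage-annotation table: orf_id, signal_end, propeptide_end.

    Empty fields mean 'not annotated'. Cleavage sites come from external
    predictors (signal peptides) or proteomic evidence (propeptides); they
    are consumed, never predicted here.
    """
    out: dict[str, tuple[int | None, int | None]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            orf_id = parts[idx["orf_id"]]
            s = parts[idx["signal_end"]] if "signal_end" in idx else ""
            p = parts[idx["propeptide_end"]] if "propeptide_end" in idx else ""
            out[orf_id] = (int(s) if s else None, int(p) if p else None)
    return out


def write_processing_report(
    rows: Iterable[tuple[str, ProcessingCandidate, float | None, MassMatch | None]],
    path: str | Path,
) -> None:
    """Serialise (orf_id, candidate, observed mass, match) rows to TSV."""
    with open(path, "w") as fh:
        fh.write(
            "orf_id\tvariant\tmass_mono\tmass_avg\tobserved\tdelta\twithin_tolerance\n"
        )
        for orf_id, cand, observed, match in rows:
            obs = "" if observed is None else f"{observed:.4f}"
            if match is not None and match.best_variant == cand.variant_label:
                delta = f"{match.delta:.4f}"
                within = str(match.within_tolerance).lower()
            else:
                delta = ""
                within = ""
            fh.write(
                f"{orf_id}\t{cand.variant_label}\t{cand.mass_mono:.4f}"
                f"\t{cand.mass_avg:.4f}\t{obs}\t{delta}\t{within}\n"
            )
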