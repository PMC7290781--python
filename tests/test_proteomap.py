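"""In-silico digestion, PSM filtering and peptide-to-protein mapping."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from venomkit.proteomap import (
    ProteinMatch,
    categorize_proteins,
    digest,
    fdr_threshold,
    map_and_infer,
    psm_filter,
    secretion_filter,
)


class TestDigest:
    def test_manual_enumeration_zero_missed(self):
        assert digest("AKRGR", max_missed=0, min_len=1) == {"AK", "R", "GR"}

    def test_proline_suppresses_cleavage(self):
        assert digest("AKPR", max_missed=0, min_len=1) == {"AKPR"}

    def test_missed_cleavages(self):
        assert digest("AKRGR", max_missed=1, min_len=1) == {
            "AK", "R", "GR", "AKR", "RGR",
        }

    def test_zero_missed_peptides_partition_the_protein(self):
        rnd = random.Random(17)
        for _ in range(30):
            protein = "".join(rnd.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200))
            peps = digest(protein, max_missed=0, min_len=1)
            # greedy reconstruction: walk the protein consuming peptides
            i = 0
            while i < len(protein):
                step = next(
                    (len(p) for p in peps if protein.startswith(p, i)
                     and _is_tryptic_boundary(protein, i, i + len(p))),
                    None,
                )
                assert step is not None
                i += step

    def test_missed_cleavage_sets_are_nested(self):
        rnd = random.Random(23)
        protein = "".join(rnd.choice("ACDEFGHIKLMNPQRSTVWYKR") for _ in range(120))
        for k in range(3):
            assert digest(protein, max_missed=k, min_len=1) <= digest(
                protein, max_missed=k + 1, min_len=1
            )

    def test_semi_mode_adds_single_ragged_termini(self):
        peps = digest("GGGGGKAAAAAK", max_missed=0, mode="semi", min_len=5)
        assert "GGGGGK" in peps and "AAAAAK" in peps
        assert "GGGGK" in peps  # non-tryptic N-terminus
        assert "GGGGG" in peps  # non-tryptic C-terminus
        full = digest("GGGGGKAAAAAK", max_missed=0, mode="full", min_len=5)
        assert full <= peps

    def test_min_length_filter(self):
        assert digest("AKRGR", max_missed=0, min_len=3) == set()


def _is_tryptic_boundary(protein, start, end):
    ok_start = start == 0 or (protein[start - 1] in "KR" and protein[start] != "P")
    ok_end = end == len(protein) or (protein[end - 1] in "KR" and protein[end] != "P")
    return ok_start and ok_end


def _brute_force_threshold(scores, decoys, max_fdr_pct):
    best = math.inf
    for t in sorted(set(scores)):
        n_t = sum(1 for s, d in zip(scores, decoys) if s >= t and not d)
        n_d = sum(1 for s, d in zip(scores, decoys) if s >= t and d)
        if n_t and 100.0 * n_d / n_t < max_fdr_pct:
            best = min(best, t)
    return best


class TestFdrThreshold:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(5, 120))
            scores = list(np.round(rng.uniform(0, 50, n), 1))
            decoys = list(rng.random(n) < 0.3)
            if not any(not d for d in decoys):
                continue
            got = fdr_threshold(scores, decoys, 2.0)
            assert got == _brute_force_threshold(scores, decoys, 2.0)

    def test_optimality_at_next_lower_threshold(self):
        rng = np.random.default_rng(5)
        scores = list(np.round(rng.uniform(0, 50, 200), 2))
        decoys = list(rng.random(200) < 0.25)
        t = fdr_threshold(scores, decoys, 2.0)
        below = sorted({s for s in scores if s < t}, reverse=True)
        if below:
            t2 = below[0]
            n_t = sum(1 for s, d in zip(scores, decoys) if s >= t2 and not d)
            n_d = sum(1 for s, d in zip(scores, decoys) if s >= t2 and d)
            assert n_t == 0 or 100.0 * n_d / n_t >= 2.0

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold([1.0], [True], 2.0)


def _evidence(rows):
    return pd.DataFrame(rows, columns=["peptide", "score", "confidence", "is_decoy"])


class TestPsmFilter:
    def test_targets_above_all_decoys_pass(self):
        rows = [(f"P{i}", 30.0 + i, 99.0, False) for i in range(98)]
        rows += [("D1", 5.0, 99.0, True), ("D2", 6.0, 99.0, True)]
        out = psm_filter(_evidence(rows))
        assert len(out) == 98
        assert not out["is_decoy"].any()

    def test_low_confidence_removed_even_with_good_score(self):
        rows = [(f"P{i}", 40.0, 94.0, False) for i in range(10)]
        assert psm_filter(_evidence(rows)).empty

    def test_filters_are_conjunctive(self):
        rows = [("A", 40.0, 99.0, False), ("B", 40.0, 94.0, False),
                ("C", 1.0, 99.0, False), ("D", 39.0, 99.0, True)]
        out = psm_filter(_evidence(rows))
        assert list(out["peptide"]) == ["A"]

    def test_no_targets_is_an_error(self):
        with pytest.raises(ValueError):
            psm_filter(_evidence([("D", 1.0, 99.0, True)]))


class TestMapAndInfer:
    ORFS = [
        ("c1", "MAAAAKBBBBBKCCCCCK".replace("B", "W").replace("C", "F")),
        ("c2", "MGGGGGKDDDDDK"),
    ]

    def _ev(self, peptides, score=30.0):
        return _evidence([(p, score, 99.0, False) for p in peptides])

    def test_single_peptide_protein_rejected(self):
        out = map_and_infer(self._ev(["MAAAAK"]), self.ORFS)
        assert out == []

    def test_two_peptides_accepted(self):
        out = map_and_infer(self._ev(["MAAAAK", "WWWWWK"]), self.ORFS)
        assert len(out) == 1
        assert out[0].contig_id == "c1"
        assert out[0].n_peptides == 2

    def test_shared_peptide_is_non_unique_everywhere(self):
        orfs = [("c1", "MAAAAKSHAREDK"), ("c2", "MGGGGKSHAREDK")]
        ev = self._ev(["SHAREDK", "MAAAAK", "MGGGGK"])
        out = map_and_infer(ev, orfs)
        assert {m.contig_id for m in out} == {"c1", "c2"}
        for m in out:
            assert m.n_peptides == 2
            assert m.n_unique_peptides == 1

    def test_identical_proteins_collapse_into_one_group(self):
        orfs = [("c1", "MAAAAKWWWWWK"), ("c2", "MAAAAKWWWWWK")]
        out = map_and_infer(self._ev(["MAAAAK", "WWWWWK"]), orfs)
        assert {m.contig_id for m in out} == {"c1", "c2"}
        assert len({m.group_id for m in out}) == 1
        # peptides contained in one group only are still unique
        assert all(m.n_unique_peptides == 2 for m in out)

    def test_coverage_of_disjoint_peptides(self):
        protein = "A" * 9 + "K" + "W" * 9 + "K" + "G" * 80
        out = map_and_infer(self._ev(["A" * 9 + "K", "W" * 9 + "K"]), [("c1", protein)])
        assert out[0].coverage_pct == pytest.approx(20.0)

    def test_min_score_enforced(self):
        out = map_and_infer(
            self._ev(["MAAAAK", "WWWWWK"], score=10.0), self.ORFS, min_score=15.0
        )
        assert out == []


class TestSecretionFilter:
    def _matches(self):
        return [
            ProteinMatch("c1", "c1", 3, 3, 10.0, 50.0),
            ProteinMatch("c2", "c2", 2, 2, 5.0, 20.0),
            ProteinMatch("c3", "c3", 4, 4, 30.0, 99.0),
        ]

    def test_partition_conserves_records(self):
        retained, excluded = secretion_filter(self._matches(), {"c1": True, "c2": False})
        assert len(retained) + len(excluded) == 3

    def test_no_signal_excluded_with_reason(self):
        retained, excluded = secretion_filter(self._matches(), {"c1": True})
        assert [m.contig_id for m in retained] == ["c1"]
        assert all(m.exclusion_reason == "no predicted signal peptide" for m in excluded)

    def test_signal_match_retained(self):
        retained, _ = secretion_filter(self._matches(), {"c1": True, "c2": True, "c3": True})
        assert len(retained) == 3


class TestCategorizeProteins:
    def _annotation(self, rows):
        return pd.DataFrame(rows, columns=["query_id", "description"])

    def test_toxin_fraction(self):
        matches = [ProteinMatch(f"c{i}", f"c{i}", 2, 2, 5.0, 50.0) for i in range(10)]
        ann = self._annotation(
            [("c0", "venom phospholipase")]
            + [(f"c{i}", "actin") for i in range(1, 10)]
        )
        table, toxin_fraction = categorize_proteins(matches, ann)
        assert toxin_fraction == pytest.approx(0.10)
        counts = dict(zip(table["category"], table["n_proteins"]))
        assert counts["structural/motor"] == 9

    def test_unannotated_proteins_are_uncharacterised(self):
        matches = [ProteinMatch("c1", "c1", 2, 2, 5.0, 50.0)]
        table, _ = categorize_proteins(matches, self._annotation([]))
        assert list(table["category"]) == ["uncharacterised"]

    def test_unknown_category_in_config_rejected(self):
        with pytest.raises(ValueError):
            categorize_proteins([], self._annotation([]), {"foo": "not-a-category"})

    def test_counts_match_grouping_oracle(self):
        rng = np.random.default_rng(6)
        descs = ["actin", "kinase domain", "venom toxin", "hypothetical", "oxidase"]
        rows = [(f"c{i}", descs[int(rng.integers(len(descs)))]) for i in range(50)]
        matches = [ProteinMatch(q, q, 2, 2, 5.0, 50.0) for q, _ in rows]
        table, _ = categorize_proteins(matches, self._annotation(rows))
        assert int(table["n_proteins"].sum()) == 50
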