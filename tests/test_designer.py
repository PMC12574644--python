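"""Unit and property tests for the ssDNA design engine."""

import numpy as np
import pytest

from phageforge import (
    DesignSpec,
    MutationLog,
    design,
    eliminate_hairpins,
    eliminate_repeats,
    find_direct_repeats,
    find_inverted_repeats,
    insert_cpg_hexamers,
    reverse_complement,
    scaffold_sequence,
    validate,
)
from phageforge.designer import find_cg_dimers
from phageforge.errors import (
    InfeasibleDesignError,
    UnresolvableHairpinError,
)


def brute_force_repeats(seq: str, k: int) -> set[tuple[int, ...]]:
    """O(n^2) oracle: position tuples of every k-mer occurring >= 2 times."""
    groups: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        groups.setdefault(seq[i : i + k], []).append(i)
    return {tuple(v) for v in groups.values() if len(v) >= 2}


def brute_force_inverted(seq: str, k: int) -> set[tuple[int, int]]:
    """O(n^2) oracle comparing every window pair against its reverse complement.

    A window is never paired with itself at identical coordinates, which the
    i < j enumeration guarantees.
    """
    n = len(seq)
    return {
        (i, j)
        for i in range(n - k + 1)
        for j in range(i + 1, n - k + 1)
        if seq[j : j + k] == reverse_complement(seq[i : i + k])
    }


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestScanners:
    def test_homopolymer_repeat(self):
        hits = find_direct_repeats("A" * 20, 9)
        assert len(hits) == 1
        assert hits[0].kmer == "A" * 9
        assert hits[0].positions == tuple(range(12))

    def test_exact_duplication(self):
        seq = "ACGTTGCAA" * 2
        hits = find_direct_repeats(seq, 9)
        assert any(h.positions == (0, 9) for h in hits)

    def test_short_sequence_empty(self):
        assert find_direct_repeats("ACGT", 9) == []

    def test_constructed_inverted_repeat(self):
        s = "ATCGATCGATCGA"  # 13-mer
        seq = s + reverse_complement(s)
        hits = find_inverted_repeats(seq, 13)
        assert any(h.arm1_start == 0 and h.arm2_start == 13 for h in hits)

    def test_homopolymer_no_hairpin(self):
        assert find_inverted_repeats("A" * 40, 13) == []

    def test_alphabet_rejected(self):
        with pytest.raises(ValueError):
            find_direct_repeats("ACGTN", 2)

    @pytest.mark.parametrize("k", [4, 9, 13])
    def test_oracle_equivalence(self, k):
        """Exact agreement with O(n^2) oracles on 200 seeded random sequences."""
        rng = np.random.default_rng(20240915 + k)
        for trial in range(200):
            n = int(rng.integers(max(20, k + 5), 301))
            seq = random_seq(rng, n)
            hits = find_direct_repeats(seq, k)
            assert {h.positions for h in hits} == brute_force_repeats(seq, k)
            inv = find_inverted_repeats(seq, k)
            assert {(h.arm1_start, h.arm2_start) for h in inv} == (
                brute_force_inverted(seq, k)
            )


class TestScaffold:
    def test_cg27_dimer_count(self):
        spec = DesignSpec(1415, 0.27, seed=1)
        seq, mask = scaffold_sequence(spec)
        assert len(seq) == 1415
        assert len(find_cg_dimers(seq)) == 191
        assert mask.sum() == 2 * 191

    def test_zero_fraction_no_dimer(self):
        seq, _ = scaffold_sequence(DesignSpec(1415, 0.0, seed=1))
        assert "CG" not in seq

    def test_tiny_zero_fraction(self):
        seq, _ = scaffold_sequence(DesignSpec(10, 0.0, seed=7))
        assert len(seq) == 10 and set(seq) <= set("ACGT") and "CG" not in seq

    def test_infeasible_spec(self):
        with pytest.raises(InfeasibleDesignError):
            DesignSpec(11, 1.0, seed=1)

    def test_deterministic(self):
        a, _ = scaffold_sequence(DesignSpec(500, 0.2, seed=11))
        b, _ = scaffold_sequence(DesignSpec(500, 0.2, seed=11))
        assert a == b


class TestRepairs:
    def test_homopolymer_repaired(self):
        seq, log = eliminate_repeats("A" * 20, np.zeros(20, bool), 9)
        assert find_direct_repeats(seq, 9) == []
        assert all(e.from_base in "AT" and e.to_base in "AT" for e in log.entries)

    def test_fixpoint_on_clean_input(self):
        seq = "ACTGCTAGCTAACTGGATCC"
        out, log = eliminate_repeats(seq, np.zeros(len(seq), bool), 9)
        assert out == seq and len(log) == 0

    def test_cg_conservation_with_protection(self):
        spec = DesignSpec(400, 0.25, seed=5)
        seq, mask = scaffold_sequence(spec)
        # force a duplication to give the repair something to do
        seq2 = seq[:150] + seq[:25] + seq[175:]
        out, log = eliminate_repeats(seq2, np.zeros(len(seq2), bool), 9)
        assert find_direct_repeats(out, 9) == []
        assert out.count("C") == seq2.count("C")
        assert out.count("G") == seq2.count("G")
        assert len(find_cg_dimers(out)) == len(find_cg_dimers(seq2))

    def test_hairpin_repaired(self):
        s = "ATAGCTTAGGCAT"
        seq = s + reverse_complement(s)
        out, log = eliminate_hairpins(seq, np.zeros(len(seq), bool), 13)
        assert find_inverted_repeats(out, 13) == []
        assert len(log) >= 1

    def test_hairpin_free_unchanged(self):
        seq = "A" * 30
        out, log = eliminate_hairpins(seq, np.zeros(30, bool), 13)
        assert out == seq and len(log) == 0

    def test_fully_protected_hairpin_unresolvable(self):
        s = "ATAGCTTAGGCAT"
        seq = s + reverse_complement(s)
        mask = np.ones(len(seq), bool)
        with pytest.raises(UnresolvableHairpinError):
            eliminate_hairpins(seq, mask, 13)


class TestHexamerConversion:
    def test_cpg40_arithmetic(self, cg27_result):
        seq, mask = cg27_result.sequence, cg27_result.mask
        out, _, log = insert_cpg_hexamers(seq, mask, 0.4, seed=1)
        assert len(out) == 1415 + 4 * 76
        assert len(find_cg_dimers(out)) == 191
        assert sum(1 for e in log.entries if e.reason == "hexamer") == 76

    def test_fraction_zero_identity(self, cg27_result):
        out, _, log = insert_cpg_hexamers(
            cg27_result.sequence, cg27_result.mask, 0.0, seed=1)
        assert out == cg27_result.sequence and len(log) == 0

    def test_full_conversion(self, cg27_result):
        out, _, _ = insert_cpg_hexamers(
            cg27_result.sequence, cg27_result.mask, 1.0, seed=1)
        assert len(out) == 1415 + 4 * 191 == 2179
        assert len(find_cg_dimers(out)) == 191
        n_mot = sum(out[i:i + 6] in ("AACGTT", "GACGTT")
                    for i in range(len(out) - 5))
        assert n_mot == 191

    def test_no_dimer_error(self):
        with pytest.raises(InfeasibleDesignError):
            insert_cpg_hexamers("ATATAT", np.zeros(6, bool), 0.5, seed=1)

    def test_in_place_preserves_length(self, cg27_result):
        out, _, _ = insert_cpg_hexamers(
            cg27_result.sequence, cg27_result.mask, 0.1, seed=1, in_place=True)
        assert len(out) == 1415
        assert len(find_cg_dimers(out)) == 191


class TestValidate:
    def test_cgcg(self):
        rep = validate("CGCG", DesignSpec(4, 1.0, seed=0))
        assert rep.n_cg_dimers == 2 and rep.cg_percent == 100

    def test_homopolymer_not_clean(self):
        rep = validate("A" * 20, DesignSpec(20, 0.0, seed=0))
        assert not rep.clean and len(rep.repeats) == 1

    def test_boundary_violation_flagged(self):
        # flank after the dimer starts with C
        rep = validate("ATCGCATAT", DesignSpec(9, 0.2, seed=0))
        assert rep.boundary_violations


class TestDesignPipeline:
    def test_cg27_clean_and_exact(self, cg27_result):
        rep = cg27_result.report
        assert rep.clean
        assert rep.length_nt == 1415
        assert rep.n_cg_dimers == 191
        assert rep.cg_percent == 27

    def test_cpg40_census(self, cpg40_result):
        rep = cpg40_result.report
        assert rep.clean
        assert rep.length_nt == 1719
        assert rep.n_cg_dimers == 191
        assert rep.n_hexamer_embedded == 76
        assert round(rep.hexamer_pct_of_cg) == 40

    def test_length_series_member(self):
        r = design(DesignSpec(721, 0.26, seed=3))
        assert r.report.clean and r.report.length_nt == 721

    def test_design_deterministic_and_seed_sensitive(self):
        a = design(DesignSpec(600, 0.2, seed=2))
        b = design(DesignSpec(600, 0.2, seed=2))
        c = design(DesignSpec(600, 0.2, seed=3))
        assert a.sequence == b.sequence
        assert c.sequence != a.sequence
        assert (a.report.n_cg_dimers, a.report.cg_percent) == (
            c.report.n_cg_dimers, c.report.cg_percent)

    def test_design_output_is_repair_fixpoint(self, cpg40_result):
        seq, mask = cpg40_result.sequence, cpg40_result.mask
        out, log = eliminate_repeats(seq, mask, 9)
        assert out == seq and len(log) == 0
        out, log = eliminate_hairpins(seq, mask, 13)
        assert out == seq and len(log) == 0

    def test_hexamer_motifs_survive_repair(self, cpg40_result):
        """Protected motifs are untouched by any later A/T pass."""
        seq = cpg40_result.sequence
        n_mot = sum(seq[i:i + 6] in ("AACGTT", "GACGTT")
                    for i in range(len(seq) - 5))
        assert n_mot == 76
        out, _ = eliminate_repeats(seq, cpg40_result.mask, 9)
        n_after = sum(out[i:i + 6] in ("AACGTT", "GACGTT")
                      for i in range(len(out) - 5))
        assert n_after == 76
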