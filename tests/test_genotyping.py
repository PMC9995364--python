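"""Mutation-finder tests: motif matching, UMI collapsing, cell and cluster calls."""

import re

import numpy as np
import pytest

from amlsc.genotyping import (
    DEFAULT_LOCUS,
    NPM1_TYPE_A,
    CellGenotype,
    MoleculeCall,
    assign_clusters,
    collapse_molecules,
    compute_coverage,
    genotype_cells,
    match_read,
)
from amlsc.readio import ReadRecord


def regex_oracle(sequence: str) -> bool:
    """Independent per-motif regex check with explicit anchoring."""
    for m in NPM1_TYPE_A.unanchored:
        if re.search(m, sequence):
            return True
    for m in NPM1_TYPE_A.suffix_anchored:
        if re.search(m + "$", sequence):
            return True
    for m in NPM1_TYPE_A.prefix_anchored:
        if re.search("^" + m, sequence):
            return True
    return False


class TestMatchRead:
    @pytest.mark.parametrize(
        "sequence,expected",
        [
            ("AGGATCTCTGTCTGGCAGTG", True),  # contains TCTCTGTCTGGC
            ("AGGATCTCTGTC", True),  # ends with GATCTCTGTC
            ("AGGATCTCTGGCAGTG", False),  # wild-type core, duplication absent
            ("GTCTGGCAGTTT", True),  # begins with GTCTGGCAG
            ("TCTCTGTCTGGC", True),  # bare unanchored motif
            ("ACGTACGTACGT", False),
        ],
    )
    def test_motif_examples(self, sequence, expected):
        assert match_read(sequence) is expected

    def test_anchoring_is_enforced(self):
        # suffix motif present internally but not at the read end: no match
        assert match_read("AGGATCTCTGTCAA") is False
        # prefix motif present internally but not at the start: no match
        assert match_read("AAGTCTGGCAGA") is False

    def test_non_acgt_never_matches(self):
        with pytest.warns(UserWarning):
            assert match_read("AGGATCTCTGTN") is False

    def test_matches_regex_oracle_on_random_and_planted_sequences(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        motifs = NPM1_TYPE_A.all_motifs()
        for i in range(3000):
            length = int(rng.integers(8, 151))
            seq = "".join(bases[rng.integers(0, 4, length)])
            if i % 2:  # enrich positives: splice in a motif fragment
                m = motifs[int(rng.integers(len(motifs)))]
                cut = int(rng.integers(0, len(m)))
                frag = m[cut:] if rng.random() < 0.5 else m[: len(m) - cut]
                pos = int(rng.integers(0, max(1, length - len(frag))))
                seq = seq[:pos] + frag + seq[pos + len(frag):]
            assert match_read(seq) == regex_oracle(seq), seq


def _read(bc, umi, start, end, seq):
    return ReadRecord(bc, umi, start, end, seq)


class TestCollapseMolecules:
    LO, HI = DEFAULT_LOCUS

    def test_any_mutant_read_wins(self):
        reads = [
            _read("c1", "u1", self.LO - 50, self.HI + 50, "AGGATCTCTGTCTGGCAGTG"),
            _read("c1", "u1", self.LO - 50, self.HI + 50, "ACGTACGTACGTACGT"),
        ]
        (call,) = collapse_molecules(reads)
        assert call.allele == "MUT" and call.n_reads == 2

    def test_containing_read_without_motif_is_wt(self):
        (call,) = collapse_molecules(
            [_read("c1", "u1", 171410500, 171410600, "ACGTACGTACGT")]
        )
        assert call.allele == "WT"

    def test_partial_overlap_is_uninformative(self):
        (call,) = collapse_molecules(
            [_read("c1", "u1", 171410500, 171410541, "ACGTACGTACGT")]
        )
        assert call.allele == "uninformative"

    def test_umi_scoped_within_barcode(self):
        reads = [
            _read("c1", "u1", self.LO, self.HI, "TCTCTGTCTGGC"),
            _read("c2", "u1", 171410500, 171410600, "ACGTACGT"),
        ]
        calls = collapse_molecules(reads)
        assert {(c.cell_barcode, c.allele) for c in calls} == {
            ("c1", "MUT"),
            ("c2", "WT"),
        }


class TestGenotypeCells:
    def _geno(self, n_mut, n_wt, coverage=True):
        mols = [
            MoleculeCall("c", f"m{i}", "MUT", 1) for i in range(n_mut)
        ] + [MoleculeCall("c", f"w{i}", "WT", 1) for i in range(n_wt)]
        (g,) = genotype_cells(mols, {"c": coverage})
        return g.call

    @pytest.mark.parametrize(
        "n_mut,n_wt,expected",
        [
            (1, 10, "MUT"),  # a single mutant transcript is enough
            (0, 6, "WT"),  # > 5 WT transcripts
            (0, 5, "ND"),  # <= 5 WT transcripts
            (0, 0, "ND"),  # covered but nothing classifiable
        ],
    )
    def test_classification_rules(self, n_mut, n_wt, expected):
        assert self._geno(n_mut, n_wt) == expected

    def test_no_reads_over_region_is_nocall(self):
        (g,) = genotype_cells([], {"c": False})
        assert g.call == "NoCall" and not g.has_coverage

    def test_molecules_without_coverage_is_inconsistent(self):
        with pytest.raises(ValueError, match="coverage"):
            genotype_cells([MoleculeCall("c", "u", "MUT", 1)], {"c": False})

    def test_classes_partition_cells(self, small_config):
        from amlsc import syndata

        reads, truth = syndata.gen_reads(small_config)
        coverage = compute_coverage(reads)
        for bc in truth.index:
            coverage.setdefault(bc, False)
        genotypes = genotype_cells(collapse_molecules(reads), coverage)
        assert len(genotypes) == len(truth)
        assert all(g.call in {"MUT", "WT", "ND", "NoCall"} for g in genotypes)
        # MUT iff >= 1 mutant UMI
        assert all((g.call == "MUT") == (g.n_mut_umi >= 1) for g in genotypes)

    def test_monotonicity_in_mutant_evidence(self):
        base = [MoleculeCall("c", "w0", "WT", 1)] * 1
        (g0,) = genotype_cells(base + [MoleculeCall("c", "m0", "MUT", 1)], {"c": True})
        assert g0.call == "MUT"
        # adding WT molecules never changes a MUT call
        more_wt = base + [MoleculeCall("c", "m0", "MUT", 1)] + [
            MoleculeCall("c", f"w{i}", "WT", 1) for i in range(1, 20)
        ]
        (g1,) = genotype_cells(more_wt, {"c": True})
        assert g1.call == "MUT"
        # adding mutant molecules never moves a cell away from MUT
        more_mut = more_wt + [MoleculeCall("c", f"m{i}", "MUT", 1) for i in range(1, 5)]
        (g2,) = genotype_cells(more_mut, {"c": True})
        assert g2.call == "MUT"


def _cluster(n_mut, n_wt, n_nocall, n_nd=0, cluster="k"):
    genos, clusters = [], {}
    i = 0
    for call, count in (("MUT", n_mut), ("WT", n_wt), ("NoCall", n_nocall), ("ND", n_nd)):
        for _ in range(count):
            bc = f"{cluster}_{i}"
            i += 1
            genos.append(
                CellGenotype(
                    bc,
                    1 if call == "MUT" else 0,
                    6 if call == "WT" else 0,
                    call != "NoCall",
                    call,
                )
            )
            clusters[bc] = cluster
    return genos, clusters


class TestAssignClusters:
    def test_criterion_1_extends_whole_cluster_minus_wt(self):
        genos, clusters = _cluster(40, 10, 50)
        (a,), aml = assign_clusters(genos, clusters)
        assert a.criterion_fired == 1 and not a.fallback
        assert sum(aml.values()) == 90  # all but the 10 WT cells

    def test_gap_configuration_falls_back_to_mut_only(self):
        genos, clusters = _cluster(25, 5, 70)
        (a,), aml = assign_clusters(genos, clusters)
        assert a.criterion_fired == 5 and a.fallback
        assert sum(aml.values()) == 25

    def test_criterion_4_needs_myeloid_and_nocall_majority(self):
        genos, clusters = _cluster(7, 0, 60, n_nd=33)
        (a,), aml = assign_clusters(genos, clusters, myeloid={"k": True})
        assert a.criterion_fired == 4 and not a.fallback
        assert sum(aml.values()) == 100
        # without the myeloid flag the same cluster is MUT-only
        (a2,), aml2 = assign_clusters(genos, clusters, myeloid={"k": False})
        assert a2.fallback and sum(aml2.values()) == 7

    def test_criterion_5_marks_only_mut_cells(self):
        genos, clusters = _cluster(2, 30, 40, n_nd=28)
        (a,), aml = assign_clusters(genos, clusters)
        assert a.criterion_fired == 5 and not a.fallback
        assert sum(aml.values()) == 2

    def test_wt_cells_never_leukemic(self):
        genos, clusters = _cluster(90, 10, 0)
        (_, aml) = assign_clusters(genos, clusters)
        wt_cells = [g.cell_barcode for g in genos if g.call == "WT"]
        assert not any(aml[bc] for bc in wt_cells)

    def test_missing_cluster_label_raises(self):
        genos, clusters = _cluster(5, 0, 5)
        clusters.pop(genos[0].cell_barcode)
        with pytest.raises(ValueError, match="cluster"):
            assign_clusters(genos, clusters)
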