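import itertools
import math

import numpy as np
import pandas as pd
import pytest

from metaqtl.genes import (
    PhysicalInterval,
    REASON_MARKER_CHR_CONFLICT,
    REASON_NO_MARKER_POSITION,
    Unresolved,
    expression_rank,
    extract_genes,
    go_enrichment,
    load_annotation,
    resolve_physical,
    write_bed,
)
from metaqtl.meta import MQTL


def _mqtl(flank_left, flank_right, chrom=1):
    return MQTL(
        name="MQTL1.1", chromosome=chrom, position_cm=10.0, ci95_cm=4.0,
        members=[("q", 1.0)], traits=frozenset({"SF"}), n_qtls=1, avg_pve=10.0,
        flank_left=flank_left, flank_right=flank_right,
    )


class TestResolvePhysical:
    LOOKUP = {"mL": (1, 1_200_000), "mR": (1, 3_400_000), "mC2": (2, 500_000)}

    def test_interval_spans_markers(self):
        iv = resolve_physical(_mqtl("mL", "mR"), self.LOOKUP)
        assert (iv.start_bp, iv.end_bp) == (1_200_000, 3_400_000)
        assert iv.source_markers == ("mL", "mR")

    def test_reversed_markers_normalised(self):
        iv = resolve_physical(_mqtl("mR", "mL"), self.LOOKUP)
        assert (iv.start_bp, iv.end_bp) == (1_200_000, 3_400_000)

    def test_missing_marker_unresolved(self):
        out = resolve_physical(_mqtl("absent", "mR"), self.LOOKUP)
        assert out == Unresolved("MQTL1.1", REASON_NO_MARKER_POSITION)

    def test_cross_chromosome_markers_unresolved(self):
        out = resolve_physical(_mqtl("mL", "mC2"), self.LOOKUP)
        assert out == Unresolved("MQTL1.1", REASON_MARKER_CHR_CONFLICT)

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        iv = resolve_physical(_mqtl("mL", "mR"), self.LOOKUP)
        bed = tmp_path / "iv.bed"
        write_bed([iv], bed)
        assert bed.read_text() == "Chr1\t1199999\t3400000\tMQTL1.1\n"


GFF3 = """##gff-version 3
Chr1\ttoy\tgene\t100\t500\t.\t+\t.\tID=g1;description=alpha
Chr1\ttoy\tgene\t900\t1500\t.\t-\t.\tID=g2;description=beta
Chr1\ttoy\tgene\t1400\t2200\t.\t+\t.\tID=g3;description=gamma
Chr1\ttoy\tgene\t5000\t6000\t.\t+\t.\tID=g4;description=delta
Chr2\ttoy\tgene\t100\t500\t.\t+\t.\tID=g5;description=epsilon
"""


@pytest.fixture
def annotation(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(GFF3)
    return load_annotation(p)


class TestExtractGenes:
    def _interval(self, start, end, chrom=1):
        return PhysicalInterval("MQTL1.1", chrom, start, end, ("a", "b"))

    def test_overlap_count(self, annotation):
        genes = extract_genes(self._interval(800, 2000), annotation)
        assert [g.gene_id for g in genes] == ["g2", "g3"]

    def test_straddling_gene_included(self, annotation):
        # g1 ends at 500; an interval starting inside g1 still captures it
        genes = extract_genes(self._interval(450, 600), annotation)
        assert [g.gene_id for g in genes] == ["g1"]

    def test_empty_region(self, annotation):
        assert extract_genes(self._interval(3000, 4000), annotation) == []

    def test_chromosome_filtering(self, annotation):
        genes = extract_genes(self._interval(1, 10_000, chrom=2), annotation)
        assert [g.gene_id for g in genes] == ["g5"]

    def test_sorted_by_start_regardless_of_file_order(self, tmp_path):
        lines = GFF3.splitlines()
        shuffled = "\n".join([lines[0]] + lines[1:][::-1]) + "\n"
        p = tmp_path / "shuf.gff3"
        p.write_text(shuffled)
        genes = extract_genes(self._interval(1, 10_000), load_annotation(p))
        assert [g.gene_id for g in genes] == ["g1", "g2", "g3", "g4"]


def hypergeom_tail_by_enumeration(N, K, n, k):
    """P(X >= k): exhaustive count over all size-n draws from N items."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += sum(1 for i in draw if i < K) >= k
    return hits / total


class TestGoEnrichment:
    def _annotation(self, N, K):
        # genes b0..b{N-1}; term T annotates the first K; term U everything
        anno = {f"b{i}": ({"T"} if i < K else set()) | {"U"} for i in range(N)}
        return anno

    def test_matches_enumeration_oracle(self):
        N, K, n, k = 20, 5, 5, 3
        anno = self._annotation(N, K)
        background = [f"b{i}" for i in range(N)]
        gene_set = [f"b{i}" for i in range(k)] + [f"b{N - 1 - i}" for i in range(n - k)]
        results = {r.term_id: r for r in go_enrichment(gene_set, anno, background)}
        expected = hypergeom_tail_by_enumeration(N, K, n, k)
        assert results["T"].p_value == pytest.approx(expected, rel=1e-12)
        assert results["T"].p_value == pytest.approx(0.07262, abs=1e-4)
        assert results["T"].k_in_set == k and results["T"].K_in_background == K

    @pytest.mark.parametrize("N,K,n,k", [(10, 3, 4, 0), (12, 6, 5, 5), (15, 7, 6, 3)])
    def test_small_cases_match_enumeration(self, N, K, n, k):
        anno = self._annotation(N, K)
        background = [f"b{i}" for i in range(N)]
        gene_set = [f"b{i}" for i in range(k)]
        gene_set += [f"b{i}" for i in range(K, K + n - k)]
        results = {r.term_id: r for r in go_enrichment(gene_set, anno, background)}
        assert results["T"].p_value == pytest.approx(
            hypergeom_tail_by_enumeration(N, K, n, k), rel=1e-12
        )

    def test_zero_hits_p_is_one(self):
        anno = self._annotation(10, 4)
        background = [f"b{i}" for i in range(10)]
        gene_set = [f"b{i}" for i in range(4, 8)]  # none annotated with T
        results = {r.term_id: r for r in go_enrichment(gene_set, anno, background)}
        assert results["T"].p_value == pytest.approx(1.0)

    def test_single_term_fdr_equals_p(self):
        anno = {f"b{i}": {"T"} if i < 3 else set() for i in range(10)}
        background = [f"b{i}" for i in range(10)]
        results = go_enrichment(["b0", "b1"], anno, background)
        assert len(results) == 1
        assert results[0].fdr == pytest.approx(results[0].p_value)

    def test_bh_fdr_monotone_in_pvalue_rank(self):
        rng = np.random.default_rng(0)
        anno = {}
        for i in range(30):
            terms = {f"T{j}" for j in range(8) if rng.random() < 0.3}
            anno[f"b{i}"] = terms
        background = [f"b{i}" for i in range(30)]
        gene_set = background[:10]
        results = sorted(go_enrichment(gene_set, anno, background),
                         key=lambda r: r.p_value)
        fdrs = [r.fdr for r in results]
        assert all(b >= a - 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_gene_outside_background_raises(self):
        anno = {"b0": {"T"}}
        with pytest.raises(ValueError, match="absent from background"):
            go_enrichment(["zzz"], anno, ["b0"])


class TestExpressionRank:
    def _matrix(self):
        return pd.DataFrame(
            {
                "anther": [10.0, 3.0, 0.0],
                "pistil": [10.0, 3.0, 0.0],
                "shoot": [1.0, 3.0, 0.0],
                "root": [1.0, 3.0, 0.0],
            },
            index=["gHigh", "gFlat", "gZero"],
        )

    def test_high_fold_gene_shortlisted(self):
        shortlist, missing = expression_rank(
            ["gHigh", "gFlat"], self._matrix(), {"anther", "pistil"}
        )
        assert list(shortlist["gene_id"]) == ["gHigh"]
        assert shortlist.iloc[0]["score"] == pytest.approx(10.1 / 1.1)
        assert missing == []

    def test_uniform_and_zero_expression_excluded(self):
        shortlist, _ = expression_rank(
            ["gFlat", "gZero"], self._matrix(), {"anther", "pistil"}
        )
        assert shortlist.empty

    def test_missing_genes_flagged(self):
        shortlist, missing = expression_rank(
            ["gHigh", "gAbsent"], self._matrix(), {"anther", "pistil"}
        )
        assert missing == ["gAbsent"]

    def test_shortlist_monotone_in_threshold(self):
        matrix = self._matrix()
        lo, _ = expression_rank(list(matrix.index), matrix, {"anther"}, fold_threshold=1.5)
        hi, _ = expression_rank(list(matrix.index), matrix, {"anther"}, fold_threshold=3.0)
        assert set(hi["gene_id"]) <= set(lo["gene_id"])

    def test_no_target_columns_raises(self):
        with pytest.raises(ValueError, match="target tissue"):
            expression_rank(["gHigh"], self._matrix(), {"nonexistent"})
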