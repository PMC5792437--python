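import numpy as np
import pandas as pd
import pytest

from cogepipe.coge import CoGECluster, CoGETable
from cogepipe.hallmarks import (
    CLUSTER_ORDER,
    HallmarkGeneSets,
    absolute_contribution,
    aggregate_and_rank,
    build_hallmark_sets,
    relative_contribution,
)
from cogepipe.io import (
    HALLMARK_VOCABULARY,
    HallmarkAnnotation,
    REFERENCE_HALLMARK,
    ValidationError,
)
from cogepipe.synthetic import (
    DESIGNATED_HALLMARK,
    SimulationConfig,
    ZERO_SHARE_HALLMARK,
    generate_annotation,
    generate_expression,
)

REF = REFERENCE_HALLMARK
ANGIO = "angiogenesis"


def small_annotation():
    # p1 {g1,g2} -> angiogenesis + reference; p2 {g3} -> reference only
    return HallmarkAnnotation(
        {"p1": {"g1", "g2"}, "p2": {"g3"}},
        {("p1", ANGIO), ("p1", REF), ("p2", REF)},
    )


def coge_of(assignments):
    clusters = pd.Series(assignments, dtype=object)
    return CoGETable("prev", "focal", clusters)


class TestBuildHallmarkSets:
    def test_constructed_union(self):
        sets = build_hallmark_sets(small_annotation())
        assert sets.gene_sets[ANGIO] == {"g1", "g2"}
        assert sets.gene_sets[REF] == {"g1", "g2", "g3"}

    def test_universe_intersection(self):
        sets = build_hallmark_sets(small_annotation(), universe={"g1"})
        assert sets.gene_sets[REF] == {"g1"}
        assert sets.gene_sets[ANGIO] == {"g1"}

    def test_hallmark_without_pathways_is_empty(self):
        sets = build_hallmark_sets(small_annotation())
        assert sets.pathway_sets[ZERO_SHARE_HALLMARK] == set()
        assert sets.gene_sets[ZERO_SHARE_HALLMARK] == set()

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            build_hallmark_sets(small_annotation(), reference="bogus")


class TestAbsoluteContribution:
    def test_constructed_counts(self):
        out = absolute_contribution(build_hallmark_sets(small_annotation()))
        assert out.loc[ANGIO, "shared_pathways"] == 1
        assert out.loc[ANGIO, "shared_genes"] == 2
        assert out.loc[REF, "shared_pathways"] == 2
        assert out.loc[REF, "shared_genes"] == 3

    def test_empty_hallmark_zero(self):
        out = absolute_contribution(build_hallmark_sets(small_annotation()))
        assert out.loc[ZERO_SHARE_HALLMARK, "shared_pathways"] == 0
        assert out.loc[ZERO_SHARE_HALLMARK, "shared_genes"] == 0

    def test_planted_overlap_recovered(self):
        config = SimulationConfig(seed=5)
        _, truth = generate_expression(config)
        annotation = generate_annotation(config, truth)
        out = absolute_contribution(build_hallmark_sets(annotation))
        for hallmark, planted in truth.planted_shared_pathways.items():
            assert out.loc[hallmark, "shared_pathways"] == planted


class TestRelativeContribution:
    def test_reference_scores_100_where_populated(self):
        sets = build_hallmark_sets(small_annotation())
        coge = coge_of({"g1": "COMMON_DOWN", "g2": "COMMON_DOWN",
                        "g3": "COMMON_UP"})
        out = relative_contribution(sets, coge)
        ref_rows = out[out["hallmark"] == REF].set_index("cluster")
        assert ref_rows.loc["COMMON_DOWN", "pct"] == 100.0
        assert ref_rows.loc["COMMON_UP", "pct"] == 100.0
        assert ref_rows.loc["CONTINUUM", "pct"] == 0.0  # n = 0

    def test_constructed_fifty_percent(self):
        # hallmark genes {a,b,c,d} in one cluster, only {a,b} in reference
        annotation = HallmarkAnnotation(
            {"pa": {"a", "b", "c", "d"}, "pr": {"a", "b"}},
            {("pa", ANGIO), ("pr", REF)},
        )
        sets = build_hallmark_sets(annotation)
        coge = coge_of({g: "COMMON_DOWN" for g in "abcd"})
        out = relative_contribution(sets, coge)
        row = out[(out["hallmark"] == ANGIO)
                  & (out["cluster"] == "COMMON_DOWN")].iloc[0]
        assert row["n_genes"] == 4
        assert row["pct"] == 50.0

    def test_zero_over_zero_is_zero(self):
        sets = build_hallmark_sets(small_annotation())
        out = relative_contribution(sets, coge_of({}))
        assert (out["pct"] == 0.0).all()
        assert (out["n_genes"] == 0).all()

    def test_no_shared_genes_means_all_zero(self):
        annotation = HallmarkAnnotation(
            {"pa": {"a"}, "pr": {"b"}}, {("pa", ANGIO), ("pr", REF)}
        )
        sets = build_hallmark_sets(annotation)
        coge = coge_of({"a": "COMMON_DOWN", "b": "COMMON_DOWN"})
        out = relative_contribution(sets, coge)
        assert (out.loc[out["hallmark"] == ANGIO, "pct"] == 0.0).all()

    def test_bounds(self):
        sets = build_hallmark_sets(small_annotation())
        coge = coge_of({"g1": "COMMON_DOWN", "g2": "CONTINUUM",
                        "g3": "COMMON_DOWN"})
        out = relative_contribution(sets, coge)
        assert out["pct"].between(0, 100).all()

    def test_enlarging_reference_never_decreases_pct(self, rng):
        genes = [f"g{i}" for i in range(12)]
        sets = HallmarkGeneSets(
            pathway_sets={h: set() for h in HALLMARK_VOCABULARY},
            gene_sets={h: set() for h in HALLMARK_VOCABULARY},
            reference=REF,
        )
        sets.gene_sets[ANGIO] = set(genes[:8])
        sets.gene_sets[REF] = set(genes[:3])
        coge = coge_of({g: "COMMON_DOWN" for g in genes[:6]})
        before = relative_contribution(sets, coge)
        sets.gene_sets[REF] |= {"g3", "g4"}
        after = relative_contribution(sets, coge)
        assert (after["pct"] >= before["pct"] - 1e-12).all()


class TestBruteForceOracle:
    """Exhaustive enumeration over every (gene, pathway, hallmark, cluster)
    tuple on annotations of at most 20 genes."""

    @staticmethod
    def brute(annotation, universe, coge, reference):
        gene_of = {}  # hallmark -> genes via any pathway
        path_of = {}
        for hallmark in annotation.vocabulary:
            path_of[hallmark] = set()
            gene_of[hallmark] = set()
            for (pathway, mapped_hallmark) in annotation.hallmark_map:
                if mapped_hallmark != hallmark:
                    continue
                path_of[hallmark].add(pathway)
                for gene in annotation.pathways[pathway]:
                    if universe is None or gene in universe:
                        gene_of[hallmark].add(gene)
        absolute = {
            h: (
                sum(1 for p in path_of[h] if p in path_of[reference]),
                sum(1 for g in gene_of[h] if g in gene_of[reference]),
            )
            for h in annotation.vocabulary
        }
        relative = {}
        for h in annotation.vocabulary:
            for cluster in CLUSTER_ORDER:
                members = [g for g, c in coge.clusters.items() if c == cluster]
                n = sum(1 for g in members if g in gene_of[h])
                shared = sum(
                    1
                    for g in members
                    if g in gene_of[h] and g in gene_of[reference]
                )
                relative[(h, cluster)] = (
                    n, 100.0 * shared / n if n else 0.0
                )
        return absolute, relative

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_annotations(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(int(rng.integers(5, 21)))]
        pathways = {
            f"p{i}": set(
                rng.choice(genes, size=rng.integers(1, len(genes) + 1),
                           replace=False)
            )
            for i in range(6)
        }
        hallmark_map = set()
        for pathway in pathways:
            for hallmark in rng.choice(
                HALLMARK_VOCABULARY, size=rng.integers(1, 3), replace=False
            ):
                hallmark_map.add((pathway, str(hallmark)))
        hallmark_map.add(("p0", REF))  # reference always populated
        annotation = HallmarkAnnotation(pathways, hallmark_map)
        clusters = {
            g: str(rng.choice([c.value for c in CoGECluster] + [None]))
            for g in genes
        }
        clusters = {g: (None if c == "None" else c)
                    for g, c in clusters.items()}
        coge = CoGETable("prev", "focal",
                         pd.Series(clusters, dtype=object))
        universe = set(rng.choice(genes, size=len(genes) // 2, replace=False))

        for uni in (None, universe):
            sets = build_hallmark_sets(annotation, universe=uni)
            abs_expected, rel_expected = self.brute(
                annotation, uni, coge, REF
            )
            abs_out = absolute_contribution(sets)
            for hallmark, (paths, genes_count) in abs_expected.items():
                assert abs_out.loc[hallmark, "shared_pathways"] == paths
                assert abs_out.loc[hallmark, "shared_genes"] == genes_count
            rel_out = relative_contribution(sets, coge).set_index(
                ["hallmark", "cluster"]
            )
            for key, (n, pct) in rel_expected.items():
                assert rel_out.loc[key, "n_genes"] == n
                assert rel_out.loc[key, "pct"] == pytest.approx(pct)


class TestAggregateAndRank:
    def test_all_hundred_gives_hundred(self):
        table = pd.DataFrame(
            {
                "hallmark": [ANGIO] * 11,
                "cluster": CLUSTER_ORDER,
                "n_genes": [1] * 11,
                "pct": [100.0] * 11,
            }
        )
        out = aggregate_and_rank({"c1": table})
        assert out.loc[ANGIO, "overall"] == pytest.approx(100.0)

    def test_printed_angiogenesis_row_mean(self):
        # eleven cluster percentages of one comparison; their mean is the
        # hallmark's per-comparison score (frozen arithmetic: 85.7818...)
        pcts = [100.0, 100.0, 82.2, 88.7, 86.0, 77.4, 83.8, 91.7, 75.0,
                87.2, 71.6]
        table = pd.DataFrame(
            {
                "hallmark": [ANGIO] * 11,
                "cluster": CLUSTER_ORDER,
                "n_genes": [1] * 11,
                "pct": pcts,
            }
        )
        out = aggregate_and_rank({"ZsG_vs_LN1": table})
        assert out.loc[ANGIO, "overall"] == pytest.approx(85.7818, abs=1e-3)

    def test_overall_is_mean_of_per_comparison_means(self):
        def table(pct):
            return pd.DataFrame(
                {
                    "hallmark": [ANGIO] * 11,
                    "cluster": CLUSTER_ORDER,
                    "n_genes": [1] * 11,
                    "pct": [pct] * 11,
                }
            )

        out = aggregate_and_rank({"c1": table(40.0), "c2": table(60.0)})
        assert out.loc[ANGIO, "overall"] == pytest.approx(50.0)

    def test_reference_excluded_from_ranking(self):
        def table(hallmark, pct):
            return pd.DataFrame(
                {
                    "hallmark": [hallmark] * 11,
                    "cluster": CLUSTER_ORDER,
                    "n_genes": [1] * 11,
                    "pct": [pct] * 11,
                }
            )

        combined = pd.concat(
            [table(REF, 100.0), table(ANGIO, 80.0),
             table("energy metabolism", 40.0)]
        )
        out = aggregate_and_rank({"c1": combined})
        assert out.loc[REF, "rank"] == 0
        assert out.loc[ANGIO, "rank"] == 1
        assert out.loc["energy metabolism", "rank"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_and_rank({})
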