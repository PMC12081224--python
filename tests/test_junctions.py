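"""Junction typing, crossover localization, allele-sharing asymmetry."""

import itertools
from math import comb

import numpy as np
import pytest

from eparscan.junctions import (
    CatalogSite,
    CrossoverInterval,
    GeneConversionError,
    VariantCatalog,
    allele_sharing_table,
    allele_sharing_test,
    classify_junction_types,
    distinct_rearranged_chromosomes,
    infer_crossover_interval,
    map_to_references,
)
from eparscan.simdata import recombinant_sequence


class TestMapToReferences:
    def test_y_parent_has_no_x_states(self, ltr6b_model):
        obs = map_to_references(
            ltr6b_model.y_element.replace("-", ""), ltr6b_model
        )
        assert obs.length_class == 559
        assert "X" not in obs.states.values()

    def test_x_parent_has_no_y_states(self, ltr6b_model):
        obs = map_to_references(
            ltr6b_model.x_element.replace("-", ""), ltr6b_model
        )
        assert obs.length_class == 551
        assert "Y" not in obs.states.values()

    def test_hybrid_states_split_at_crossover(self, ltr6b_model):
        c = 70  # between fixed positions 58 and 85
        obs = map_to_references(recombinant_sequence(ltr6b_model, c), ltr6b_model)
        for site in ltr6b_model.catalog.fixed_sites():
            expected = "X" if site.position < c else "Y"
            assert obs.states[site.position] == expected

    def test_distal_short_variant_aligns(self, ltr6b_model):
        """A 554-bp product (short distal allele) maps cleanly."""
        aligned = ltr6b_model.y_element
        distal = ltr6b_model.length_sites[0]
        hacked = (
            aligned[: distal.start - 1] + "C" + "-" * 5 + aligned[distal.end :]
        )
        seq = hacked.replace("-", "")
        assert len(seq) == 554
        obs = map_to_references(seq, ltr6b_model)
        assert obs.length_class == 554
        assert "X" not in obs.states.values()

    def test_disallowed_length_rejected_with_length_named(self, ltr6b_model):
        seq = ltr6b_model.y_element.replace("-", "")[:-6]  # 553 bp
        with pytest.raises(ValueError, match="553"):
            map_to_references(seq, ltr6b_model)


class TestRegistry:
    def test_exact_duplicates_collapse(self, ltr6b_model):
        seq = recombinant_sequence(ltr6b_model, 200)
        obs = [
            map_to_references(seq, ltr6b_model, sample_id=f"s{i}")
            for i in range(2)
        ]
        registry = classify_junction_types(obs)
        assert len(registry) == 1
        assert registry.counts() == {"Junc1": 2}

    def test_shuffled_input_preserves_partition(self, ltr6b_model):
        seqs = [recombinant_sequence(ltr6b_model, c) for c in (20, 20, 50, 300, 50)]
        obs = [
            map_to_references(s, ltr6b_model, sample_id=f"s{i}")
            for i, s in enumerate(seqs)
        ]
        fwd = classify_junction_types(obs)
        rev = classify_junction_types(obs[::-1])
        assert len(fwd) == len(rev) == 3

        def partition(reg):
            groups = {}
            for sample, tid in reg.assignments.items():
                groups.setdefault(tid, set()).add(sample)
            return {frozenset(v) for v in groups.values()}

        assert partition(fwd) == partition(rev)

    def test_sorted_canonicalization_stabilizes_ids(self, ltr6b_model):
        seqs = [recombinant_sequence(ltr6b_model, c) for c in (300, 20)]
        obs = [
            map_to_references(s, ltr6b_model, sample_id=f"s{i}")
            for i, s in enumerate(seqs)
        ]
        a = classify_junction_types(obs, sort_canonical=True)
        b = classify_junction_types(obs[::-1], sort_canonical=True)
        assert a.assignments == b.assignments

    def test_published_types_claim_their_sequences(self, ltr6b_model):
        junc1 = recombinant_sequence(ltr6b_model, 300)
        junc2 = recombinant_sequence(ltr6b_model, 300, role="DELETION")
        obs = [
            map_to_references(junc1, ltr6b_model, sample_id="a"),
            map_to_references(junc2, ltr6b_model, sample_id="b", role="DELETION"),
            map_to_references(
                recombinant_sequence(ltr6b_model, 20), ltr6b_model, sample_id="c"
            ),
        ]
        registry = classify_junction_types(
            obs, published={"Junc1": junc1, "Junc2": junc2}
        )
        assert registry.assignments == {"a": "Junc1", "b": "Junc2", "c": "Junc3"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_junction_types([])


class TestCrossoverInterval:
    def test_direct_rule_on_synthetic_states(self, ltr6b_model):
        """X at 15..58, Y from 85 on -> open interval (58, 85)."""
        obs = map_to_references(recombinant_sequence(ltr6b_model, 60), ltr6b_model)
        ci = infer_crossover_interval(obs, ltr6b_model.catalog)
        assert (ci.lo, ci.hi) == (58, 85)
        assert ci.status == "bounded"

    def test_all_proximal_parent_is_indeterminate(self, ltr6b_model):
        obs = map_to_references(recombinant_sequence(ltr6b_model, 1), ltr6b_model)
        ci = infer_crossover_interval(obs, ltr6b_model.catalog)
        assert ci.lo is None and ci.status == "indeterminate"

    def test_round_trip_containment_many_crossovers(self, ltr6b_model):
        """For every c between informative sites the interval brackets c."""
        fixed = [s.position for s in ltr6b_model.catalog.fixed_sites()]
        rng = np.random.default_rng(23)
        for c in rng.integers(2, 560, size=250):
            c = int(c)
            obs = map_to_references(
                recombinant_sequence(ltr6b_model, c), ltr6b_model
            )
            ci = infer_crossover_interval(obs, ltr6b_model.catalog)
            assert ci.contains(c)
            distal = [p for p in fixed if p < c]
            proximal = [p for p in fixed if p >= c]
            assert ci.lo == (max(distal) if distal else None)
            assert ci.hi == (min(proximal) if proximal else None)

    def test_reciprocal_products_share_the_interval(self, ltr6b_model):
        for c in (30, 60, 120, 400):
            epar = map_to_references(
                recombinant_sequence(ltr6b_model, c, "EPAR"), ltr6b_model,
                role="EPAR",
            )
            dele = map_to_references(
                recombinant_sequence(ltr6b_model, c, "DELETION"), ltr6b_model,
                role="DELETION",
            )
            a = infer_crossover_interval(epar, ltr6b_model.catalog)
            b = infer_crossover_interval(dele, ltr6b_model.catalog)
            assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_major_allele_mode_never_wider(self, ltr6b_model):
        rng = np.random.default_rng(5)
        for c in rng.integers(2, 560, size=50):
            obs = map_to_references(
                recombinant_sequence(ltr6b_model, int(c)), ltr6b_model
            )
            fixed_ci = infer_crossover_interval(
                obs, ltr6b_model.catalog, "FIXED_ONLY"
            )
            major_ci = infer_crossover_interval(
                obs, ltr6b_model.catalog, "MAJOR_ALLELE"
            )
            lo_f = -1 if fixed_ci.lo is None else fixed_ci.lo
            hi_f = 10**9 if fixed_ci.hi is None else fixed_ci.hi
            lo_m = -1 if major_ci.lo is None else major_ci.lo
            hi_m = 10**9 if major_ci.hi is None else major_ci.hi
            assert lo_m >= lo_f and hi_m <= hi_f

    def test_interleaved_states_flag_gene_conversion(self, ltr6b_model):
        seq = list(recombinant_sequence(ltr6b_model, 100))
        # overwrite the distal-most fixed site with the Y-parent base
        site = ltr6b_model.catalog.site(15)
        seq[15 - 1] = next(iter(site.y_alleles))
        obs = map_to_references("".join(seq), ltr6b_model)
        with pytest.raises(GeneConversionError, match="gene"):
            infer_crossover_interval(obs, ltr6b_model.catalog)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError, match="below"):
            CrossoverInterval(lo=10, hi=10, mode="FIXED_ONLY")


class TestDistinctChromosomes:
    def test_identical_observations_one_chromosome(self, ltr6b_model):
        seq = recombinant_sequence(ltr6b_model, 200, "DELETION")
        obs = [
            map_to_references(seq, ltr6b_model, sample_id=f"s{i}",
                              role="DELETION", flanking=("A", "G", "T"))
            for i in range(4)
        ]
        count, partition = distinct_rearranged_chromosomes(obs)
        assert count == 1

    def test_flanking_haplotype_splits_types(self, ltr6b_model):
        obs = []
        for i, c in enumerate((20, 60, 200)):
            seq = recombinant_sequence(ltr6b_model, c, "DELETION")
            obs.append(map_to_references(seq, ltr6b_model, sample_id=f"a{i}",
                                         role="DELETION", flanking=("A", "G", "T")))
        # one junction type shared by a second flanking haplotype
        obs.append(map_to_references(
            recombinant_sequence(ltr6b_model, 200, "DELETION"), ltr6b_model,
            sample_id="b", role="DELETION", flanking=("G", "G", "T"),
        ))
        count, _ = distinct_rearranged_chromosomes(obs)
        assert count == 4

    def test_mixed_roles_rejected(self, ltr6b_model):
        obs = [
            map_to_references(recombinant_sequence(ltr6b_model, 100),
                              ltr6b_model, sample_id="a"),
            map_to_references(recombinant_sequence(ltr6b_model, 100, "DELETION"),
                              ltr6b_model, sample_id="b", role="DELETION"),
        ]
        with pytest.raises(ValueError, match="mix"):
            distinct_rearranged_chromosomes(obs)


def fisher_oracle(table):
    """Exact one-tailed p by enumerating all tables with the same margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    p = 0.0
    for a2 in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        if a2 >= a:
            p += comb(r1, a2) * comb(n - r1, c1 - a2) / denom
    return p


class TestAlleleSharing:
    def test_degenerate_margin_p_one(self):
        assert allele_sharing_test([[0, 0], [3, 4]]) == 1.0

    def test_hand_computed_table(self):
        p = allele_sharing_test([[5, 0], [1, 4]])
        assert p == pytest.approx(6 / 252)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            table = rng.integers(0, 8, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            assert allele_sharing_test(table) == pytest.approx(
                fisher_oracle(table.tolist())
            )

    def test_catalog_table_counts_sharing_patterns(self, ltr6b_model):
        table = allele_sharing_table(ltr6b_model.catalog)
        assert table.sum() == len(ltr6b_model.catalog.shared_sites())
        # the synthetic catalog plants an excess of X-minor == Y-major sites
        assert table[0].sum() > table[:, 0].sum()

    def test_no_shared_sites_rejected(self):
        catalog = VariantCatalog([CatalogSite(5, {"A": 1.0}, {"G": 1.0})])
        with pytest.raises(ValueError, match="shared"):
            allele_sharing_test(catalog)
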