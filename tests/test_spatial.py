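"""Fragment assignment and the SNP-gene contact join, checked against
brute-force oracles and order/orientation invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from speqtl.spatial import (assign_to_fragments, find_spatial_pairs,
                            gene_fragment_map)
from speqtl.synthetic import plant_effects, simulate_contacts, simulate_genome
from tests.test_synthetic import _spec


def _frags(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id"])


def _genes(*rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score",
                                     "strand"])
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    return df


def _snps(*rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait_p",
                                       "locus_class", "regulatory_score"])


def _contacts(*rows):
    return pd.DataFrame(rows, columns=["frag_id_a", "frag_id_b", "count", "cell_line"])


TWO_FRAGS = _frags(("chr1", 0, 1000, "f0"), ("chr1", 1000, 2000, "f1"))


def test_point_on_fragment_boundary_goes_to_the_right_fragment():
    pts = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1"], "pos": [999, 1000, 1999]})
    assert list(assign_to_fragments(pts, TWO_FRAGS)) == ["f0", "f1", "f1"]


def test_point_outside_any_fragment_is_explicitly_unmapped():
    pts = pd.DataFrame({"chrom": ["chr1", "chr9"], "pos": [2000, 10]})
    out = assign_to_fragments(pts, TWO_FRAGS)
    assert out.isna().all()


def test_gene_spanning_fragments_maps_to_all_of_them():
    genes = _genes(("chr1", 500, 1500, "gA", ".", "+"))
    assert gene_fragment_map(genes, TWO_FRAGS)["gA"] == {"f0", "f1"}


def test_assignment_matches_brute_force_linear_scan():
    spec = _spec(chromosomes=[("chr1", 30_000), ("chr2", 20_000)],
                 fragment_size_mean=700)
    fragments, _, _ = simulate_genome(spec, seed=13)
    rng = np.random.default_rng(13)
    chroms = rng.choice(["chr1", "chr2", "chrX"], size=10_000)
    pos = rng.integers(0, 35_000, size=10_000)
    pts = pd.DataFrame({"chrom": chroms, "pos": pos})
    fast = assign_to_fragments(pts, fragments)
    rows = fragments.to_dict("records")
    for i in range(0, 10_000, 7):  # spot-check a third of the points exhaustively
        hit = [r["fragment_id"] for r in rows
               if r["chrom"] == chroms[i] and r["start"] <= pos[i] < r["end"]]
        expected = hit[0] if hit else None
        got = fast.iloc[i]
        assert (got is None or (isinstance(got, float) and np.isnan(got))) \
            if expected is None else got == expected


def test_hand_built_join_recovers_exact_pairs():
    fragments = _frags(("chr1", 0, 1000, "f0"), ("chr1", 1000, 2000, "f1"),
                       ("chr2", 0, 1000, "g0f"))
    genes = _genes(("chr2", 100, 900, "gA", ".", "+"))
    snps = _snps(("rs1", "chr1", 500, 1e-8, "non-HLA", 0.5))
    contacts = _contacts(("f0", "g0f", 3, "IMR90"))
    pairs = find_spatial_pairs(snps, genes, fragments, contacts)
    assert len(pairs) == 1
    row = pairs.iloc[0]
    assert (row.snp_id, row.gene_id, row.supporting_contacts) == ("rs1", "gA", 3)
    assert not row.same_fragment


def test_simulator_round_trip_recovers_every_planted_pair():
    spec = _spec(chromosomes=[("chr1", 60_000), ("chr2", 60_000)],
                 n_genes=10, n_snps=15)
    fragments, genes, snps = simulate_genome(spec, seed=21)
    planted = plant_effects(fragments, genes, snps, ["t1"], n_cis=3, n_trans=2,
                            beta=1.0, seed=21)
    contacts = simulate_contacts(fragments, genes, snps, planted, 0.0, seed=21)
    pairs = find_spatial_pairs(snps, genes, fragments, contacts,
                               include_same_fragment=False)
    recovered = set(zip(pairs["snp_id"], pairs["gene_id"]))
    assert {(e.snp_id, e.gene_id) for e in planted} <= recovered


def test_supporting_contacts_sum_across_cell_lines():
    fragments = _frags(("chr1", 0, 1000, "f0"), ("chr2", 0, 1000, "g0f"))
    genes = _genes(("chr2", 0, 800, "gA", ".", "+"))
    snps = _snps(("rs1", "chr1", 10, 1e-8, "non-HLA", 0.5))
    contacts = _contacts(("f0", "g0f", 3, "IMR90"), ("f0", "g0f", 4, "HUVEC"))
    pairs = find_spatial_pairs(snps, genes, fragments, contacts)
    assert pairs.iloc[0].supporting_contacts == 7
    assert pairs.iloc[0].n_cell_lines == 2


def test_min_count_above_all_counts_gives_empty_result():
    fragments = _frags(("chr1", 0, 1000, "f0"), ("chr2", 0, 1000, "g0f"))
    genes = _genes(("chr2", 0, 800, "gA", ".", "+"))
    snps = _snps(("rs1", "chr1", 10, 1e-8, "non-HLA", 0.5))
    contacts = _contacts(("f0", "g0f", 3, "IMR90"))
    pairs = find_spatial_pairs(snps, genes, fragments, contacts, min_count=4,
                               include_same_fragment=False)
    assert pairs.empty


@given(seed=st.integers(0, 200))
def test_min_count_filtering_is_monotone(seed):
    spec = _spec(chromosomes=[("chr1", 30_000)], n_genes=6, n_snps=8,
                 hla_like_interval=("chr1", 0, 5_000))
    fragments, genes, snps = simulate_genome(spec, seed=seed)
    contacts = simulate_contacts(fragments, genes, snps, [], 0.01, seed=seed)
    prev = None
    for mc in (1, 2, 3, 5):
        pairs = find_spatial_pairs(snps, genes, fragments, contacts, min_count=mc,
                                   include_same_fragment=False)
        got = set(zip(pairs["snp_id"], pairs["gene_id"]))
        if prev is not None:
            assert got <= prev
        prev = got


def test_output_invariant_under_row_order_and_orientation():
    spec = _spec(chromosomes=[("chr1", 30_000), ("chr2", 20_000)], n_genes=6,
                 n_snps=8)
    fragments, genes, snps = simulate_genome(spec, seed=4)
    contacts = simulate_contacts(fragments, genes, snps, [], 0.02, seed=4)
    base = find_spatial_pairs(snps, genes, fragments, contacts)
    shuffled = contacts.sample(frac=1, random_state=0).reset_index(drop=True)
    flipped = shuffled.rename(columns={"frag_id_a": "frag_id_b",
                                       "frag_id_b": "frag_id_a"})
    for variant in (shuffled, flipped):
        pd.testing.assert_frame_equal(
            base, find_spatial_pairs(snps, genes, fragments, variant))


def test_join_matches_naive_nested_loop():
    spec = _spec(chromosomes=[("chr1", 25_000), ("chr2", 25_000)], n_genes=8,
                 n_snps=10)
    fragments, genes, snps = simulate_genome(spec, seed=17)
    contacts = simulate_contacts(fragments, genes, snps, [], 0.02, seed=17)
    pairs = find_spatial_pairs(snps, genes, fragments, contacts,
                               include_same_fragment=False)
    got = {(r.snp_id, r.gene_id): r.supporting_contacts
           for r in pairs.itertuples(index=False)}

    from speqtl.spatial import assign_snps_to_fragments
    snp_frag = assign_snps_to_fragments(snps, fragments)
    gfrags = gene_fragment_map(genes, fragments)
    naive = {}
    for snp_id, sf in snp_frag.items():
        for gene_id, gfs in gfrags.items():
            total = 0
            for row in contacts.itertuples(index=False):
                fa, fb, cnt = row.frag_id_a, row.frag_id_b, row[2]
                if (fa == sf and fb in gfs) or (fb == sf and fa in gfs):
                    if fa == fb and sf not in gfs:
                        continue
                    total += cnt
            if total > 0:
                naive[(snp_id, gene_id)] = total
    assert got == naive


def test_empty_contacts_warns_and_returns_empty():
    fragments = _frags(("chr1", 0, 1000, "f0"))
    genes = _genes(("chr2", 0, 800, "gA", ".", "+"))
    snps = _snps(("rs1", "chr1", 10, 1e-8, "non-HLA", 0.5))
    empty = _contacts()
    with pytest.warns(UserWarning, match="empty contact table"):
        pairs = find_spatial_pairs(snps, genes, fragments, empty,
                                   include_same_fragment=False)
    assert pairs.empty


def test_same_fragment_pair_flagged_and_excludable():
    fragments = _frags(("chr1", 0, 1000, "f0"))
    genes = _genes(("chr1", 100, 900, "gA", ".", "+"))
    snps = _snps(("rs1", "chr1", 500, 1e-8, "non-HLA", 0.5))
    no_contacts = _contacts()
    with pytest.warns(UserWarning):
        kept = find_spatial_pairs(snps, genes, fragments, no_contacts,
                                  include_same_fragment=True)
    assert len(kept) == 1 and kept.iloc[0].same_fragment
    assert kept.iloc[0].supporting_contacts == 1
    with pytest.warns(UserWarning):
        dropped = find_spatial_pairs(snps, genes, fragments, no_contacts,
                                     include_same_fragment=False)
    assert dropped.empty
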