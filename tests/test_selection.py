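"""Partition rates, the two-proportion z test and the NG86 dN/dS estimator."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irscreen import (
    CodonAlignment,
    DegenerateProportionsError,
    ExonPartitionTable,
    SiteCall,
    SiteCallSet,
    map_sites_to_partitions,
    ng86_dnds,
    partition_rates,
    two_proportion_z,
)
from irscreen.selection import _diff_fractions, _site_fractions

ISOFORM_PARTITIONS = ExonPartitionTable(
    (("shared", ((1, 575),)), ("type2only", ((576, 700),))), 700
)


def calls_in(ranges_and_counts, category, method="FEL", start_at=1):
    """Spread `count` calls over a partition's first positions."""
    calls = []
    for (start, _end), count in ranges_and_counts:
        calls.extend(
            SiteCall(start + k, category, method) for k in range(count)
        )
    return calls


# ---------------------------------------------------------------------------
# Partition rates


def test_partition_rates_match_printed_isoform_comparison():
    """17/125 and 84/575 negative, 1/125 and 38/575 positive selected sites."""
    calls = SiteCallSet(
        tuple(
            calls_in([((1, 575), 84)], "negative")
            + calls_in([((576, 700), 17)], "negative")
            + [SiteCall(300 + k, "positive", "FEL") for k in range(38)]
            + [SiteCall(650, "positive", "FEL")]
        ),
        700,
    )
    counts = partition_rates(calls, ISOFORM_PARTITIONS)
    shared, specific = counts.row("shared"), counts.row("type2only")
    assert (shared.n_negative, shared.length_aa) == (84, 575)
    assert shared.rate_negative == 14.6
    assert specific.rate_negative == 13.6
    assert shared.rate_positive == 6.6
    assert specific.rate_positive == 0.8


def test_partition_rates_zero_calls():
    counts = partition_rates(SiteCallSet((), 700), ISOFORM_PARTITIONS)
    assert all(
        r.rate_positive == 0.0 and r.rate_negative == 0.0 for r in counts.rows
    )


def test_partition_counts_match_brute_force_membership_scan():
    import numpy as np

    rng = np.random.default_rng(7)
    table = ExonPartitionTable(
        (("a", ((1, 40), (81, 100))), ("b", ((41, 60),)), ("c", ((101, 150),))), 200
    )
    positions = rng.choice(200, size=50, replace=False) + 1
    classes = rng.choice(["positive", "negative"], size=50)
    calls = SiteCallSet(
        tuple(SiteCall(int(p), c, "MEME") for p, c in zip(positions, classes)), 200
    )
    counts = partition_rates(calls, table)
    # oracle: exhaustive per-position membership scan
    for label, intervals in table.partitions:
        members = {
            pos for start, end in intervals for pos in range(start, end + 1)
        }
        for category, attr in (("positive", "n_positive"), ("negative", "n_negative")):
            expected = sum(
                1
                for call in calls.calls
                if call.category == category and call.position in members
            )
            assert getattr(counts.row(label), attr) == expected
    total = sum(r.n_positive + r.n_negative for r in counts.rows)
    total += counts.unassigned_positive + counts.unassigned_negative
    assert total == 50  # conservation


def test_mixed_methods_require_explicit_selection():
    calls = SiteCallSet(
        (SiteCall(5, "positive", "MEME"), SiteCall(6, "positive", "FEL")), 700
    )
    with pytest.raises(ValueError, match="mixes methods"):
        partition_rates(calls, ISOFORM_PARTITIONS)
    counts = partition_rates(calls, ISOFORM_PARTITIONS, method="MEME")
    assert counts.row("shared").n_positive == 1


@pytest.mark.parametrize(
    "position, expected",
    [(1, "a"), (100, "a"), (101, "unassigned")],
)
def test_site_to_partition_mapping_is_inclusive(position, expected):
    table = ExonPartitionTable((("a", ((1, 100),)),), 200)
    calls = SiteCallSet((SiteCall(position, "positive", "MEME"),), 200)
    ((_, label),) = map_sites_to_partitions(calls, table)
    assert label == expected


# ---------------------------------------------------------------------------
# Two-proportion z test


def test_isoform_rate_difference_is_significant_at_printed_p():
    result = two_proportion_z(38, 575, 1, 125)
    assert round(result.p_two_tailed, 2) == 0.01


def test_equal_proportions_give_z_zero_p_one():
    result = two_proportion_z(5, 100, 5, 100)
    assert result.z == 0.0 and result.p_two_tailed == 1.0


def test_z_matches_direct_formula_evaluation():
    result = two_proportion_z(10, 100, 1, 100)
    pooled = 11 / 200
    se = math.sqrt(pooled * (1 - pooled) * (2 / 100))
    z = (0.10 - 0.01) / se
    assert result.z == pytest.approx(z)
    assert result.z == pytest.approx(2.79145, abs=1e-4)
    assert result.p_two_tailed == pytest.approx(0.00525, abs=1e-4)


def test_degenerate_pooled_proportion_errors():
    with pytest.raises(DegenerateProportionsError):
        two_proportion_z(0, 100, 0, 50)
    with pytest.raises(DegenerateProportionsError):
        two_proportion_z(100, 100, 50, 50)
    with pytest.raises(ValueError):
        two_proportion_z(5, 0, 1, 10)


@settings(deadline=None, max_examples=50)
@given(
    st.integers(1, 99), st.integers(100, 200), st.integers(1, 99),
    st.integers(100, 200),
)
def test_z_antisymmetry_under_sample_swap(x1, n1, x2, n2):
    fwd = two_proportion_z(x1, n1, x2, n2)
    rev = two_proportion_z(x2, n2, x1, n1)
    assert rev.z == pytest.approx(-fwd.z)
    assert rev.p_two_tailed == pytest.approx(fwd.p_two_tailed)


# ---------------------------------------------------------------------------
# Codon alignments


@pytest.mark.parametrize(
    "a, b, message",
    [
        ("ATGA", "ATGA", "multiple of 3"),
        ("ATG", "ATGAAA", "length"),
        ("ATG---", "ATGAAA", "illegal"),
        ("ATGTAAAAA", "ATGAAAAAA", "stop"),
        ("", "", "multiple of 3|empty"),
    ],
)
def test_codon_alignment_validation(a, b, message):
    with pytest.raises(ValueError, match=message):
        CodonAlignment(a, b)


# ---------------------------------------------------------------------------
# NG86


def test_site_fractions_known_codons():
    # TTT (Phe): only position 3 T->C is synonymous -> 1/3 synonymous sites
    assert _site_fractions("TTT") == pytest.approx((1 / 3, 8 / 3))
    # Four-fold degenerate third position: GGN all Gly
    assert _site_fractions("GGT") == pytest.approx((1.0, 2.0))
    # ATG (Met): no synonymous neighbour
    assert _site_fractions("ATG") == pytest.approx((0.0, 3.0))


def test_site_counts_sum_to_three_per_codon():
    aln = CodonAlignment("ATGAAACTGGTGCCCGGT", "ATGAAACTGGTGCCCGGT")
    result = ng86_dnds(aln)
    assert result.n_sites + result.s_sites == pytest.approx(3 * aln.n_codons)


def test_identical_sequences_have_zero_divergence():
    result = ng86_dnds(CodonAlignment("ATGAAACCC", "ATGAAACCC"))
    assert result.nd == result.sd == 0.0
    assert result.dn == result.ds == 0.0
    assert result.omega is None and "ds_zero" in result.flags


def test_stop_traversing_paths_are_excluded():
    # TCA (Ser) -> TGG (Trp): the path via position 2 first passes through the
    # stop codon TGA, leaving the single path TCA -> TCG (syn) -> TGG (nonsyn).
    assert _diff_fractions("TCA", "TGG") == pytest.approx((1.0, 1.0))


def test_two_position_difference_averages_both_paths():
    # AAA (Lys) -> ACG (Thr): AAA->ACA (nonsyn) ->ACG (syn) and
    # AAA->AAG (syn) ->ACG (nonsyn); average (1, 1).
    assert _diff_fractions("AAA", "ACG") == pytest.approx((1.0, 1.0))


# Golden values frozen from an independent enumeration of the counting rules
# (cross-checked against Bio.codonalign cal_dn_ds on this fixture, whose
# mutational paths avoid stop codons so both conventions coincide).
FIXTURE_A = "ATGAAACTGGTGCCCGGTGACCATAAAGCTTGCACC"
FIXTURE_B = "ATGAGACTTGTGCACGGAGACCATACGGCTTGCACC"


def test_ng86_fixture_matches_frozen_golden_values():
    result = ng86_dnds(CodonAlignment(FIXTURE_A, FIXTURE_B))
    assert result.n_sites == pytest.approx(28.0)
    assert result.s_sites == pytest.approx(8.0)
    assert (result.nd, result.sd) == (3.0, 3.0)
    assert result.dn == pytest.approx(0.1156130, abs=1e-6)
    assert result.ds == pytest.approx(0.5198604, abs=1e-6)
    assert result.omega == pytest.approx(0.2223924, abs=1e-6)


def test_ng86_agrees_with_independent_biopython_route():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    dn, ds = cal_dn_ds(CodonSeq(FIXTURE_A), CodonSeq(FIXTURE_B), method="NG86")
    result = ng86_dnds(CodonAlignment(FIXTURE_A, FIXTURE_B))
    assert result.dn == pytest.approx(dn)
    assert result.ds == pytest.approx(ds)


def test_ng86_is_symmetric_in_its_inputs():
    fwd = ng86_dnds(CodonAlignment(FIXTURE_A, FIXTURE_B))
    rev = ng86_dnds(CodonAlignment(FIXTURE_B, FIXTURE_A))
    assert fwd == rev


def test_saturated_synonymous_divergence_is_flagged():
    # ps >= 3/4 makes the Jukes-Cantor correction diverge
    result = ng86_dnds(
        CodonAlignment("GGTGGCGGAGGG" * 3, "GGCGGAGGGGGT" * 3)
    )
    assert result.ds is None
    assert "ds_correction_diverges" in result.flags
    assert result.omega is None


def test_omega_recovery_from_simulation_at_half():
    """A 500-codon pair simulated at true omega = 0.5 is recovered closely."""
    from irscreen import simulate_codon_family
    from irscreen.simulate import codon_alignment_pair

    leaves, _ = simulate_codon_family(
        "(a:0.15,b:0.15);", 500, kappa=1.0, omega_classes=((0.5, 1.0),), seed=11
    )
    result = ng86_dnds(codon_alignment_pair(leaves, "a", "b"))
    assert result.omega == pytest.approx(0.5, abs=0.15)
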