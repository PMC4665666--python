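import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rsalogit import (
    AlignmentProfile,
    AminoClassScheme,
    ChainSequence,
    DEFAULT_SIX_CLASSES,
    PairwiseHit,
    ParseError,
    build_profile,
    entropy6,
    entropy20,
    filter_hits,
    fshp,
    fsr,
    homology_status,
)
from rsalogit.io_formats import STANDARD_AA, STRONGLY_HYDROPHOBIC

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
_CLASS_OF = {aa: ci for ci, cls in enumerate(DEFAULT_SIX_CLASSES.classes)
             for aa in cls}


def profile_from_counts(count_map, n_hits=None):
    counts = np.zeros((1, 20))
    for aa, c in count_map.items():
        counts[0, _AA_INDEX[aa]] = c
    total = int(sum(count_map.values()))
    return AlignmentProfile(chain_id="x", counts=counts,
                            n_hits=n_hits if n_hits is not None else total)


def entropy_oracle(letters, classes=None):
    """Brute-force multiset entropy: tally letters (optionally mapped to a
    class first), then -sum p ln p."""
    mapped = [classes[a] if classes else a for a in letters]
    n = len(mapped)
    return -sum(
        (c / n) * math.log(c / n) for c in Counter(mapped).values()
    )


def _hit(qseq, sseq, qstart=1, score=100.0, sid="s1"):
    return PairwiseHit(query_id="q", subject_id=sid, bit_score=score,
                       query_start=qstart, aligned_query=qseq,
                       aligned_subject=sseq)


# ----------------------------------------------------------- filter_hits

def test_filter_hits_examples():
    hits = [_hit("M", "M", score=s, sid=f"s{s}") for s in (100.0, 50.0, 39.9)]
    kept = filter_hits(hits)
    assert [h.bit_score for h in kept] == [100.0, 50.0]
    # the 40% boundary is inclusive
    boundary = [_hit("M", "M", score=100.0), _hit("M", "M", score=40.0, sid="s2")]
    assert len(filter_hits(boundary)) == 2
    assert filter_hits([_hit("M", "M", score=87.0)]) == [_hit("M", "M", score=87.0)]
    assert filter_hits([]) == []


@pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
def test_filter_hits_fraction_out_of_range(fraction):
    with pytest.raises(ValueError):
        filter_hits([_hit("M", "M")], fraction)


@given(
    scores=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=30),
    f_lo=st.floats(0.05, 1.0),
    f_hi=st.floats(0.05, 1.0),
)
def test_filter_hits_monotone_in_fraction(scores, f_lo, f_hi):
    """Raising the bit-score fraction never enlarges the retained set."""
    f_lo, f_hi = min(f_lo, f_hi), max(f_lo, f_hi)
    hits = [_hit("M", "M", score=s, sid=f"s{i}") for i, s in enumerate(scores)]
    kept_lo = {h.subject_id for h in filter_hits(hits, f_lo)}
    kept_hi = {h.subject_id for h in filter_hits(hits, f_hi)}
    assert kept_hi <= kept_lo


# --------------------------------------------------------- build_profile

def test_build_profile_single_hit():
    query = ChainSequence("q", "MKV")
    profile = build_profile(query, [_hit("MKV", "MRV")])
    assert profile.counts[1, _AA_INDEX["R"]] == 1
    assert profile.n_aligned[1] == 1
    assert profile.n_hits == 1


def test_build_profile_subject_gap_excluded():
    query = ChainSequence("q", "MKV")
    profile = build_profile(query, [_hit("MKV", "M-V")])
    assert profile.n_aligned[1] == 0


def test_build_profile_two_hits_accumulate():
    query = ChainSequence("q", "MKV")
    profile = build_profile(
        query, [_hit("MKV", "MKV"), _hit("MKV", "MRV", sid="s2")]
    )
    assert profile.counts[1, _AA_INDEX["K"]] == 1
    assert profile.counts[1, _AA_INDEX["R"]] == 1
    assert profile.n_aligned[1] == 2


def test_build_profile_query_gap_column_maps_nothing():
    # insertion in the subject: query '-' column consumes no query position
    query = ChainSequence("q", "MKV")
    profile = build_profile(query, [_hit("MK-V", "MKAV")])
    assert profile.n_aligned.tolist() == [1, 1, 1]


def test_build_profile_mismatch_names_position():
    query = ChainSequence("q", "MKV")
    with pytest.raises(ParseError, match="position 2"):
        build_profile(query, [_hit("MRV", "MRV")])


def test_build_profile_overrun_is_error():
    query = ChainSequence("q", "MKVAG")
    with pytest.raises(ParseError, match="past the end"):
        build_profile(query, [_hit("VAGMK", "VAGMK", qstart=3)])


def test_build_profile_nonstandard_subject_letter_excluded():
    query = ChainSequence("q", "MKV")
    profile = build_profile(query, [_hit("MKV", "MBV")])
    assert profile.n_aligned[1] == 0


# ------------------------------------------------------------- entropies

def test_entropy20_examples():
    assert entropy20(profile_from_counts({"L": 8}), 1) == 0.0
    assert entropy20(profile_from_counts({"V": 2, "L": 2}), 1) == pytest.approx(
        math.log(2), abs=1e-12
    )
    uniform = profile_from_counts({aa: 1 for aa in STANDARD_AA})
    assert entropy20(uniform, 1) == pytest.approx(math.log(20), abs=1e-12)


def test_entropy6_examples():
    # V and L share the aliphatic class: a single-class column
    assert entropy6(profile_from_counts({"V": 3, "L": 1}), 1) == 0.0
    # one residue from each of the six classes
    six = profile_from_counts({"A": 1, "F": 1, "S": 1, "K": 1, "D": 1, "G": 1})
    assert entropy6(six, 1) == pytest.approx(math.log(6), abs=1e-12)
    # class probabilities {0.75, 0.25}
    three_one = profile_from_counts({"V": 3, "K": 1})
    expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
    assert entropy6(three_one, 1) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.5623, abs=5e-5)


def test_empty_column_descriptors_missing():
    profile = AlignmentProfile(chain_id="x", counts=np.zeros((1, 20)), n_hits=3)
    assert math.isnan(entropy20(profile, 1))
    assert math.isnan(entropy6(profile, 1))
    assert math.isnan(fshp(profile, 1))
    assert math.isnan(fsr(profile, 1))


def test_fshp_fsr_examples():
    p = profile_from_counts({"V": 1, "L": 1, "A": 1, "G": 1})
    assert fshp(p, 1) == 0.5
    assert fsr(p, 1) == 0.5
    assert fshp(profile_from_counts({"W": 4}), 1) == 1.0
    assert fshp(profile_from_counts({"G": 4}), 1) == 0.0
    assert fsr(profile_from_counts({"A": 4}), 1) == 1.0
    assert fsr(profile_from_counts({"K": 2, "V": 2}), 1) == 0.0


column_strategy = st.lists(
    st.sampled_from(STANDARD_AA), min_size=1, max_size=60
)


@given(letters=column_strategy)
def test_entropy_matches_brute_force_oracle(letters):
    profile = profile_from_counts(Counter(letters))
    assert entropy20(profile, 1) == pytest.approx(
        entropy_oracle(letters), abs=1e-12
    )
    assert entropy6(profile, 1) == pytest.approx(
        entropy_oracle(letters, _CLASS_OF), abs=1e-12
    )


@given(letters=column_strategy)
def test_coarse_graining_cannot_increase_entropy(letters):
    profile = profile_from_counts(Counter(letters))
    assert 0.0 <= entropy6(profile, 1) <= entropy20(profile, 1) + 1e-12
    assert entropy20(profile, 1) <= math.log(20) + 1e-12


@given(letters=column_strategy)
def test_entropy_invariant_under_duplication(letters):
    """Duplicating the whole hit set leaves the column probabilities — hence
    all four descriptors — unchanged."""
    single = profile_from_counts(Counter(letters))
    doubled = profile_from_counts({a: 2 * c for a, c in Counter(letters).items()})
    for func in (entropy20, entropy6, fshp, fsr):
        assert func(single, 1) == pytest.approx(func(doubled, 1), abs=1e-12)


@given(letters=column_strategy)
def test_fshp_complement_sums_to_one(letters):
    profile = profile_from_counts(Counter(letters))
    non_hyd = sum(1 for a in letters if a not in STRONGLY_HYDROPHOBIC)
    assert fshp(profile, 1) + non_hyd / len(letters) == pytest.approx(1.0, abs=1e-12)


def test_hit_order_permutation_invariance(rng):
    query = ChainSequence("q", "MKVA")
    hits = [
        _hit("MKVA", "MRVA"), _hit("MKVA", "MKLA", sid="s2"),
        _hit("MKVA", "WKVG", sid="s3"),
    ]
    forward = build_profile(query, hits)
    backward = build_profile(query, hits[::-1])
    assert np.array_equal(forward.counts, backward.counts)


# ------------------------------------------------------- homology status

@pytest.mark.parametrize("n_hits,expected", [(10, "optimum"), (9, "non_optimum"),
                                             (0, "non_optimum")])
def test_homology_status_boundary(n_hits, expected):
    profile = AlignmentProfile(chain_id="x", counts=np.zeros((1, 20)),
                               n_hits=n_hits)
    assert homology_status(profile) == expected


# ------------------------------------------------------------ scheme

def test_class_scheme_must_partition():
    with pytest.raises(ValueError):
        AminoClassScheme("five", DEFAULT_SIX_CLASSES.classes[:5])
    overlapping = (frozenset("AVLIMC"), frozenset("CFWYH"), frozenset("STNQ"),
                   frozenset("KR"), frozenset("DE"), frozenset("GP"))
    with pytest.raises(ValueError):
        AminoClassScheme("overlap", overlapping)
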