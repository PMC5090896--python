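"""Break profiler: location profiles, break detection, candidate calling,
feature extraction and truth labelling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chimerabench.kmer import GenomeKmerIndex, SupportTable
from chimerabench.mutate import FusionTruth
from chimerabench.profiler import (
    Break,
    CandidateJunction,
    KmerProfile,
    ProfilerParams,
    call_candidate,
    detect_breaks,
    extract_features,
    junction_matches_truth,
    label_candidates,
    profile_read,
)

from conftest import random_sequences

K = 16  # large enough that accidental matches on the toy genome are negligible
PARAMS = ProfilerParams(k=K)


@pytest.fixture(scope="module")
def toy_genome():
    return random_sequences({"chr1": 4000, "chr2": 4000}, seed=123)


@pytest.fixture(scope="module")
def toy_index(toy_genome):
    return GenomeKmerIndex(toy_genome, k=K)


def _support_for(reads):
    return SupportTable(reads, K)


def test_genomic_substring_fully_mapped(toy_genome, toy_index):
    read = toy_genome["chr1"][100:160]
    prof = profile_read(read, toy_index, _support_for([read]))
    assert len(prof) == 60 - K + 1
    assert prof.mapped.all()


def test_clean_chimeric_read_breaks_exactly_k_minus_1(toy_genome, toy_index):
    """A junction at offset j in [k, L-k] yields k-1 consecutive
    location-less k-mers at positions j-k+1 .. j-1."""
    L = 60
    for j in (K, 25, 40, L - K):
        read, _ = _chimera_read(toy_genome, 200, 700, j, L=L)
        prof = profile_read(read, toy_index, _support_for([read]))
        unmapped = np.nonzero(~prof.mapped)[0]
        assert unmapped.tolist() == list(range(j - K + 1, j))


def test_read_of_length_k_has_profile_length_one(toy_genome, toy_index):
    read = toy_genome["chr1"][0:K]
    prof = profile_read(read, toy_index, _support_for([read]))
    assert len(prof) == 1


def test_read_shorter_than_k_skipped_with_warning(toy_index):
    with pytest.warns(UserWarning, match="shorter than k"):
        assert profile_read("ACGT", toy_index, _support_for([])) is None


@pytest.mark.parametrize(
    "flags,gap,expected",
    [
        ([1, 1, 1, 1], 2, []),
        ([1, 1, 0, 0, 0, 1, 1], 2, [(2, 4, 1)]),
        ([1, 0, 0, 1, 0, 0, 1], 1, [(1, 5, 2)]),
        ([1, 0, 0, 1, 0, 0, 1], 0, [(1, 2, 1), (4, 5, 1)]),
        ([0, 0, 1, 1, 1, 1, 0], 2, [(0, 1, 1), (6, 6, 1)]),
    ],
)
def test_detect_breaks_hand_traces(flags, gap, expected):
    got = [(b.start, b.end, b.n_merged) for b in detect_breaks(flags, gap)]
    assert got == expected


def _naive_breaks(flags, merge_gap):
    """Independent oracle: explicit left-to-right scan of the merge rule."""
    runs = []
    i = 0
    while i < len(flags):
        if not flags[i]:
            j = i
            while j + 1 < len(flags) and not flags[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            ps, pe, n = merged[-1]
            merged[-1] = (ps, e, n + 1)
        else:
            merged.append((s, e, 1))
    return merged


def test_detect_breaks_matches_naive_scan_on_random_profiles():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        flags = (rng.random(rng.integers(1, 40)) < 0.7).tolist()
        for gap in (0, 1, 2, 3):
            got = [(b.start, b.end, b.n_merged) for b in detect_breaks(flags, gap)]
            assert got == _naive_breaks(flags, gap)


def _chimera_read(toy_genome, a, b, j, L=60, chrom_b="chr2"):
    """Junction read from two loci, avoiding terminal micro-homology (a
    junction whose first foreign base equals the reference continuation
    legitimately shortens the break, so the k-1 closed form needs
    homology-free junctions)."""
    g1, g2 = toy_genome["chr1"], toy_genome[chrom_b]
    while g2[b] == g1[a + j] or g2[b - 1] == g1[a + j - 1]:
        b += 1
    return g1[a : a + j] + g2[b : b + L - j], b


def _call_on(toy_genome, toy_index, read):
    prof = profile_read(read, toy_index, _support_for([read]))
    breaks = detect_breaks(prof.mapped, PARAMS.merge_gap)
    assert len(breaks) == 1
    return prof, call_candidate(prof, breaks[0], toy_index, PARAMS)


def test_interchromosomal_anchors_give_class_1_candidate(toy_genome, toy_index):
    read, b = _chimera_read(toy_genome, 200, 700, 30)
    prof, cand = _call_on(toy_genome, toy_index, read)
    assert cand.category == "chimera_candidate"
    assert cand.class_hint == 1
    # junction coordinates recover the construction exactly
    assert (cand.chrom_l, cand.pos_l) == ("chr1", 229)
    assert (cand.chrom_r, cand.pos_r) == ("chr2", b)


def test_intron_sized_colinear_gap_is_splice(toy_genome, toy_index):
    read = toy_genome["chr1"][200:230] + toy_genome["chr1"][330:360]
    prof, cand = _call_on(toy_genome, toy_index, read)
    assert cand.category == "splice"


def test_inverted_order_gives_class_2(toy_genome, toy_index):
    read = toy_genome["chr1"][2000:2030] + toy_genome["chr1"][500:530]
    prof, cand = _call_on(toy_genome, toy_index, read)
    assert cand.category == "chimera_candidate"
    assert cand.class_hint == 2


def test_opposite_strand_gives_class_3(toy_genome, toy_index):
    from chimerabench.reads import revcomp

    read = toy_genome["chr1"][200:230] + revcomp(toy_genome["chr1"][2000:2030])
    prof, cand = _call_on(toy_genome, toy_index, read)
    assert cand.category == "chimera_candidate"
    assert cand.class_hint == 3


def test_break_at_read_edge_is_unresolved(toy_genome, toy_index):
    read = "T" * 12 + toy_genome["chr1"][600:648]  # break reaches the read start
    prof = profile_read(read, toy_index, _support_for([read]))
    breaks = detect_breaks(prof.mapped, PARAMS.merge_gap)
    cand = call_candidate(prof, breaks[0], toy_index, PARAMS)
    assert cand.category == "unresolved"
    assert cand.left_anchor is None


def _manual_candidate(support_values, k=6, flank_value=9):
    """Profile with a single central break and prescribed support inside it."""
    w = len(support_values)
    mult = np.array([1] * k + [0] * w + [1] * k)
    support = np.array([flank_value] * k + list(support_values) + [flank_value] * k)
    prof = KmerProfile("r", "N", np.zeros(mult.size, dtype=np.int64), mult, support)
    brk = Break(k, k + w - 1, 1)
    cand = CandidateJunction(
        read_id="r", brk=brk,
        left_anchor=("chr1", 0, "+"), right_anchor=("chr2", 0, "+"),
        chrom_l="chr1", pos_l=5, strand_l="+", chrom_r="chr2", pos_r=0, strand_r="+",
        category="chimera_candidate", class_hint=1, left_mult=1, right_mult=1,
    )
    return cand, prof


def test_feature_values_from_type7_quartiles():
    cand, prof = _manual_candidate([1, 2, 3, 4, 5])
    feats = extract_features(cand, prof, k=6)
    assert feats["coefficient_dispersion_interquartile"] == pytest.approx((4 - 2) / (4 + 2))
    assert feats["score_break_variance"] == pytest.approx(2.0)
    assert feats["score_break_length"] == pytest.approx(5 / 5)
    assert feats["mean_amplitude"] == pytest.approx(9 - 3)
    assert feats["score_is_duplicate"] == 0.0


def test_constant_break_support_zeroes_dispersion_features():
    cand, prof = _manual_candidate([4, 4, 4, 4])
    feats = extract_features(cand, prof, k=6)
    assert feats["score_break_variance"] == 0.0
    assert feats["coefficient_variation"] == 0.0
    assert feats["coefficient_dispersion_interquartile"] == 0.0


def test_clean_junction_score_break_length_is_one(toy_genome, toy_index):
    read, _ = _chimera_read(toy_genome, 900, 1500, 25)
    prof, cand = _call_on(toy_genome, toy_index, read)
    feats = extract_features(cand, prof, K)
    assert feats["score_break_length"] == pytest.approx(1.0)  # (k-1)/(k-1)
    assert feats["score_nb_merge"] == 1.0


@given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=15))
def test_feature_ranges(support_values):
    cand, prof = _manual_candidate(support_values)
    feats = extract_features(cand, prof, k=6)
    assert 0.0 <= feats["coefficient_dispersion_interquartile"] <= 1.0
    assert feats["score_break_variance"] >= 0.0
    assert feats["coefficient_variation"] >= 0.0
    assert feats["score_is_duplicate"] in (0.0, 1.0)
    assert feats["score_has_repeat"] in (0.0, 1.0)
    assert feats["score_break_length"] > 0.0


def test_errors_never_shrink_the_junction_break(toy_genome, toy_index):
    """Extra substitution errors can extend or merge, never shorten, the
    break spanning the junction."""
    rng = np.random.default_rng(5)
    L = 60
    for _ in range(30):
        j = int(rng.integers(K, L - K))
        read, _ = _chimera_read(toy_genome, 150, 2200, j, L=L)
        prof = profile_read(read, toy_index, _support_for([read]))
        base = [b for b in detect_breaks(prof.mapped, 2) if b.start <= j - 1 <= b.end]
        p = int(rng.integers(0, L))
        alt = "ACGT"[(("ACGT".index(read[p])) + 1) % 4]
        noisy = read[:p] + alt + read[p + 1 :]
        prof2 = profile_read(noisy, toy_index, _support_for([noisy]))
        after = [b for b in detect_breaks(prof2.mapped, 2) if b.start <= j - 1 <= b.end]
        assert after and base
        assert after[0].width >= base[0].width


def _toy_truth(breakpoint3=700):
    return FusionTruth(
        event_id="T001a", gene5="A", gene5_exons=(0, 1), gene3="B", gene3_exons=(1, 2),
        chrom5="chr1", breakpoint5=230, chrom3="chr2", breakpoint3=breakpoint3,
        reciprocal_id="T001b",
    )


def test_truth_matching_and_labelling(toy_genome, toy_index):
    read, b = _chimera_read(toy_genome, 200, 700, 30)
    prof, cand = _call_on(toy_genome, toy_index, read)
    fusion = _toy_truth(b)
    assert junction_matches_truth(cand, fusion, tolerance=5)
    labels = label_candidates([cand], {cand.read_id: (True, "T001a")}, {"T001a": fusion})
    assert labels == [True]
    # a candidate on a normal read stays FALSE even with valid anchors
    labels = label_candidates([cand], {cand.read_id: (False, None)}, {"T001a": fusion})
    assert labels == [False]


def test_labelling_unknown_read_errors(toy_genome, toy_index):
    read, _ = _chimera_read(toy_genome, 200, 700, 30)
    prof, cand = _call_on(toy_genome, toy_index, read)
    with pytest.raises(KeyError):
        label_candidates([cand], {}, {})


def test_mismatched_junction_is_false(toy_genome, toy_index):
    read, b = _chimera_read(toy_genome, 200, 700, 30)
    prof, cand = _call_on(toy_genome, toy_index, read)
    fusion = _toy_truth(b)
    shifted = FusionTruth(**{**fusion.__dict__, "breakpoint5": 300})
    assert not junction_matches_truth(cand, shifted, tolerance=5)
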